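parameter,M,sigma,extreme_low,extreme_high,level2_group,level3_block,source
"SDNN, ms",50,20,-30,130,Time-domain HRV,Regulation,literature
"RMSSD, ms",42,18,-30,114,Time-domain HRV,Regulation,literature
"SDSD, ms",42,18,-30,114,Time-domain HRV,Regulation,literature
"PNN50, %",18,10,-22,58,Time-domain HRV,Regulation,literature
"LF, ms2",1170,700,-1630,3970,Frequency-domain HRV,Regulation,literature
"HF, ms2",975,600,-1425,3375,Frequency-domain HRV,Regulation,literature
LF/HF ratio,1.8,1.0,-2.2,5.8,Frequency-domain HRV,Regulation,literature
Heart rate (bpm),70,9,34,106,Rhythm stability,Regulation,literature
RR range (ms),250,100,-150,650,Rhythm stability,Regulation,literature
Amplitude P-wave (μV) (lead II),120,40,-40,280,ECG waves amplitudes index (lead II),Myocardial condition,literature
Amplitude Q-wave (μV) (lead II),-60,30,-180,60,ECG waves amplitudes index (lead II),Myocardial condition,literature
Amplitude R-wave (μV) (lead II),1000,300,-200,2200,ECG waves amplitudes index (lead II),Myocardial condition,literature
Amplitude S-wave (μV) (lead II),-150,80,-470,170,ECG waves amplitudes index (lead II),Myocardial condition,literature
Amplitude T-wave (μV) (lead II),250,100,-150,650,ECG waves amplitudes index (lead II),Myocardial condition,literature
P duration (sec),0.10,0.02,0.02,0.18,ECG interval duration index,Myocardial condition,literature
Q duration (sec),0.02,0.01,-0.02,0.06,ECG interval duration index,Myocardial condition,literature
QRS duration (sec),0.09,0.015,0.03,0.15,ECG interval duration index,Myocardial condition,literature
Duration PQ (sec),0.16,0.02,0.08,0.24,ECG interval duration index,Myocardial condition,literature
Duration QT (sec),0.40,0.03,0.28,0.52,ECG interval duration index,Myocardial condition,literature
QTcF duration (sec),0.41,0.02,0.33,0.49,ECG interval duration index,Myocardial condition,literature
Macruz index P/(PQ-P),1.6,0.5,-0.4,3.6,Atrial conduction,Arrhythmia,literature
J-point dislocation (μV) (lead I),0,25,-100,100,Repolarisation stability,Arrhythmia,literature
J-point dislocation (μV) (lead II),0,25,-100,100,Repolarisation stability,Arrhythmia,literature
Baevsky stress index,120,60,-120,360,Autonomic stress indices,Psycho-emotional status,literature
Mashin psycho-emotional index,0.5,0.25,-0.5,1.5,Autonomic stress indices,Psycho-emotional status,literature
McCraty psycho-emotional index,1.0,0.6,-1.4,3.4,Autonomic stress indices,Psycho-emotional status,literature
Detrended Fluctuation Analysis (DFA) of HRV,1.0,0.15,0.4,1.6,Autonomic stress indices,Psycho-emotional status,literature
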