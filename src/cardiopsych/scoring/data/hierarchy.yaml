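# Four-level composite hierarchy: root -> blocks -> groups -> parameters.
# Group membership is a documented reconstruction; membership lists and norm
# anchors (norm_ranges.csv) are configuration, not fixed facts.
name: Integral cardiovascular indicator
children:
  - name: Regulation
    children:
      - name: Time-domain HRV
        leaves:
          - "SDNN, ms"
          - "RMSSD, ms"
          - "SDSD, ms"
          - "PNN50, %"
      - name: Frequency-domain HRV
        leaves:
          - "LF, ms2"
          - "HF, ms2"
          - "LF/HF ratio"
      - name: Rhythm stability
        leaves:
          - "Heart rate (bpm)"
          - "RR range (ms)"
  - name: Myocardial condition
    children:
      - name: ECG waves amplitudes index (lead II)
        leaves:
          - "Amplitude P-wave (μV) (lead II)"
          - "Amplitude Q-wave (μV) (lead II)"
          - "Amplitude R-wave (μV) (lead II)"
          - "Amplitude S-wave (μV) (lead II)"
          - "Amplitude T-wave (μV) (lead II)"
      - name: ECG interval duration index
        leaves:
          - "P duration (sec)"
          - "Q duration (sec)"
          - "QRS duration (sec)"
          - "Duration PQ (sec)"
          - "Duration QT (sec)"
          - "QTcF duration (sec)"
  - name: Arrhythmia
    children:
      - name: Atrial conduction
        leaves:
          - "Macruz index P/(PQ-P)"
      - name: Repolarisation stability
        leaves:
          - "J-point dislocation (μV) (lead I)"
          - "J-point dislocation (μV) (lead II)"
  - name: Psycho-emotional status
    children:
      - name: Autonomic stress indices
        leaves:
          - "Baevsky stress index"
          - "Mashin psycho-emotional index"
          - "McCraty psycho-emotional index"
          - "Detrended Fluctuation Analysis (DFA) of HRV"
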