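"""6-lead ECG and HRV feature extraction.

``extract_features`` runs the whole chain (R peaks -> delineation ->
measurement -> ratios -> HRV) and returns one labelled row per subject whose
column names match the published feature labels (e.g.
"Amplitude Q-wave (μV) (lead AvR)", "PNN50, %", "QTcF duration (sec)").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cardiopsych.core import ECGRecord, LEAD_DISPLAY, RRSeries
from cardiopsych.errors import InsufficientDataError
from cardiopsych.features.rpeaks import detect_r_peaks
from cardiopsych.features.delineation import FiducialSet, delineate, measure_waves
from cardiopsych.features.ratios import derive_ratios
from cardiopsych.features.hrv import hrv_time, hrv_freq, hrv_dfa, psycho_indices

__all__ = [
    "detect_r_peaks", "delineate", "measure_waves", "derive_ratios",
    "hrv_time", "hrv_freq", "hrv_dfa", "psycho_indices",
    "extract_features", "FiducialSet",
]

LBL_DFA = "Detrended Fluctuation Analysis (DFA) of HRV"

_HRV_LABELS = {
    "sdnn": "SDNN, ms", "rmssd": "RMSSD, ms", "sdsd": "SDSD, ms",
    "pnn50": "PNN50, %", "lf": "LF, ms2", "hf": "HF, ms2",
    "lf_hf": "LF/HF ratio",
    "baevsky_si": "Baevsky stress index",
    "mashin_index": "Mashin psycho-emotional index",
    "mccraty_coherence": "McCraty psycho-emotional index",
}

_DUR_LABELS = {
    "P_dur": "P duration (sec)", "Q_dur": "Q duration (sec)",
    "QRS_dur": "QRS duration (sec)", "PQ_dur": "Duration PQ (sec)",
    "QT_dur": "Duration QT (sec)",
}


def measurement_labels(measurements: pd.DataFrame,
                       interval_lead: str = "II") -> pd.Series:
    """Flatten a per-lead measurement table into published feature labels."""
    out: dict[str, float] = {}
    for lead in measurements.index:
        disp = LEAD_DISPLAY.get(lead, lead)
        m = measurements.loc[lead]
        for wave in ("P", "Q", "R", "S", "T"):
            out[f"Amplitude {wave}-wave (μV) (lead {disp})"] = float(m[f"{wave}_amp"])
        out[f"Area P (μV·s) (lead {disp})"] = float(m["P_area"])
        out[f"Area QRS (μV·s) (lead {disp})"] = float(m["QRS_area"])
        out[f"J-point dislocation (μV) (lead {disp})"] = float(m["J_disp"])
    ival = measurements.loc[interval_lead]
    for key, label in _DUR_LABELS.items():
        out[label] = float(ival[key])
    return pd.Series(out)


def extract_features(record: ECGRecord, rr: RRSeries | None = None,
                     detection_lead: str = "II",
                     interval_lead: str = "II") -> pd.Series:
    """Full feature row for one subject.

    When ``rr`` is omitted the RR series is taken from the detected R peaks.
    HRV metrics that need more data than is available are reported missing.
    """
    rpeaks = detect_r_peaks(record, lead=detection_lead)
    fiducials = delineate(record, rpeaks)
    measurements = measure_waves(record, fiducials)

    if rr is None:
        ms = np.diff(rpeaks) / record.sampling_rate * 1000.0
        rr = RRSeries(ms) if ms.size else None
    rr_mean_s = float(np.mean(rr.intervals_ms)) / 1000.0 if rr is not None else None

    row = measurement_labels(measurements, interval_lead=interval_lead)
    row = pd.concat([row, derive_ratios(measurements, rr_mean_s=rr_mean_s,
                                        interval_lead=interval_lead)])

    hrv_row: dict[str, float] = {}
    if rr is not None:
        x = rr.intervals_ms
        hrv_row["Heart rate (bpm)"] = 60000.0 / float(np.mean(x))
        hrv_row["RR range (ms)"] = float(np.ptp(x))
        for fn in (hrv_time, hrv_freq, psycho_indices):
            try:
                for key, val in fn(rr).items():
                    hrv_row[_HRV_LABELS.get(key, key)] = val
            except InsufficientDataError:
                pass
        try:
            hrv_row[LBL_DFA] = hrv_dfa(rr)
        except InsufficientDataError:
            pass
    return pd.concat([row, pd.Series(hrv_row, dtype=float)])
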