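"""Derived amplitude/area/interval ratios: Q/R, R/P, R/T, P/QRS, Macruz, QTcF."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cardiopsych.core import LEAD_DISPLAY
from cardiopsych.errors import MeasurementError

log = logging.getLogger(__name__)


def _safe_ratio(num: float, den: float, label: str) -> float:
    """Ratio with the missing-value convention: zero denominator -> NaN, logged."""
    if den == 0 or not np.isfinite(den) or not np.isfinite(num):
        log.warning("ratio %s undefined (denominator %r); reported missing",
                    label, den)
        return np.nan
    return num / den


def derive_ratios(measurements: pd.DataFrame,
                  rr_mean_s: float | None = None,
                  interval_lead: str = "II") -> pd.Series:
    """Flat labelled series of ratio features from a per-lead measurement table.

    Amplitude ratios use absolute amplitudes.  Macruz index and QTcF are
    computed from the durations measured on ``interval_lead``; QTcF
    (Fridericia, QT / RR^(1/3)) requires ``rr_mean_s``.
    """
    out: dict[str, float] = {}
    for lead in measurements.index:
        disp = LEAD_DISPLAY.get(lead, lead)
        m = measurements.loc[lead]
        out[f"Amplitude Q/R ratio (lead {disp})"] = _safe_ratio(
            abs(m["Q_amp"]), abs(m["R_amp"]), f"Q/R lead {disp}")
        out[f"Amplitude ratio R/P (lead {disp})"] = _safe_ratio(
            abs(m["R_amp"]), abs(m["P_amp"]), f"R/P lead {disp}")
        out[f"R/T amplitude ratio (lead {disp})"] = _safe_ratio(
            abs(m["R_amp"]), abs(m["T_amp"]), f"R/T lead {disp}")
        out[f"Area ratio P/QRS (lead {disp})"] = _safe_ratio(
            m["P_area"], m["QRS_area"], f"P/QRS area lead {disp}")

    if interval_lead not in measurements.index:
        raise MeasurementError(
            f"interval lead {interval_lead!r} not measured; available: "
            f"{list(measurements.index)}")
    ival = measurements.loc[interval_lead]
    p_dur, pq = float(ival["P_dur"]), float(ival["PQ_dur"])
    out["Macruz index P/(PQ-P)"] = _safe_ratio(p_dur, pq - p_dur, "Macruz")
    if rr_mean_s is not None:
        out["QTcF duration (sec)"] = _safe_ratio(
            float(ival["QT_dur"]), float(rr_mean_s) ** (1.0 / 3.0), "QTcF")
    return pd.Series(out)
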