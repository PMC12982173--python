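"""Median-beat wave delineation and amplitude/time/area measurement.

A median beat is built per lead from windows centred on the detected R peaks.
Wave onsets/offsets are located by scanning outward from each wave peak until
the baseline-relative excursion falls below 5% of the wave's peak excursion
(or the excursion changes sign, which handles overlap between adjacent
waves).  Baseline is the median of the PQ segment of the median beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cardiopsych.core import ECGRecord
from cardiopsych.errors import DelineationError, MeasurementError

WAVES = ("P", "Q", "R", "S", "T")
THRESHOLD_FRACTION = 0.05

#: Q/S search span (s) adjacent to the detected R onset/offset, and the gap
#: separating the P window from QRS and the T window from QRS
_QS_SPAN = 0.08
_T_GAP = 0.06


@dataclass
class FiducialSet:
    """Delineation result: R peaks plus per-lead median-beat wave marks.

    ``marks[lead][wave]`` is ``(onset_s, peak_s, offset_s)`` relative to the
    R peak, or None when the wave is absent.  ``j_point_s`` is the QRS offset.
    """

    rpeaks: np.ndarray
    sampling_rate: float
    beat_time: np.ndarray                 # relative time grid of the median beat
    median_beats: dict                    # lead -> median beat samples (uV)
    marks: dict                           # lead -> wave -> (onset, peak, offset) s
    baseline: dict                        # lead -> baseline level (uV)
    qrs_onset_s: dict
    qrs_offset_s: dict
    j_point_s: dict

    @property
    def leads(self) -> tuple:
        return tuple(self.median_beats)

    def per_beat_frame(self, lead: str) -> pd.DataFrame:
        """Project median-beat marks onto every beat (sample indices)."""
        fs = self.sampling_rate
        rows = []
        for b, r in enumerate(self.rpeaks):
            for w in WAVES:
                mk = self.marks[lead].get(w)
                if mk is None:
                    continue
                on, pk, off = mk
                rows.append({"beat": b, "wave": w,
                             "onset": int(round(r + on * fs)),
                             "peak": int(round(r + pk * fs)),
                             "offset": int(round(r + off * fs))})
        return pd.DataFrame(rows)


def _median_beat(sig: np.ndarray, rpeaks: np.ndarray, fs: float,
                 pre_s: float, post_s: float) -> tuple[np.ndarray, np.ndarray]:
    pre, post = int(pre_s * fs), int(post_s * fs)
    windows = [sig[r - pre:r + post] for r in rpeaks
               if r - pre >= 0 and r + post <= len(sig)]
    if not windows:
        raise DelineationError("no beat fits entirely inside the record")
    mb = np.median(np.vstack(windows), axis=0)
    t = (np.arange(mb.size) - pre) / fs
    return t, mb


def _scan_bounds(mb: np.ndarray, peak_idx: int, base: float) -> tuple[int, int]:
    """Scan outward from peak until <5% excursion or sign flip."""
    exc = mb[peak_idx] - base
    thr = THRESHOLD_FRACTION * abs(exc)
    sign = np.sign(exc)
    on = peak_idx
    while on > 0:
        d = mb[on - 1] - base
        if abs(d) < thr or np.sign(d) != sign:
            break
        on -= 1
    off = peak_idx
    last = mb.size - 1
    while off < last:
        d = mb[off + 1] - base
        if abs(d) < thr or np.sign(d) != sign:
            break
        off += 1
    return on, off


def _window_indices(t: np.ndarray, lo: float | None, hi: float | None) -> np.ndarray:
    mask = np.ones(t.size, dtype=bool)
    if lo is not None:
        mask &= t >= lo
    if hi is not None:
        mask &= t <= hi
    return np.flatnonzero(mask)


def delineate(record: ECGRecord, rpeaks: np.ndarray) -> FiducialSet:
    """Delineate P/Q/R/S/T on the median beat of every lead."""
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size < 2:
        raise DelineationError("need at least 2 beats to delineate")
    fs = record.sampling_rate
    med_rr = float(np.median(np.diff(rpeaks))) / fs
    pre_s = min(0.40, 0.45 * med_rr)
    post_s = min(0.60, 0.55 * med_rr)

    median_beats, marks, baselines = {}, {}, {}
    qrs_on, qrs_off, j_point = {}, {}, {}
    beat_time = None
    for lead in record.lead_names:
        t, mb = _median_beat(record.lead(lead), rpeaks, fs, pre_s, post_s)
        beat_time = t
        b0 = float(np.median(mb))
        r_exc_floor = None

        lead_marks: dict = {}
        # R: largest excursion near the window centre (sign-free: the R wave
        # points down on aVR)
        ridx = _window_indices(t, -0.05, 0.05)
        r_peak = ridx[np.argmax(np.abs(mb[ridx] - b0))]
        r_on, r_off = _scan_bounds(mb, r_peak, b0)
        lead_marks["R"] = (t[r_on], t[r_peak], t[r_off])
        r_exc_floor = max(2.0, 0.01 * abs(mb[r_peak] - b0))

        # Q/S flank the detected R extent; P and T sit clear of the QRS
        windows = {
            "Q": (t[r_on] - _QS_SPAN, t[r_on] - 1.0 / fs),
            "S": (t[r_off] + 1.0 / fs, t[r_off] + _QS_SPAN),
            "P": (None, t[r_on] - _QS_SPAN),
            "T": (t[r_off] + _T_GAP, None),
        }
        # a peak sitting on the window edge facing the QRS is residual R
        # flank (e.g. an absent Q), not a wave
        qrs_edge = {"Q": -1, "S": 0, "P": -1, "T": 0}
        for wave in ("P", "Q", "S", "T"):
            lo, hi = windows[wave]
            idx = _window_indices(t, lo, hi)
            if idx.size == 0:
                lead_marks[wave] = None
                continue
            peak = idx[np.argmax(np.abs(mb[idx] - b0))]
            if peak == idx[qrs_edge[wave]]:
                lead_marks[wave] = None
                continue
            if abs(mb[peak] - b0) < r_exc_floor:
                lead_marks[wave] = None
                continue
            on, off = _scan_bounds(mb, peak, b0)
            lead_marks[wave] = (t[on], t[peak], t[off])

        onset = lead_marks["Q"][0] if lead_marks["Q"] else lead_marks["R"][0]
        offset = lead_marks["S"][2] if lead_marks["S"] else lead_marks["R"][2]
        qrs_on[lead], qrs_off[lead], j_point[lead] = onset, offset, offset

        # baseline from the PQ segment (P offset -> QRS onset), else global median
        base = b0
        if lead_marks["P"] is not None:
            seg = _window_indices(t, lead_marks["P"][2], onset)
            if seg.size >= 3:
                base = float(np.median(mb[seg]))
        median_beats[lead] = mb
        marks[lead] = lead_marks
        baselines[lead] = base

    return FiducialSet(rpeaks=rpeaks, sampling_rate=fs, beat_time=beat_time,
                       median_beats=median_beats, marks=marks,
                       baseline=baselines, qrs_onset_s=qrs_on,
                       qrs_offset_s=qrs_off, j_point_s=j_point)


def measure_waves(record: ECGRecord, fiducials: FiducialSet) -> pd.DataFrame:
    """Per-lead amplitude (uV), duration (s), area (uV*s) and J-point table.

    Amplitudes are signed and baseline-relative; absent waves report
    amplitude 0 and duration 0.  Areas are trapezoidal integrals of
    |signal - baseline| over the wave span.
    """
    rows = {}
    t = fiducials.beat_time
    for lead in record.lead_names:
        if lead not in fiducials.median_beats:
            raise MeasurementError(
                f"lead {lead!r} missing from fiducials; available: "
                f"{list(fiducials.median_beats)}")
        mb = fiducials.median_beats[lead]
        base = fiducials.baseline[lead]
        mk = fiducials.marks[lead]
        row = {}
        for w in WAVES:
            if mk.get(w) is None:
                row[f"{w}_amp"] = 0.0
                row[f"{w}_dur"] = 0.0
                continue
            on, pk, off = mk[w]
            pk_idx = int(np.argmin(np.abs(t - pk)))
            row[f"{w}_amp"] = float(mb[pk_idx] - base)
            row[f"{w}_dur"] = float(off - on)

        qon, qoff = fiducials.qrs_onset_s[lead], fiducials.qrs_offset_s[lead]
        row["QRS_dur"] = float(qoff - qon)
        row["PQ_dur"] = float(qon - mk["P"][0]) if mk.get("P") else np.nan
        row["QT_dur"] = float(mk["T"][2] - qon) if mk.get("T") else np.nan

        def _area(lo: float, hi: float) -> float:
            seg = _window_indices(t, lo, hi)
            if seg.size < 2:
                return 0.0
            return float(np.trapezoid(np.abs(mb[seg] - base), t[seg]))

        row["P_area"] = _area(*mk["P"][::2]) if mk.get("P") else 0.0
        row["QRS_area"] = _area(qon, qoff)
        j_idx = int(np.argmin(np.abs(t - fiducials.j_point_s[lead])))
        row["J_disp"] = float(mb[j_idx] - base)
        rows[lead] = row
    return pd.DataFrame.from_dict(rows, orient="index")
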