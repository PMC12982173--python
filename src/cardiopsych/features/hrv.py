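"""Heart-rate-variability metrics: time domain, frequency domain, DFA and
psycho-emotional indices (Baevsky stress index, Mashin index, McCraty-style
coherence ratio).

Conventions (fixed and tested):

* SDNN and SDSD use the population SD (ddof=0).
* pNN50 counts successive differences strictly greater than 50 ms.
* LF band [0.04, 0.15) Hz, HF band [0.15, 0.40] Hz, on a cubic-interpolated
  4 Hz tachogram, linearly detrended, Welch with 64 s Hann segments and 50%
  overlap.
* Baevsky histogram bins are 50 ms wide and centred on multiples of 50 ms.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
from scipy import interpolate, signal as sps

from cardiopsych.core import RRSeries
from cardiopsych.errors import InsufficientDataError

log = logging.getLogger(__name__)

RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 64.0
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.0033, 0.40)
COHERENCE_PEAK_RANGE = (0.04, 0.26)
COHERENCE_HALF_WINDOW = 0.015


def _as_ms(rr) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.intervals_ms
    return np.asarray(rr, dtype=float)


def hrv_time(rr) -> dict:
    """SDNN, RMSSD, SDSD (ms) and pNN50 (%)."""
    x = _as_ms(rr)
    if x.size < 3:
        raise InsufficientDataError("time-domain HRV needs >= 3 intervals")
    d = np.diff(x)
    return {
        "sdnn": float(np.std(x)),
        "rmssd": float(np.sqrt(np.mean(d ** 2))),
        "sdsd": float(np.std(d)),
        "pnn50": float(100.0 * np.count_nonzero(np.abs(d) > 50.0) / d.size),
    }


def _interpolated_psd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.cumsum(x) / 1000.0
    duration = t[-1] - t[0]
    if duration < WELCH_SEGMENT_S:
        raise InsufficientDataError(
            f"series spans {duration:.1f} s, shorter than one "
            f"{WELCH_SEGMENT_S:.0f} s Welch segment")
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    tach = interpolate.CubicSpline(t, x)(grid)
    tach = sps.detrend(tach, type="linear")
    nperseg = int(WELCH_SEGMENT_S * RESAMPLE_HZ)
    freqs, psd = sps.welch(tach, fs=RESAMPLE_HZ, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2)
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray,
                lo: float, hi: float, closed_hi: bool = True) -> float:
    # rectangle rule (sum * bin width): keeps single-bin bands meaningful and
    # preserves total power (Parseval) unlike the trapezoid rule
    mask = (freqs >= lo) & ((freqs <= hi) if closed_hi else (freqs < hi))
    if not mask.any():
        return 0.0
    df = float(freqs[1] - freqs[0])
    return float(np.sum(psd[mask]) * df)


def hrv_freq(rr) -> dict:
    """LF and HF power (ms^2), LF/HF ratio and the coherence ratio."""
    x = _as_ms(rr)
    if x.size < 64:
        raise InsufficientDataError("frequency-domain HRV needs >= 64 intervals")
    freqs, psd = _interpolated_psd(x)
    lf = _band_power(freqs, psd, *LF_BAND, closed_hi=False)
    hf = _band_power(freqs, psd, *HF_BAND, closed_hi=True)
    lf_hf = lf / hf if hf > 0 else np.nan

    peak_mask = (freqs >= COHERENCE_PEAK_RANGE[0]) & (freqs <= COHERENCE_PEAK_RANGE[1])
    coherence = np.nan
    if peak_mask.any():
        sub = np.flatnonzero(peak_mask)
        fpeak = freqs[sub[np.argmax(psd[sub])]]
        lo = max(fpeak - COHERENCE_HALF_WINDOW, TOTAL_BAND[0])
        hi = min(fpeak + COHERENCE_HALF_WINDOW, TOTAL_BAND[1])
        peak_power = _band_power(freqs, psd, lo, hi)
        total = _band_power(freqs, psd, *TOTAL_BAND)
        rest = total - peak_power
        if rest > 0:
            coherence = peak_power / rest
        elif total > 0:
            coherence = np.inf
    return {"lf": lf, "hf": hf, "lf_hf": lf_hf, "coherence_ratio": coherence}


def hrv_dfa(rr, box_sizes: tuple[int, int] = (4, 16)) -> float:
    """Short-term DFA scaling exponent alpha1 (boxes of 4..16 beats)."""
    x = _as_ms(rr)
    if x.size < 100:
        raise InsufficientDataError("DFA needs >= 100 intervals")
    y = np.cumsum(x - x.mean())
    sizes = np.arange(box_sizes[0], box_sizes[1] + 1)
    fluct = np.empty(sizes.size)
    for k, s in enumerate(sizes):
        nb = y.size // s
        boxes = y[:nb * s].reshape(nb, s)
        t = np.arange(s) - (s - 1) / 2.0
        slope = boxes @ t / (t @ t)
        resid = boxes - boxes.mean(axis=1, keepdims=True) - slope[:, None] * t
        fluct[k] = np.sqrt(np.mean(resid ** 2))
    alpha, _ = np.polyfit(np.log(sizes), np.log(fluct), 1)
    return float(alpha)


BAEVSKY_BIN_MS = 50.0


def _lag1_autocorr_detrended(x: np.ndarray) -> float:
    z = sps.detrend(x, type="linear")
    a, b = z[:-1], z[1:]
    denom = np.std(a) * np.std(b)
    if denom == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / denom)


def psycho_indices(rr, mashin_fn: Callable[[np.ndarray], float] | None = None) -> dict:
    """Baevsky stress index, Mashin index and a McCraty-style coherence score.

    ``mashin_fn`` swaps in an alternative Mashin-index formula; the default is
    the lag-1 autocorrelation of the linearly detrended RR series.

    Histogram bins for the stress index are 50 ms wide, centred on multiples
    of 50 ms (e.g. 775-825 ms), so the modal bin centre (Mo) is a multiple of
    50 ms.  A zero RR range makes the stress index undefined (missing).
    """
    x = _as_ms(rr)
    if x.size < 2:
        raise InsufficientDataError("psycho-emotional indices need >= 2 intervals")

    bin_idx = np.floor((x + BAEVSKY_BIN_MS / 2.0) / BAEVSKY_BIN_MS).astype(int)
    idx, counts = np.unique(bin_idx, return_counts=True)
    modal = idx[np.argmax(counts)]
    amo = 100.0 * counts.max() / x.size                  # modal bin share, %
    mo = modal * BAEVSKY_BIN_MS / 1000.0                 # modal bin centre, s
    mxdmn = float(x.max() - x.min()) / 1000.0            # RR range, s
    if mxdmn == 0.0:
        log.warning("Baevsky SI: zero RR range, index reported missing")
        si = np.nan
    else:
        si = amo / (2.0 * mo * mxdmn)

    mashin = (mashin_fn or _lag1_autocorr_detrended)(x)

    try:
        mccraty = hrv_freq(x)["coherence_ratio"]
    except InsufficientDataError:
        mccraty = np.nan
    return {"baevsky_si": float(si), "mashin_index": float(mashin),
            "mccraty_coherence": float(mccraty)}
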