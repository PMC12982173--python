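"""R-peak detection: band-pass + squared-derivative envelope + adaptive threshold."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from cardiopsych.core import ECGRecord
from cardiopsych.errors import DetectionError

REFRACTORY_S = 0.25
BAND_HZ = (5.0, 25.0)


def detect_r_peaks(record: ECGRecord, lead: str = "II") -> np.ndarray:
    """Detect R peaks on `lead`; returns strictly increasing sample indices.

    The threshold is a fixed fraction of the envelope maximum, so detection
    is invariant to uniform amplitude rescaling.
    """
    sig = record.lead(lead)
    fs = record.sampling_rate
    if record.duration_s < 2.0:
        raise DetectionError(f"lead {lead}: record shorter than 2 s")
    if np.ptp(sig) == 0:
        raise DetectionError(f"lead {lead}: flat signal, no peaks detectable")

    nyq = fs / 2.0
    b, a = sps.butter(3, [BAND_HZ[0] / nyq, BAND_HZ[1] / nyq], btype="band")
    band = sps.filtfilt(b, a, sig)
    env = np.gradient(band) ** 2
    win = max(int(0.15 * fs), 1)
    env = np.convolve(env, np.ones(win) / win, mode="same")
    if env.max() <= 0:
        raise DetectionError(f"lead {lead}: empty envelope")

    height = 0.2 * env.max()
    distance = max(int(REFRACTORY_S * fs), 1)
    raw_peaks, _ = sps.find_peaks(env, height=height, distance=distance)
    if raw_peaks.size == 0:
        raise DetectionError(f"lead {lead}: no peaks above adaptive threshold")

    # refine each envelope peak to the largest baseline deviation nearby
    base = np.median(sig)
    half = int(0.10 * fs)
    refined = []
    for p in raw_peaks:
        lo, hi = max(0, p - half), min(len(sig), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(sig[lo:hi] - base))))
    refined = np.array(sorted(set(refined)), dtype=int)
    # enforce refractory after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= distance:
            keep.append(int(p))
    return np.array(keep, dtype=int)
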