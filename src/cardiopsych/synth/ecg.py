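"""Synthetic 6-lead limb ECG built from a sum-of-Gaussians beat template.

Leads I and II are primary; the other four follow limb-lead algebra
sample-wise:

    III = II - I,  aVR = -(I + II)/2,  aVL = I - II/2,  aVF = II - I/2

Wave amplitudes are per-lead; wave timing (centre offset from R, width) is a
single template shared by all leads, so each beat has one set of ground-truth
fiducials.  A wave's ground-truth onset/offset is where its Gaussian falls to
5% of peak amplitude, i.e. centre +/- sqrt(2*ln 20)*width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardiopsych.core import ECGRecord, LIMB_LEADS
from cardiopsych.errors import ParameterError
from cardiopsych.synth.rhythm import RhythmSpec, generate_rr_series

WAVES = ("P", "Q", "R", "S", "T")

#: half-extent of a Gaussian wave, in widths, at the 5% amplitude threshold
EXTENT = math.sqrt(2.0 * math.log(20.0))

_DEFAULT_CENTERS = {"P": -0.17, "Q": -0.045, "R": 0.0, "S": 0.045, "T": 0.30}
_DEFAULT_WIDTHS = {"P": 0.020, "Q": 0.007, "R": 0.012, "S": 0.007, "T": 0.040}
_DEFAULT_AMP_II = {"P": 150.0, "Q": -100.0, "R": 1100.0, "S": -200.0, "T": 300.0}
_DEFAULT_AMP_I = {"P": 90.0, "Q": -60.0, "R": 660.0, "S": -120.0, "T": 180.0}


@dataclass(frozen=True)
class BeatSpec:
    """Analytic beat template: Gaussian waves on leads I and II."""

    centers_s: dict = field(default_factory=lambda: dict(_DEFAULT_CENTERS))
    widths_s: dict = field(default_factory=lambda: dict(_DEFAULT_WIDTHS))
    amplitudes_uv: dict = field(default_factory=lambda: {
        "I": dict(_DEFAULT_AMP_I), "II": dict(_DEFAULT_AMP_II)})
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 250.0:
            raise ParameterError("sampling_rate must be at least 250 Hz")
        for w in WAVES:
            if w not in self.centers_s or w not in self.widths_s:
                raise ParameterError(f"missing timing for wave {w}")
            if not self.widths_s[w] > 0:
                raise ParameterError(f"width of wave {w} must be positive")
        for lead in ("I", "II"):
            if lead not in self.amplitudes_uv:
                raise ParameterError(f"missing amplitudes for lead {lead}")
        order = [self.centers_s[w] for w in WAVES]
        if sorted(order) != order:
            raise ParameterError("wave centres must be ordered P < Q < R < S < T")
        if not self.pq_s < self.qt_s:
            raise ParameterError("PQ must be shorter than QT")

    # --- amplitude helpers -------------------------------------------------
    def amplitude(self, lead: str, wave: str) -> float:
        return float(self.amplitudes_uv[lead].get(wave, 0.0))

    def _present(self, wave: str) -> bool:
        return any(abs(self.amplitude(lead, wave)) > 0 for lead in ("I", "II"))

    # --- ground-truth geometry (seconds relative to the R centre) ----------
    def wave_onset_s(self, wave: str) -> float:
        return self.centers_s[wave] - EXTENT * self.widths_s[wave]

    def wave_offset_s(self, wave: str) -> float:
        return self.centers_s[wave] + EXTENT * self.widths_s[wave]

    @property
    def qrs_onset_s(self) -> float:
        first = "Q" if self._present("Q") else "R"
        return self.wave_onset_s(first)

    @property
    def qrs_offset_s(self) -> float:
        last = "S" if self._present("S") else "R"
        return self.wave_offset_s(last)

    @property
    def pq_s(self) -> float:
        """P onset to QRS onset."""
        return self.qrs_onset_s - self.wave_onset_s("P")

    @property
    def qt_s(self) -> float:
        """QRS onset to T offset."""
        return self.wave_offset_s("T") - self.qrs_onset_s

    @property
    def qrs_s(self) -> float:
        return self.qrs_offset_s - self.qrs_onset_s

    def template(self, lead: str, t: np.ndarray) -> np.ndarray:
        """Evaluate the analytic beat template for `lead` at times `t` (s, R at 0)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for w in WAVES:
            a = self.amplitude(lead, w)
            if a == 0.0:
                continue
            c, s = self.centers_s[w], self.widths_s[w]
            out += a * np.exp(-0.5 * ((t - c) / s) ** 2)
        return out


@dataclass(frozen=True)
class TrueFiducials:
    """Ground-truth marks for one generated beat, in samples."""

    beat: int
    r_sample: int
    waves: dict  # wave -> (onset, peak, offset) sample indices
    j_sample: int


def _derive_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> np.ndarray:
    iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return np.column_stack([lead_i, lead_ii, iii, avr, avl, avf])


def generate_ecg_record(beat: BeatSpec, rhythm: RhythmSpec,
                        noise_uv: float = 0.0,
                        ) -> tuple[ECGRecord, list[TrueFiducials]]:
    """Render a 6-lead record from a beat template and a rhythm spec.

    Optional additive white noise (`noise_uv`, SD in microvolts, drawn from
    the rhythm seed) is applied to leads I and II before lead derivation.
    Returns the record and the per-beat ground-truth fiducials.
    """
    fs = beat.sampling_rate
    min_span = min(2.0 * EXTENT * beat.widths_s[w]
                   for w in WAVES if beat._present(w))
    if fs * min_span < 5.0:
        raise ParameterError(
            f"sampling_rate {fs} Hz gives fewer than 5 samples across the "
            f"narrowest wave ({min_span * 1e3:.1f} ms)")

    rr = generate_rr_series(rhythm)
    pre = 0.5 - beat.wave_onset_s("P")  # margin so the first P is fully inside
    r_times = pre + np.concatenate([[0.0], np.cumsum(rr.intervals_ms[:-1])]) / 1000.0
    duration = r_times[-1] + beat.wave_offset_s("T") + 0.5
    n = int(math.ceil(duration * fs))
    t = np.arange(n) / fs

    lead_i = np.zeros(n)
    lead_ii = np.zeros(n)
    half_span = max(abs(beat.wave_onset_s("P")), beat.wave_offset_s("T")) + 0.1
    for rt in r_times:
        lo = max(0, int((rt - half_span) * fs))
        hi = min(n, int((rt + half_span) * fs) + 1)
        rel = t[lo:hi] - rt
        lead_i[lo:hi] += beat.template("I", rel)
        lead_ii[lo:hi] += beat.template("II", rel)

    if noise_uv > 0:
        nrng = np.random.default_rng(np.random.SeedSequence(
            entropy=rhythm.seed, spawn_key=(0xECC,)))
        lead_i = lead_i + nrng.normal(0.0, noise_uv, n)
        lead_ii = lead_ii + nrng.normal(0.0, noise_uv, n)

    record = ECGRecord(_derive_leads(lead_i, lead_ii), fs, LIMB_LEADS)

    fiducials = []
    for b, rt in enumerate(r_times):
        marks = {}
        for w in WAVES:
            marks[w] = (int(round((rt + beat.wave_onset_s(w)) * fs)),
                        int(round((rt + beat.centers_s[w]) * fs)),
                        int(round((rt + beat.wave_offset_s(w)) * fs)))
        fiducials.append(TrueFiducials(
            beat=b,
            r_sample=int(round(rt * fs)),
            waves=marks,
            j_sample=int(round((rt + beat.qrs_offset_s) * fs))))
    return record, fiducials


def fiducials_to_frame(fiducials: list[TrueFiducials]) -> pd.DataFrame:
    """Flatten fiducials to a (beat, wave, onset, peak, offset) table."""
    rows = []
    for f in fiducials:
        for w, (on, pk, off) in f.waves.items():
            rows.append({"beat": f.beat, "wave": w,
                         "onset": on, "peak": pk, "offset": off})
    return pd.DataFrame(rows)
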