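"""Sinus-rhythm RR interval generator.

The tachogram is a constant mean plus two sinusoidal modulations — a 0.1 Hz
("low frequency") and a 0.25 Hz ("high frequency") component — plus white
Gaussian noise:

    RR_k = mean_rr + lf_amp * sin(2*pi*0.1*t_k) + hf_amp * sin(2*pi*0.25*t_k) + eps_k

with ``t_k`` the cumulative time of beat k and ``eps_k ~ N(0, noise_sd)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardiopsych.core import RRSeries
from cardiopsych.errors import ParameterError

LF_HZ = 0.1
HF_HZ = 0.25


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of the synthetic rhythm.

    ``sd_rr`` is an alias for the white-noise SD: it is used only when
    ``noise_sd`` is left as None.
    """

    mean_rr: float = 1000.0
    sd_rr: float = 0.0
    lf_amp: float = 0.0
    hf_amp: float = 0.0
    noise_sd: float | None = None
    n_beats: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rr > 200.0:
            raise ParameterError("mean_rr must exceed 200 ms")
        if self.n_beats < 2:
            raise ParameterError("n_beats must be at least 2")
        eff = self.effective_noise_sd
        for name, val in (("sd_rr", self.sd_rr), ("lf_amp", self.lf_amp),
                          ("hf_amp", self.hf_amp), ("noise_sd", eff)):
            if val < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def effective_noise_sd(self) -> float:
        return self.sd_rr if self.noise_sd is None else self.noise_sd


def generate_rr_series(spec: RhythmSpec) -> RRSeries:
    """Generate ``spec.n_beats`` RR intervals (ms), deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    noise_sd = spec.effective_noise_sd
    rr = np.empty(spec.n_beats)
    t = 0.0  # cumulative time, seconds
    for k in range(spec.n_beats):
        val = (spec.mean_rr
               + spec.lf_amp * np.sin(2 * np.pi * LF_HZ * t)
               + spec.hf_amp * np.sin(2 * np.pi * HF_HZ * t))
        if noise_sd > 0:
            val += rng.normal(0.0, noise_sd)
        rr[k] = val
        t += val / 1000.0
    return RRSeries(rr)
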