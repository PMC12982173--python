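"""Core signal containers and their plain-text (CSV) serialisation.

Signals travel as a CSV dialect: first column ``time_s``, one column per
lead (header = lead name), amplitudes in microvolts.  RR series travel as a
single-column CSV in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cardiopsych.errors import ParameterError

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")

#: display spelling used in published feature labels ("lead AvR" etc.)
LEAD_DISPLAY = {"I": "I", "II": "II", "III": "III",
                "aVR": "AvR", "aVL": "AvL", "aVF": "AvF"}


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat RR intervals in milliseconds."""

    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals_ms, dtype=float)
        if arr.ndim != 1:
            raise ParameterError("RR series must be one-dimensional")
        if arr.size < 1:
            raise ParameterError("RR series must contain at least one interval")
        object.__setattr__(self, "intervals_ms", arr)

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def times_s(self) -> np.ndarray:
        """Cumulative beat times in seconds (time of beat k = sum of RR_1..RR_k)."""
        return np.cumsum(self.intervals_ms) / 1000.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"rr_ms": self.intervals_ms}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RRSeries":
        df = pd.read_csv(path)
        col = "rr_ms" if "rr_ms" in df.columns else df.columns[0]
        return cls(df[col].to_numpy(dtype=float))


@dataclass(frozen=True)
class ECGRecord:
    """Multi-lead ECG: ``samples[t, lead]`` in microvolts at ``sampling_rate`` Hz."""

    samples: np.ndarray
    sampling_rate: float
    lead_names: tuple = field(default=LIMB_LEADS)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ParameterError("samples must be a (time, lead) matrix")
        names = tuple(self.lead_names)
        if len(names) < 1:
            raise ParameterError("at least one lead is required")
        if arr.shape[1] != len(names):
            raise ParameterError(
                f"{arr.shape[1]} signal columns but {len(names)} lead names")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "lead_names", names)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        from cardiopsych.errors import MeasurementError
        if name not in self.lead_names:
            raise MeasurementError(
                f"lead {name!r} not in record; available: {list(self.lead_names)}")
        return self.samples[:, self.lead_names.index(name)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.samples, columns=list(self.lead_names))
        df.insert(0, "time_s", self.time_s)
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ECGRecord":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ParameterError(f"{path}: missing 'time_s' column")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ParameterError(f"{path}: need at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        leads = [c for c in df.columns if c != "time_s"]
        return cls(df[leads].to_numpy(dtype=float), fs, tuple(leads))
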