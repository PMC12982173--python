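"""Norm-anchored piecewise-linear scaling of raw parameters to 0-100 points.

A parameter value at the normal-range mean M maps to ``points_at_mean``
(default 100), at one SD from M to ``points_at_norm_boundary`` (default 75),
and at the side-specific extreme pathology bound to ``points_at_extreme``
(default 0), with linear interpolation between anchors and clamping beyond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from cardiopsych.errors import ParameterError, StructuralError

NORM_COLUMNS = ("parameter", "M", "sigma", "extreme_low", "extreme_high",
                "level2_group", "level3_block", "source")


@dataclass(frozen=True)
class NormRange:
    """Normal-range anchors for one parameter, in the parameter's own units."""

    parameter: str
    m: float
    sigma: float
    extreme_low: float
    extreme_high: float
    source: str = "literature"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"{self.parameter}: sigma must be positive")
        if not self.extreme_low < self.m - self.sigma:
            raise ParameterError(
                f"{self.parameter}: extreme_low must lie below M - sigma")
        if not self.extreme_high > self.m + self.sigma:
            raise ParameterError(
                f"{self.parameter}: extreme_high must lie above M + sigma")


@dataclass(frozen=True)
class ScaleAnchors:
    points_at_mean: float = 100.0
    points_at_norm_boundary: float = 75.0
    points_at_extreme: float = 0.0

    def __post_init__(self) -> None:
        ok = (100.0 >= self.points_at_mean > self.points_at_norm_boundary
              > self.points_at_extreme >= 0.0)
        if not ok:
            raise ParameterError(
                "anchors must satisfy 100 >= mean > boundary > extreme >= 0")


DEFAULT_ANCHORS = ScaleAnchors()


def scale_parameter(value: float, norm: NormRange,
                    anchors: ScaleAnchors = DEFAULT_ANCHORS) -> float:
    """Map a raw value onto the point scale; missing in -> missing out."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    v = float(value)
    d = abs(v - norm.m) / norm.sigma
    pm, pb, pe = (anchors.points_at_mean, anchors.points_at_norm_boundary,
                  anchors.points_at_extreme)
    if d <= 1.0:
        pts = pm - (pm - pb) * d
    else:
        extreme = norm.extreme_high if v >= norm.m else norm.extreme_low
        d_extreme = abs(extreme - norm.m) / norm.sigma
        pts = pb - (pb - pe) * (d - 1.0) / (d_extreme - 1.0)
    return float(min(max(pts, pe), pm))


# --- norm table I/O ---------------------------------------------------------

def _default_table_path():
    return resources.files("cardiopsych.scoring").joinpath("data/norm_ranges.csv")


def load_norm_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a norm-range CSV (bundled defaults when `path` is None)."""
    src = _default_table_path() if path is None else Path(path)
    with (src.open("rb") if hasattr(src, "open") else open(src, "rb")) as fh:
        df = pd.read_csv(fh)
    missing = [c for c in NORM_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(f"norm table missing columns: {missing}")
    return df


def norm_table_violations(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Row-wise invariant check; returns (row number, message) per violation."""
    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            NormRange(str(row["parameter"]), float(row["M"]), float(row["sigma"]),
                      float(row["extreme_low"]), float(row["extreme_high"]),
                      str(row["source"]))
        except (ParameterError, ValueError) as exc:
            problems.append((int(i) + 2, str(exc)))  # +2: header + 1-based
    return problems


def norms_from_table(df: pd.DataFrame) -> dict[str, NormRange]:
    out: dict[str, NormRange] = {}
    for _, row in df.iterrows():
        nr = NormRange(str(row["parameter"]), float(row["M"]), float(row["sigma"]),
                       float(row["extreme_low"]), float(row["extreme_high"]),
                       str(row["source"]))
        out[nr.parameter] = nr
    return out


def norms_from_cohort(features: pd.DataFrame,
                      hierarchy_columns: pd.DataFrame | None = None,
                      extreme_sigmas: float = 4.0) -> pd.DataFrame:
    """Regenerate a norm table from a (synthetic) normative cohort.

    M and sigma are the column mean and SD; extremes are placed
    ``extreme_sigmas`` SDs from M.  Source tag: "normative-database".
    """
    if extreme_sigmas <= 1.0:
        raise ParameterError("extreme_sigmas must exceed 1")
    rows = []
    for col in features.columns:
        vals = features[col].dropna().to_numpy(dtype=float)
        if vals.size < 2 or np.std(vals) == 0:
            continue
        m, s = float(np.mean(vals)), float(np.std(vals, ddof=1))
        group = block = ""
        if hierarchy_columns is not None and col in hierarchy_columns.index:
            group = hierarchy_columns.loc[col, "level2_group"]
            block = hierarchy_columns.loc[col, "level3_block"]
        rows.append({"parameter": col, "M": m, "sigma": s,
                     "extreme_low": m - extreme_sigmas * s,
                     "extreme_high": m + extreme_sigmas * s,
                     "level2_group": group, "level3_block": block,
                     "source": "normative-database"})
    return pd.DataFrame(rows, columns=list(NORM_COLUMNS))
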