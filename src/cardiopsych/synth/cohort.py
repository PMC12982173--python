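"""Synthetic cohort tables with planted signal, collinearity, outliers and gaps.

Features are standard Gaussian; each target is a linear combination of its
informative features plus Gaussian noise, so the population R-squared is known
in closed form:  R2_true = Var(X beta) / (Var(X beta) + noise_sd^2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cardiopsych.errors import ParameterError

TARGETS = ("pcl5", "phq9", "beck", "conclusion")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic subjects-by-features cohort."""

    n_subjects: int = 90
    n_features: int = 120
    #: target name -> tuple of (feature index, beta)
    informative: dict = field(default_factory=dict)
    #: target name -> noise SD (defaults to 1.0 per target)
    noise_sd: dict = field(default_factory=dict)
    #: tuple of (i, j, rho): column j is rebuilt as rho*col_i + sqrt(1-rho^2)*z
    collinear_pairs: tuple = ()
    outlier_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_features < 1:
            raise ParameterError("cohort needs >= 2 subjects and >= 1 feature")
        for frac, name in ((self.outlier_fraction, "outlier_fraction"),
                           (self.missing_fraction, "missing_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        for target, terms in self.informative.items():
            if target not in TARGETS:
                raise ParameterError(f"unknown target {target!r}; use {TARGETS}")
            for idx, beta in terms:
                if not 0 <= idx < self.n_features:
                    raise ParameterError(f"informative index {idx} out of range")
                if not math.isfinite(beta):
                    raise ParameterError("betas must be finite")
        derived = set()
        members = set()
        for i, j, rho in self.collinear_pairs:
            if i == j:
                raise ParameterError("collinear pair must use two distinct columns")
            if not (0 <= i < self.n_features and 0 <= j < self.n_features):
                raise ParameterError("collinear pair index out of range")
            if not abs(rho) < 1.0:
                raise ParameterError("|rho| must be < 1")
            if j in members or i in derived:
                raise ParameterError(
                    f"collinear pair ({i}, {j}) overlaps another pair "
                    "inconsistently (chained or duplicated construction)")
            derived.add(j)
            members.update((i, j))

    def noise_for(self, target: str) -> float:
        return float(self.noise_sd.get(target, 1.0))


@dataclass(frozen=True)
class GroundTruth:
    """Everything planted in the cohort, for downstream verification."""

    r2_true: dict            # target -> population R^2
    informative: dict        # target -> tuple of (index, beta)
    collinear_pairs: tuple
    outlier_rows: tuple
    missing_mask: np.ndarray
    conclusion_cuts: tuple   # quartile cut points of the latent 4th target
    latent_conclusion: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "r2_true": self.r2_true,
            "informative": {k: [list(t) for t in v]
                            for k, v in self.informative.items()},
            "collinear_pairs": [list(p) for p in self.collinear_pairs],
            "outlier_rows": list(self.outlier_rows),
            "n_missing_cells": int(self.missing_mask.sum()),
            "conclusion_cuts": list(self.conclusion_cuts),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _population_r2(spec: CohortSpec, target: str) -> float:
    terms = spec.informative.get(target, ())
    if not terms:
        return 0.0
    p = spec.n_features
    sigma = np.eye(p)
    for i, j, rho in spec.collinear_pairs:
        sigma[i, j] = sigma[j, i] = rho
    beta = np.zeros(p)
    for idx, b in terms:
        beta[idx] += b
    var_signal = float(beta @ sigma @ beta)
    if var_signal == 0.0:
        return 0.0
    noise_var = spec.noise_for(target) ** 2
    return var_signal / (var_signal + noise_var)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (features, targets, ground truth); deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_features

    x = rng.standard_normal((n, p))
    for i, j, rho in spec.collinear_pairs:
        x[:, j] = rho * x[:, i] + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)

    targets = {}
    r2_true = {}
    latent_conclusion = None
    cuts: tuple = ()
    for target in TARGETS:
        terms = spec.informative.get(target, ())
        signal = np.zeros(n)
        for idx, beta in terms:
            signal = signal + beta * x[:, idx]
        noise = spec.noise_for(target)
        y = signal + (rng.normal(0.0, noise, n) if noise > 0 else 0.0)
        r2_true[target] = _population_r2(spec, target)
        if target == "conclusion":
            latent_conclusion = y.copy()
            qs = np.quantile(y, [0.25, 0.5, 0.75])
            cuts = tuple(float(q) for q in qs)
            y = 1.0 + np.searchsorted(qs, y, side="right").astype(float)
        targets[target] = y

    # gross outliers: shift >= 6 SD on >= 10% of the columns of the chosen rows
    n_out = int(round(spec.outlier_fraction * n))
    outlier_rows: tuple = ()
    if n_out > 0:
        rows = np.sort(rng.choice(n, size=n_out, replace=False))
        n_cols = max(int(math.ceil(0.15 * p)), 1)
        for r in rows:
            cols = rng.choice(p, size=n_cols, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_cols)
            x[r, cols] += 8.0 * signs
        outlier_rows = tuple(int(r) for r in rows)

    missing_mask = np.zeros((n, p), dtype=bool)
    if spec.missing_fraction > 0:
        missing_mask = rng.random((n, p)) < spec.missing_fraction
        x = x.copy()
        x[missing_mask] = np.nan

    subject_ids = [f"S{k + 1:03d}" for k in range(n)]
    feature_names = [f"feat_{k:03d}" for k in range(p)]
    features = pd.DataFrame(x, index=pd.Index(subject_ids, name="subject"),
                            columns=feature_names)
    target_df = pd.DataFrame(targets, index=features.index)

    truth = GroundTruth(
        r2_true=r2_true,
        informative={k: tuple((int(i), float(b)) for i, b in v)
                     for k, v in spec.informative.items()},
        collinear_pairs=tuple(tuple(pair) for pair in spec.collinear_pairs),
        outlier_rows=outlier_rows,
        missing_mask=missing_mask,
        conclusion_cuts=cuts,
        latent_conclusion=latent_conclusion,
    )
    return features, target_df, truth
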