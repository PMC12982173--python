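"""Correlation screening of features against psychological targets.

Pearson and Spearman coefficients with two-sided p-values (t distribution
with n-2 df), pairwise-complete deletion per feature-target pair, results
sorted by p, and tiered significance summaries.  Tiers are exclusive bins by
default (a p = 0.005 feature counts under "p < 0.01" only); cumulative counts
are reported alongside.  No multiple-testing correction is applied by
default; a Benjamini-Hochberg adjusted column is available on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cardiopsych.errors import (AlignmentError, InsufficientDataError,
                                UndefinedCorrelationError)

DEFAULT_TIERS = (0.001, 0.01, 0.05, 0.1)


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    target: str
    method: str            # "pearson" | "spearman"
    coefficient: float
    p_value: float
    n_used: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _check(x: np.ndarray, y: np.ndarray, method: str) -> None:
    if x.size < 3:
        raise InsufficientDataError(
            f"{method}: need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"{method}: constant input")


def pearson_with_p(x, y, feature: str = "x", target: str = "y") -> CorrelationResult:
    """Product-moment r with a two-sided p-value; missing pairs dropped."""
    xa, ya = _pairwise_complete(x, y)
    _check(xa, ya, "pearson")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(feature, target, "pearson",
                             float(r), float(p), int(xa.size))


def spearman_with_p(x, y, feature: str = "x", target: str = "y") -> CorrelationResult:
    """Rank correlation (mid-ranks for ties) with a two-sided p-value."""
    xa, ya = _pairwise_complete(x, y)
    _check(xa, ya, "spearman")
    rho, p = stats.spearmanr(xa, ya)
    return CorrelationResult(feature, target, "spearman",
                             float(rho), float(p), int(xa.size))


_METHODS = {"pearson": pearson_with_p, "spearman": spearman_with_p}


@dataclass
class ScreenResult:
    """Sorted per-(target, method) correlation tables plus tier summaries."""

    results: dict          # (target, method) -> list[CorrelationResult], by p
    tier_exclusive: pd.DataFrame
    tier_cumulative: pd.DataFrame
    skipped: list          # (feature, target, method, reason)
    tiers: tuple

    def table(self, target: str, method: str,
              max_p: float | None = None) -> pd.DataFrame:
        """Ranked table (rank, feature, coefficient, significance)."""
        rows = [{"rank": i + 1, "feature": r.feature,
                 "coefficient": r.coefficient, "significance": r.p_value,
                 "n_used": r.n_used}
                for i, r in enumerate(self.results[(target, method)])
                if max_p is None or r.p_value < max_p]
        return pd.DataFrame(rows,
                            columns=["rank", "feature", "coefficient",
                                     "significance", "n_used"])


def _tier_counts(pvals: np.ndarray, tiers: tuple) -> tuple[list[int], list[int]]:
    cumulative = [int(np.sum(pvals < t)) for t in tiers]
    exclusive = [cumulative[0]] + [cumulative[i] - cumulative[i - 1]
                                   for i in range(1, len(tiers))]
    return exclusive, cumulative


def correlation_screen(features: pd.DataFrame, targets: pd.DataFrame,
                       tiers: tuple = DEFAULT_TIERS,
                       methods: tuple = ("pearson", "spearman"),
                       benjamini_hochberg: bool = False) -> ScreenResult:
    """Screen every feature against every target with both methods."""
    common = features.index.intersection(targets.index)
    if len(common) == 0:
        raise AlignmentError("features and targets share no subjects")
    feats = features.loc[common]
    targs = targets.loc[common]

    results: dict = {}
    skipped: list = []
    ex_rows, cu_rows = [], []
    for method in methods:
        fn = _METHODS[method]
        for target in targs.columns:
            lst = []
            for col in feats.columns:
                try:
                    lst.append(fn(feats[col], targs[target],
                                  feature=col, target=target))
                except (InsufficientDataError, UndefinedCorrelationError) as exc:
                    skipped.append((col, target, method, str(exc)))
            lst.sort(key=lambda r: (r.p_value, r.feature))
            results[(target, method)] = lst
            pvals = np.array([r.p_value for r in lst])
            ex, cu = _tier_counts(pvals, tiers)
            ex_rows.append({"method": method, "target": target,
                            **{f"p < {t:g}": c for t, c in zip(tiers, ex)}})
            cu_rows.append({"method": method, "target": target,
                            **{f"p < {t:g}": c for t, c in zip(tiers, cu)}})

    out = ScreenResult(results=results,
                       tier_exclusive=pd.DataFrame(ex_rows),
                       tier_cumulative=pd.DataFrame(cu_rows),
                       skipped=skipped, tiers=tiers)
    if benjamini_hochberg:
        for lst in out.results.values():
            _apply_bh(lst)
    return out


def _apply_bh(results: list) -> None:
    """Attach Benjamini-Hochberg adjusted p-values (off by default)."""
    m = len(results)
    order = np.argsort([r.p_value for r in results])
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, results[idx].p_value * m / rank)
        adj[idx] = prev = val
    for r, a in zip(results, adj):
        object.__setattr__(r, "p_adjusted", float(a))
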