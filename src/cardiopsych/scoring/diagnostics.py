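"""Robustness and homogeneity diagnostics for composite indices."""

from __future__ import annotations

import numpy as np
from sklearn.cluster import HDBSCAN

from cardiopsych.errors import InsufficientDataError

HUBER_C = 1.345
HUBER_TOL = 1e-8
ROBUST_DELTA_FACTOR = 0.25


def huber_location(values: np.ndarray, c: float = HUBER_C,
                   tol: float = HUBER_TOL, max_iter: int = 500) -> float:
    """Huber M-estimate of location by iterative reweighting (MAD scale)."""
    x = np.asarray(values, dtype=float)
    scale = 1.4826 * np.median(np.abs(x - np.median(x)))
    if scale == 0:
        return float(np.mean(x))
    loc = float(np.median(x))
    for _ in range(max_iter):
        u = (x - loc) / scale
        w = np.minimum(1.0, c / np.maximum(np.abs(u), 1e-300))
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - loc) < tol:
            return new
        loc = new
    return loc


def huber_robustness(index_values) -> dict:
    """Stability check of a composite index over a cohort.

    The index is flagged robust when the Huber location stays within
    0.25 robust SDs (1.4826*MAD) of the plain mean.
    """
    x = np.asarray(index_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise InsufficientDataError("Huber robustness needs >= 10 values")
    loc = huber_location(x)
    mean = float(np.mean(x))
    delta = abs(loc - mean)
    robust_sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    return {
        "robust": bool(delta <= ROBUST_DELTA_FACTOR * robust_sd),
        "huber_location": loc,
        "mean": mean,
        "delta": delta,
    }


def homogeneity_check(index_values, min_cluster_size: int = 10) -> dict:
    """Density-based clustering of 1-D index values (HDBSCAN).

    Homogeneous <=> exactly one cluster holds at least 90% of the non-noise
    points.
    """
    x = np.asarray(index_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 20:
        raise InsufficientDataError("homogeneity check needs >= 20 values")
    labels = HDBSCAN(min_cluster_size=min_cluster_size,
                     allow_single_cluster=True,
                     copy=True).fit_predict(x.reshape(-1, 1))
    clusters, counts = np.unique(labels[labels >= 0], return_counts=True)
    n_clusters = int(clusters.size)
    non_noise = int(counts.sum())
    # homogeneous <=> a single dominant cluster: >= 90% of non-noise points
    homogeneous = bool(n_clusters >= 1 and counts.max() >= 0.9 * non_noise)
    return {"n_clusters": n_clusters, "labels": labels,
            "homogeneous": homogeneous}
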