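"""Universal norm-anchored scoring: 0-100 point scale, 4-level hierarchy,
robustness and homogeneity diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cardiopsych.scoring.scale import (
    DEFAULT_ANCHORS, NORM_COLUMNS, NormRange, ScaleAnchors, load_norm_table,
    norm_table_violations, norms_from_cohort, norms_from_table, scale_parameter,
)
from cardiopsych.scoring.hierarchy import Node, ScoreHierarchy, aggregate
from cardiopsych.scoring.diagnostics import (
    homogeneity_check, huber_location, huber_robustness,
)

__all__ = [
    "NormRange", "ScaleAnchors", "DEFAULT_ANCHORS", "NORM_COLUMNS",
    "scale_parameter", "load_norm_table", "norm_table_violations",
    "norms_from_table", "norms_from_cohort",
    "Node", "ScoreHierarchy", "aggregate",
    "huber_location", "huber_robustness", "homogeneity_check",
    "score_cohort",
]

COMPOSITE_SUFFIX = " (composite index)"


def score_cohort(features: pd.DataFrame,
                 norm_table: pd.DataFrame | None = None,
                 hierarchy: ScoreHierarchy | None = None,
                 anchors: ScaleAnchors = DEFAULT_ANCHORS,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a subjects-by-parameters table through the hierarchy.

    Returns ``(scored, leaf_points)``: `scored` is the input table with one
    "<node> (composite index)" column appended per hierarchy node;
    `leaf_points` holds the per-parameter point values.
    """
    if norm_table is None:
        norm_table = load_norm_table()
    if hierarchy is None:
        hierarchy = ScoreHierarchy.from_yaml()
    norms = norms_from_table(norm_table)

    leaf_names = hierarchy.leaf_names()
    leaf_rows, node_rows = [], []
    for _, row in features.iterrows():
        pts = {}
        for leaf in leaf_names:
            if leaf in norms and leaf in features.columns:
                pts[leaf] = scale_parameter(row[leaf], norms[leaf], anchors)
            else:
                pts[leaf] = np.nan
        nodes = aggregate(hierarchy, pts)
        leaf_rows.append(pts)
        node_rows.append({name: nodes[name] for name in hierarchy.node_names()})

    leaf_points = pd.DataFrame(leaf_rows, index=features.index)
    composites = pd.DataFrame(node_rows, index=features.index)
    composites.columns = [c + COMPOSITE_SUFFIX for c in composites.columns]
    return pd.concat([features, composites], axis=1), leaf_points
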