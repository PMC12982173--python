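"""Four-level composite-score hierarchy and its averaging aggregation.

Levels: 1 = individual parameters (leaves), 2 = groups of related indicators,
3 = blocks (regulation, myocardial condition, arrhythmia, psycho-emotional
status), 4 = the root integral indicator.  Every non-leaf value is the
arithmetic mean of its non-missing children; a node is missing only when all
of its children are missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from cardiopsych.errors import StructuralError


@dataclass
class Node:
    name: str
    children: list = field(default_factory=list)   # Node for levels 3/2
    leaves: list = field(default_factory=list)     # parameter names, level-2 only


@dataclass
class ScoreHierarchy:
    root: Node

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.root.children:
            raise StructuralError("hierarchy root has no blocks")
        for block in self.root.children:
            if not block.children:
                raise StructuralError(f"block {block.name!r} has no groups")
            for group in block.children:
                if group.children:
                    raise StructuralError(
                        f"group {group.name!r} nests deeper than 4 levels")
                if not group.leaves:
                    raise StructuralError(f"group {group.name!r} has no leaves")

    def leaf_names(self) -> list[str]:
        return [leaf for block in self.root.children
                for group in block.children for leaf in group.leaves]

    def node_names(self) -> list[str]:
        names = [self.root.name]
        for block in self.root.children:
            names.append(block.name)
            names.extend(group.name for group in block.children)
        return names

    # --- YAML round trip ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ScoreHierarchy":
        """Load a hierarchy (bundled default when `path` is None)."""
        if path is None:
            src = resources.files("cardiopsych.scoring").joinpath(
                "data/hierarchy.yaml")
            text = src.read_text(encoding="utf-8")
        else:
            text = Path(path).read_text(encoding="utf-8")
        spec = yaml.safe_load(text)
        try:
            root = Node(spec["name"], children=[
                Node(b["name"], children=[
                    Node(g["name"], leaves=list(g["leaves"]))
                    for g in b["children"]])
                for b in spec["children"]])
        except (KeyError, TypeError) as exc:
            raise StructuralError(f"malformed hierarchy YAML: {exc}") from exc
        return cls(root)

    def to_yaml(self, path: str | Path) -> None:
        spec = {"name": self.root.name, "children": [
            {"name": b.name, "children": [
                {"name": g.name, "leaves": list(g.leaves)}
                for g in b.children]}
            for b in self.root.children]}
        Path(path).write_text(yaml.safe_dump(spec, sort_keys=False,
                                             allow_unicode=True))


def _mean_skip_missing(values: list[float]) -> float:
    ok = [v for v in values if not math.isnan(v)]
    return sum(ok) / len(ok) if ok else float("nan")


def aggregate(hierarchy: ScoreHierarchy,
              leaf_points: Mapping[str, float]) -> dict[str, float]:
    """Per-node composite points (leaves included) from leaf point values.

    Leaves absent from ``leaf_points`` count as missing.  Aggregation is the
    arithmetic mean of non-missing children at every level, which makes the
    result invariant to child order and idempotent on aggregated subtrees.
    """
    out: dict[str, float] = {}
    block_vals = []
    for block in hierarchy.root.children:
        group_vals = []
        for group in block.children:
            leaf_vals = []
            for leaf in group.leaves:
                v = float(leaf_points.get(leaf, float("nan")))
                out[leaf] = v
                leaf_vals.append(v)
            out[group.name] = _mean_skip_missing(leaf_vals)
            group_vals.append(out[group.name])
        out[block.name] = _mean_skip_missing(group_vals)
        block_vals.append(out[block.name])
    out[hierarchy.root.name] = _mean_skip_missing(block_vals)
    return out
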