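"""Quantitative classification rules from a fully grown decision tree.

A CART/Gini tree is fitted on all cells (original cells only — synthetic
SMOTE samples are never used here) restricted to a feature prefix and grown
until leaves are pure or unsplittable.  Each leaf becomes one conjunctive
rule: the root-to-leaf path's threshold conditions, merged per gene to the
tightest bounds (at most one ``<=`` and one ``>`` per gene), predicting the
leaf's majority class with the leaf's training support.  Because the leaves
partition the feature space, the resulting rules are mutually exclusive and
exhaustive: every cell satisfies exactly one rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .data_io import LabelledMatrix
from .errors import ConfigurationError, ConsistencyError

__all__ = ["Rule", "RuleSet", "extract_rules", "apply_rules", "summarize_rules"]

LE, GT = "<=", ">"  # CART orientation: x[g] <= t goes left, x[g] > t goes right


@dataclass
class Rule:
    """One conjunctive threshold rule: conditions on gene expression (TPM-like
    units) implying a predicted class, with training support and leaf purity."""

    conditions: list[tuple[str, str, float]]
    predicted_class: str
    support: int
    purity: float

    def matches(self, row: np.ndarray, gene_pos: dict[str, int]) -> bool:
        for g, op, t in self.conditions:
            v = row[gene_pos[g]]
            if op == LE and not v <= t:
                return False
            if op == GT and not v > t:
                return False
        return True


@dataclass
class RuleSet:
    rules: list[Rule]
    feature_ids: list[str]
    class_rule_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.class_rule_counts:
            counts: dict[str, int] = {}
            for r in self.rules:
                counts[r.predicted_class] = counts.get(r.predicted_class, 0) + 1
            self.class_rule_counts = counts

    def __len__(self) -> int:
        return len(self.rules)


def _merge_path(path: list[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    """Tightest per-gene bounds: min over <= thresholds, max over > thresholds.
    Condition order follows first appearance of each (gene, comparator) pair."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[tuple[str, str]] = []
    for g, op, t in path:
        bounds = upper if op == LE else lower
        if g not in bounds:
            order.append((g, op))
            bounds[g] = t
        else:
            bounds[g] = min(bounds[g], t) if op == LE else max(bounds[g], t)
    return [(g, op, (upper if op == LE else lower)[g]) for g, op in order]


def extract_rules(
    data: LabelledMatrix, features, seed: int = 0, max_depth: int | None = None
) -> RuleSet:
    """Fit an unpruned CART tree on ``features`` and return one rule per leaf.

    Thresholds are the tree's CART midpoints between adjacent observed
    values; the predicted class is the leaf majority.
    """
    features = list(features)
    if not features:
        raise ConfigurationError("extract_rules requires a non-empty feature list")
    data.require_trainable()
    cols = data.gene_index(features)
    X = data.values[:, cols]
    y = data.label_array().astype(str)

    tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth, random_state=seed)
    tree.fit(X, y)
    t = tree.tree_
    classes = [str(c) for c in tree.classes_]

    rules: list[Rule] = []

    def walk(node: int, path: list[tuple[str, str, float]]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0] * t.weighted_n_node_samples[node]
            counts = np.rint(counts).astype(int)
            total = int(counts.sum())
            k = int(np.argmax(counts))
            rules.append(
                Rule(
                    conditions=_merge_path(path),
                    predicted_class=classes[k],
                    support=total,
                    purity=float(counts[k] / total),
                )
            )
            return
        g = features[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], path + [(g, LE, thr)])
        walk(t.children_right[node], path + [(g, GT, thr)])

    walk(0, [])
    return RuleSet(rules=rules, feature_ids=features)


def apply_rules(rules: RuleSet, data: LabelledMatrix) -> list[str]:
    """Classify every cell by the single rule whose conditions it satisfies.

    Raises :class:`ConsistencyError` if any cell matches zero or multiple
    rules — that would violate the tiling invariant of a tree-derived set.
    """
    cols = data.gene_index(rules.feature_ids)
    X = data.values[:, cols]
    n = X.shape[0]
    pos = {g: i for i, g in enumerate(rules.feature_ids)}

    match = np.ones((n, len(rules.rules)), dtype=bool)
    for r_i, rule in enumerate(rules.rules):
        for g, op, thr in rule.conditions:
            col = X[:, pos[g]]
            match[:, r_i] &= (col <= thr) if op == LE else (col > thr)
    counts = match.sum(axis=1)
    if np.any(counts != 1):
        bad = int(np.flatnonzero(counts != 1)[0])
        raise ConsistencyError(
            f"cell {data.cell_ids[bad]} matches {int(counts[bad])} rules (expected exactly 1)"
        )
    which = match.argmax(axis=1)
    return [rules.rules[j].predicted_class for j in which]


def summarize_rules(rules: RuleSet) -> dict:
    """Per-class rule counts, the total, and the class with most rules."""
    counts = dict(rules.class_rule_counts)
    top = max(counts, key=lambda c: (counts[c], c)) if counts else None
    return {"counts": counts, "total": len(rules.rules), "top_class": top}
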