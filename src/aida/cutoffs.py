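"""Pairwise decision-tree cut-off derivation for ICD vs non-ICD.

The published risk-zone thresholds were obtained by growing a shallow
classification tree on one parameter pair at a time (AoP-AD, HSD-AD,
MLA-AD) against the binary cesarean outcome. This module implements that
procedure explicitly: Gini impurity, candidate thresholds at midpoints of
consecutive distinct sorted values (which is why every published threshold
ends in .5), ties broken toward the smaller threshold, depth limited to 2,
no pruning, minimum leaf size 1. Growth is fully deterministic.

The published thresholds themselves cannot be re-derived because the raw
cohort is not deposited; they live as constants in the default
:class:`~aida.zoning.ZoneScheme`, while this module demonstrates and tests
the derivation procedure on synthetic cohorts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .records import BinaryOutcome, PatientRecord

PAIRS = {
    "AD-AoP": ("ad_mm", "aop_deg"),
    "AD-HSD": ("ad_mm", "hsd_mm"),
    "AD-MLA": ("ad_mm", "mla_deg"),
}


def gini(labels) -> float:
    """Gini impurity of a multiset of ICD/NOICD labels, in [0, 0.5]."""
    labels = list(labels)
    if not labels:
        raise ValueError("Gini impurity is undefined for an empty node")
    p = sum(l == BinaryOutcome.ICD for l in labels) / len(labels)
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def candidate_thresholds(values) -> list[float]:
    """Midpoints of consecutive distinct sorted feature values."""
    distinct = sorted(set(values))
    return [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]


def best_split(points) -> tuple[float, float] | None:
    """Best single-feature split of ``points`` = [(value, label), ...].

    Returns ``(threshold, impurity_decrease)`` maximizing the weighted Gini
    decrease over midpoint candidates, ties broken toward the smallest
    threshold; ``None`` when all feature values coincide.
    """
    points = list(points)
    values = [v for v, _ in points]
    labels = [l for _, l in points]
    candidates = candidate_thresholds(values)
    if not candidates:
        return None
    parent = gini(labels)
    n = len(points)
    best = None
    for t in candidates:
        left = [l for v, l in points if v < t]
        right = [l for v, l in points if v >= t]
        child = (len(left) * gini(left) + len(right) * gini(right)) / n
        decrease = parent - child
        if best is None or decrease > best[1] + 1e-12:
            best = (t, decrease)
    return best


@dataclass
class SplitNode:
    """Internal node of a two-feature classification tree."""

    feature: str
    threshold: float
    impurity_decrease: float
    left: "SplitNode | BinaryOutcome" = None   # feature < threshold
    right: "SplitNode | BinaryOutcome" = None  # feature >= threshold


def _majority(labels) -> BinaryOutcome:
    # ties go to the negative class: no cesarean without majority evidence
    counts = Counter(labels)
    if counts[BinaryOutcome.ICD] > counts[BinaryOutcome.NOICD]:
        return BinaryOutcome.ICD
    return BinaryOutcome.NOICD


def grow_tree(rows, labels, features, max_depth=2, min_leaf=1) -> SplitNode | BinaryOutcome:
    """Grow a CART on ``rows`` (dicts of feature -> value) deterministically.

    Features are scanned in the given order; a later feature replaces the
    incumbent split only with a strictly larger impurity decrease, so ties
    across features keep the earlier feature.
    """
    if len(set(labels)) == 1 or max_depth == 0 or len(labels) < 2 * min_leaf:
        return _majority(labels)
    best = None
    for feat in features:
        res = best_split([(row[feat], l) for row, l in zip(rows, labels)])
        if res is None:
            continue
        t, dec = res
        if best is None or dec > best[2] + 1e-12:
            best = (feat, t, dec)
    if best is None or best[2] <= 1e-12:
        return _majority(labels)
    feat, t, dec = best
    left_ix = [i for i, row in enumerate(rows) if row[feat] < t]
    right_ix = [i for i, row in enumerate(rows) if row[feat] >= t]
    node = SplitNode(feature=feat, threshold=t, impurity_decrease=dec)
    node.left = grow_tree(
        [rows[i] for i in left_ix], [labels[i] for i in left_ix],
        features, max_depth - 1, min_leaf,
    )
    node.right = grow_tree(
        [rows[i] for i in right_ix], [labels[i] for i in right_ix],
        features, max_depth - 1, min_leaf,
    )
    return node


@dataclass(frozen=True)
class CutoffRule:
    """Conjunction of threshold conditions leading to one ICD leaf."""

    conditions: tuple[tuple[str, str, float], ...]  # (feature, '>=' or '<', threshold)


@dataclass(frozen=True)
class PairCutoffs:
    pair: str
    rules: tuple[CutoffRule, ...]
    tree: SplitNode | BinaryOutcome = field(compare=False, default=None)

    def thresholds(self, feature: str) -> list[float]:
        """Sorted distinct thresholds applied to one feature across rules."""
        return sorted(
            {t for rule in self.rules for f, _, t in rule.conditions if f == feature}
        )

    def to_dict(self) -> dict:
        return {
            "pair": self.pair,
            "rules": [
                [{"feature": f, "direction": op, "threshold": t}
                 for f, op, t in rule.conditions]
                for rule in self.rules
            ],
        }


def _icd_paths(node, prefix=()) -> list[CutoffRule]:
    if isinstance(node, BinaryOutcome):
        return [CutoffRule(conditions=prefix)] if node is BinaryOutcome.ICD else []
    paths = _icd_paths(node.left, prefix + ((node.feature, "<", node.threshold),))
    paths += _icd_paths(node.right, prefix + ((node.feature, ">=", node.threshold),))
    return paths


def derive_pair_cutoffs(
    cohort: list[PatientRecord], pair: str, max_depth: int = 2
) -> PairCutoffs:
    """Grow the pair's tree on the cohort and extract its ICD decision rules."""
    if pair not in PAIRS:
        raise KeyError(f"unknown pair {pair!r}; expected one of {sorted(PAIRS)}")
    features = PAIRS[pair]
    labels = [r.binary_outcome for r in cohort]
    if len(set(labels)) < 2:
        raise ValueError("no split target: cohort contains a single outcome class")
    rows = [{f: getattr(r, f) for f in features} for r in cohort]
    tree = grow_tree(rows, labels, features, max_depth=max_depth)
    return PairCutoffs(pair=pair, rules=tuple(_icd_paths(tree)), tree=tree)
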