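"""Class-stratified, NA-aware evaluation of ICD predictions.

Confusion matrices take intrapartum cesarean delivery (ICD) as the positive
class and, by default, weight each prediction-table row by its repetition
count, so the per-class totals equal the expanded prediction counts.

Metrics follow the published convention for undefined values: a metric is
NA exactly when its defining denominator is zero (PPV with no positive
predictions, recall with no actual positives, and so on), and F1 is NA when
PPV or recall is NA or when they sum to zero. Internally the metrics are
exact rationals on the counts; display rounding never feeds back into a
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

from .fixtures import FixtureSet
from .records import BinaryOutcome, PredictionRecord

ALGORITHMS = ("RF", "SVM", "MLP")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError(f"confusion counts must be non-negative: {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Six performance metrics; ``None`` encodes NA (undefined)."""

    accuracy: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    recall: Fraction | None
    specificity: Fraction | None
    f1: Fraction | None

    def rounded(self, digits: int = 4) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "ppv", "npv", "recall", "specificity", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round(float(v), digits)
        return out


def confusion(
    predictions: list[PredictionRecord],
    algorithm: str,
    aida_class: int | None = None,
    expand_by_repetitions: bool = True,
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN for one learner, optionally within one AIDA class."""
    tp = fp = fn = tn = 0
    for rec in predictions:
        if aida_class is not None and rec.aida_class != aida_class:
            continue
        w = rec.n_predictions if expand_by_repetitions else 1
        predicted = rec.predicted(algorithm)
        if rec.actual_outcome is BinaryOutcome.ICD:
            if predicted is BinaryOutcome.ICD:
                tp += w
            else:
                fn += w
        else:
            if predicted is BinaryOutcome.ICD:
                fp += w
            else:
                tn += w
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Exact-rational metric set with the zero-denominator NA convention."""
    if cm.total == 0:
        raise ValueError("metrics are undefined for an empty confusion matrix")
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if ppv is None or recall is None or ppv + recall == 0:
        f1 = None
    else:
        f1 = 2 * ppv * recall / (ppv + recall)
    return MetricSet(
        accuracy=Fraction(cm.tp + cm.tn, cm.total),
        ppv=ppv,
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        recall=recall,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        f1=f1,
    )


def _round_as_printed(value: Fraction | None, printed: str) -> str:
    """Render ``value`` at the precision of the printed cell."""
    if value is None:
        return "NA"
    printed = printed.strip()
    if "." not in printed:
        return str(int(value)) if value.denominator == 1 else f"{float(value)}"
    digits = len(printed.split(".")[1])
    q = Decimal(value.numerator) / Decimal(value.denominator)
    return str(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


def reproduce_table6(fixtures: FixtureSet) -> tuple[pd.DataFrame, list[str]]:
    """Recompute the per-class performance table from the prediction tables.

    Returns the computed table (counts plus metrics rounded to four
    decimals) and a structured diff: one message per cell that disagrees
    with the published value at its printed precision. An empty diff means
    all nine (class, algorithm) rows reproduce.
    """
    metric_cols = ("accuracy", "ppv", "npv", "recall", "specificity", "f1")
    rows, diffs = [], []
    published = fixtures.performance.set_index(["aida_class", "algorithm"])
    for aida_class in sorted(fixtures.predictions):
        for algo in ALGORITHMS:
            cm = confusion(fixtures.predictions[aida_class], algo)
            ms = metrics(cm)
            row = {"aida_class": aida_class, "algorithm": algo,
                   "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
            row.update(ms.rounded())
            rows.append(row)
            ref = published.loc[(aida_class, algo)]
            for count in ("tp", "fp", "fn", "tn"):
                if int(ref[count]) != row[count]:
                    diffs.append(
                        f"class {aida_class} {algo} {count}: computed "
                        f"{row[count]}, published {int(ref[count])}"
                    )
            for col in metric_cols:
                printed = str(ref[col])
                got = _round_as_printed(getattr(ms, col), printed)
                want = "NA" if printed == "NA" else printed
                if got != want:
                    diffs.append(
                        f"class {aida_class} {algo} {col}: computed {got}, "
                        f"published {want}"
                    )
    return pd.DataFrame(rows), diffs


def agreement_view(predictions: list[PredictionRecord]) -> pd.DataFrame:
    """Per-patient agreement table, grouped by class and asynclitism type.

    One row per prediction record with a boolean agreement flag per learner
    (True when the predicted label matches the actual outcome), mirroring
    the green/red colour coding of the published per-patient tables.
    """
    rows = []
    for rec in sorted(
        predictions, key=lambda r: (r.aida_class, r.asynclitism_type.value)
    ):
        row = {
            "aida_class": rec.aida_class,
            "asynclitism_type": rec.asynclitism_type.value,
            "patient_id": rec.patient_id,
            "n_predictions": rec.n_predictions,
            "actual": rec.actual_outcome.value,
        }
        for algo in ALGORITHMS:
            row[f"agree_{algo.lower()}"] = rec.predicted(algo) == rec.actual_outcome
        rows.append(row)
    return pd.DataFrame(rows)
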