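"""Machine-readable copies of the published study tables.

The raw per-patient cohort behind the study is not deposited anywhere; what
is public are summary tables: cohort descriptive statistics, the Pearson
correlation table, the decision-tree cut-offs, the per-class confusion
matrices/metrics, and three per-patient prediction tables (AIDA classes 0,
3 and 4) with zone labels, repetition counts, and the label each learner
predicted. Those tables ship here as small CSV files and load into a
validated :class:`FixtureSet`.

The prediction tables use "SPD" for their fourth zone column in the source;
it is mapped to HSD (head-symphysis distance), the only distance parameter
among the four.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .records import PredictionRecord, Zone

#: Expanded prediction counts per AIDA class (sum of n_predictions).
EXPECTED_EXPANDED = {0: 68, 3: 50, 4: 31}
#: Distinct patients per AIDA class prediction table.
EXPECTED_PATIENTS = {0: 38, 3: 30, 4: 18}


class FixtureError(RuntimeError):
    """A packaged fixture file is missing or internally inconsistent."""


@dataclass(frozen=True)
class FixtureSet:
    summary_stats: pd.DataFrame      # per-variable min/max/mean/SD
    correlations: pd.DataFrame       # pair, coefficient, strength, p
    cutoffs: pd.DataFrame            # pairwise decision-tree thresholds
    performance: pd.DataFrame        # per (class, algorithm) metrics + counts
    importance_ranks: pd.DataFrame   # per-algorithm feature-importance order
    predictions: dict[int, list[PredictionRecord]]  # AIDA class -> records

    def all_predictions(self) -> list[PredictionRecord]:
        return [r for recs in self.predictions.values() for r in recs]

    def distinct_patients(self) -> int:
        return len({r.patient_id for r in self.all_predictions()})

    def expanded_predictions(self, aida_class: int | None = None) -> int:
        recs = (
            self.all_predictions()
            if aida_class is None
            else self.predictions[aida_class]
        )
        return sum(r.n_predictions for r in recs)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("aida.data").joinpath(name)
    try:
        with ref.open("r", encoding="utf-8") as fh:
            # keep "NA" cells as literal strings (the published NA convention)
            return pd.read_csv(fh, keep_default_na=False)
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise FixtureError(f"fixture table {name!r} is missing or corrupt: {exc}")


def _prediction_records(name: str, aida_class: int) -> list[PredictionRecord]:
    frame = _read(name)
    records = []
    for _, row in frame.iterrows():
        records.append(
            PredictionRecord(
                patient_id=str(row["patient_id"]),
                aida_class=aida_class,
                zone_ad=row["zone_ad"],
                zone_aop=row["zone_aop"],
                zone_mla=row["zone_mla"],
                zone_hsd=row["zone_hsd"],
                asynclitism_type=row["asynclitism_type"],
                actual_outcome=row["actual_outcome"],
                predicted_svm=row["predicted_svm"],
                predicted_rf=row["predicted_rf"],
                predicted_mlp=row["predicted_mlp"],
                n_predictions=int(row["n_predictions"]),
            )
        )
    return records


def load_fixtures() -> FixtureSet:
    """Load and cross-validate all packaged study tables."""
    fs = FixtureSet(
        summary_stats=_read("table2_geometry.csv").merge(
            _read("table1_demographics.csv").rename(
                columns={"characteristic": "parameter"}
            ),
            how="outer",
            on=("parameter", "mean", "sd"),
        ),
        correlations=_read("table3_correlations.csv"),
        cutoffs=_read("table5_cutoffs.csv"),
        performance=_read("table6_performance.csv"),
        importance_ranks=_read("table4_importance.csv"),
        predictions={
            c: _prediction_records(f"predictions_class{c}.csv", c)
            for c in (0, 3, 4)
        },
    )
    _validate(fs)
    return fs


def _validate(fs: FixtureSet) -> None:
    for c, expected in EXPECTED_EXPANDED.items():
        got = fs.expanded_predictions(c)
        if got != expected:
            raise FixtureError(
                f"prediction table for class {c}: expected {expected} expanded "
                f"predictions, found {got}"
            )
    for c, expected in EXPECTED_PATIENTS.items():
        got = len({r.patient_id for r in fs.predictions[c]})
        if got != expected:
            raise FixtureError(
                f"prediction table for class {c}: expected {expected} distinct "
                f"patients, found {got}"
            )
    for c, recs in fs.predictions.items():
        for r in recs:
            greens = sum(z is Zone.GREEN for z in r.zones())
            if greens != 4 - c:
                raise FixtureError(
                    f"class-{c} row for patient {r.patient_id} has {greens} "
                    f"green zones; expected {4 - c}"
                )
    perf = fs.performance
    for (c, _), grp in perf.groupby(["aida_class", "algorithm"]):
        total = int(grp[["tp", "fp", "fn", "tn"]].sum(axis=1).iloc[0])
        if total != EXPECTED_EXPANDED[int(c)]:
            raise FixtureError(
                f"performance table row for class {c}: counts sum to {total}, "
                f"expected {EXPECTED_EXPANDED[int(c)]}"
            )
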