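"""Delimited-text readers and writers for cohorts and prediction tables.

Cohort files are plain CSV (UTF-8, "." decimal) with one header row. Required
columns: patient_id, ad_mm, aop_deg, hsd_mm, mla_deg, asynclitism_type,
delivery_outcome, apgar1, apgar5. The optional demographic columns
age_years, gestational_age_weeks, bmi and neonatal_weight_g are preserved
when present.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import pandas as pd

from .records import PatientRecord, PredictionRecord, ValidationError

REQUIRED_COLUMNS = [
    "patient_id",
    "ad_mm",
    "aop_deg",
    "hsd_mm",
    "mla_deg",
    "asynclitism_type",
    "delivery_outcome",
    "apgar1",
    "apgar5",
]
OPTIONAL_COLUMNS = ["age_years", "gestational_age_weeks", "bmi", "neonatal_weight_g"]

PREDICTION_COLUMNS = [
    "patient_id",
    "aida_class",
    "zone_ad",
    "zone_aop",
    "zone_mla",
    "zone_hsd",
    "asynclitism_type",
    "actual_outcome",
    "predicted_svm",
    "predicted_rf",
    "predicted_mlp",
    "n_predictions",
]


class SchemaError(ValueError):
    """The file is missing a required column."""


def read_cohort(path: str | os.PathLike) -> list[PatientRecord]:
    """Read a cohort CSV, validating every row.

    Raises :class:`SchemaError` if a required column is absent and
    :class:`~aida.records.ValidationError` (naming row and field) if a value
    is out of range. Row order is preserved.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing columns: {missing}")
    extras = [c for c in OPTIONAL_COLUMNS if c in frame.columns]
    records = []
    for i, row in frame.iterrows():
        kwargs = {c: row[c] for c in REQUIRED_COLUMNS + extras}
        kwargs["apgar1"] = int(row["apgar1"])
        kwargs["apgar5"] = int(row["apgar5"])
        for c in extras:
            if pd.isna(row[c]):
                kwargs.pop(c)
        try:
            records.append(PatientRecord(**kwargs))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i} ({row['patient_id']}): {exc}") from exc
    return records


def cohort_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the documented column order."""
    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
    for col in ("asynclitism_type", "delivery_outcome"):
        frame[col] = frame[col].map(lambda v: v.value)
    if not rows:  # keep a stable schema for the empty cohort
        frame = frame.astype(object)
    return frame


def write_cohort(records: list[PatientRecord], path: str | os.PathLike) -> None:
    """Write a cohort CSV such that ``read_cohort`` round-trips losslessly."""
    frame = cohort_frame(records)
    # drop optional columns that are entirely absent
    for col in OPTIONAL_COLUMNS:
        if frame[col].isna().all():
            frame = frame.drop(columns=col)
    frame.to_csv(path, index=False)


def read_predictions(path: str | os.PathLike) -> list[PredictionRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"prediction file {path} is missing columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                PredictionRecord(
                    **{c: row[c] for c in PREDICTION_COLUMNS if c not in
                       ("aida_class", "n_predictions")},
                    aida_class=int(row["aida_class"]),
                    n_predictions=int(row["n_predictions"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i} ({row['patient_id']}): {exc}") from exc
    return records


def write_predictions(records: list[PredictionRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        rows.append({c: getattr(d[c], "value", d[c]) for c in PREDICTION_COLUMNS})
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, index=False)
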