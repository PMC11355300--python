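"""Pearson correlation with fixed strength bands and significance stars.

The strength of a coefficient r is read off |r| in half-open bands:
[0, 0.2) very weak, [0.2, 0.4) weak, [0.4, 0.6) moderate, [0.6, 0.8)
strong, [0.8, 1] very strong. Two-sided p-values come from the exact
t-transform with n - 2 degrees of freedom and are starred at the usual
p < 0.05 (*), p < 0.01 (**) and p < 0.001 (***) thresholds, all strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import cohort_frame
from .records import PatientRecord

_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (np.inf, "very strong"),
)


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    pc: float
    p: float
    strength: str
    stars: str
    n: int


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson coefficient and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson needs two equal-length 1-d series of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def strength_label(pc: float) -> str:
    """Strength band of a coefficient, by |pc|."""
    a = abs(pc)
    if a > 1:
        raise ValueError(f"|pc| must be <= 1, got {pc}")
    for bound, label in _BANDS:
        if a < bound:
            return label
    raise AssertionError("unreachable")


def significance_stars(p: float) -> str:
    # p == 0.0 arises from floating-point underflow of tiny p-values
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_report(
    cohort: list[PatientRecord] | pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> list[CorrelationResult]:
    """One :class:`CorrelationResult` per requested column pair."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    results = []
    for a, b in pairs:
        for col in (a, b):
            if col not in frame.columns:
                raise KeyError(f"cohort has no column {col!r}")
        r, p = pearson(frame[a], frame[b])
        results.append(
            CorrelationResult(
                pair=(a, b), pc=r, p=p,
                strength=strength_label(r),
                stars=significance_stars(p),
                n=len(frame),
            )
        )
    return results


def report_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Correlation results laid out like the published correlation table."""
    return pd.DataFrame(
        {
            "var1": [r.pair[0] for r in results],
            "var2": [r.pair[1] for r in results],
            "pc": [r.pc for r in results],
            "strength": [r.strength for r in results],
            "p": [r.p for r in results],
            "stars": [r.stars for r in results],
            "n": [r.n for r in results],
        }
    )
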