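"""Synthetic cohort generator: determinism, marginal and correlation recovery."""

import numpy as np
import pytest

from aida import (
    assign_outcome,
    default_model,
    default_zone_scheme,
    generate_cohort,
    sample_apgar,
    sample_geometry,
)
from aida.io import cohort_frame
from aida.records import BinaryOutcome, DeliveryOutcome
from aida.synthetic import CohortModel, Marginal, substream
from aida.zoning import profile


def test_default_model_holds_published_statistics(model):
    m = model.marginals["ad_mm"]
    assert (m.mean, m.sd, m.lo, m.hi) == (60.18, 18.866, 4, 95)
    assert model.correlation("ad_mm", "aop_deg") == 0.36
    assert model.correlation("aop_deg", "ad_mm") == 0.36  # symmetric lookup
    assert model.correlation("aop_deg", "hsd_mm") == 0.0  # unpublished -> 0
    assert model.anterior_fraction == pytest.approx(50 / 135)


def test_generate_cohort_deterministic(model):
    a = generate_cohort(model, n=50, seed=42)
    b = generate_cohort(model, n=50, seed=42)
    assert a == b
    c = generate_cohort(model, n=50, seed=43)
    assert a != c


def test_study_sized_cohort_is_valid(cohort135):
    assert len(cohort135) == 135
    assert cohort135[0].patient_id == "S0001"
    assert len({r.patient_id for r in cohort135}) == 135


def test_geometry_within_bounds_and_moments_recovered(model):
    g = sample_geometry(model, 10_000, seed=1)
    for j, name in enumerate(("ad_mm", "aop_deg", "hsd_mm", "mla_deg")):
        m = model.marginals[name]
        assert g[:, j].min() >= m.lo and g[:, j].max() <= m.hi
        se = m.sd / np.sqrt(len(g))
        assert abs(g[:, j].mean() - m.mean) < 3 * se, name


def test_correlation_recovery(model):
    g = sample_geometry(model, 10_000, seed=2)
    corr = np.corrcoef(g.T)
    assert corr[0, 1] == pytest.approx(0.36, abs=0.05)  # AD-AoP
    assert corr[0, 2] == pytest.approx(0.18, abs=0.05)  # AD-HSD
    assert corr[0, 3] == pytest.approx(0.14, abs=0.05)  # AD-MLA


def test_zero_correlation_model_independent(model):
    flat = CohortModel(
        marginals=model.marginals,
        correlations={},
        anterior_fraction=model.anterior_fraction,
        outcome_intercept=model.outcome_intercept,
        outcome_slope=model.outcome_slope,
    )
    g = sample_geometry(flat, 10_000, seed=3)
    corr = np.corrcoef(g.T)
    off = corr[np.triu_indices(4, k=1)]
    assert np.all(np.abs(off) < 3 / np.sqrt(len(g)) * 1.5)


def test_apgar_correlations_and_range(model):
    g = sample_geometry(model, 10_000, seed=4)
    cont = sample_apgar(model, g[:, 0], substream(4, "apgar"), rounded=False)
    assert np.corrcoef(cont.T)[0, 1] == pytest.approx(0.8, abs=0.05)
    assert np.corrcoef(g[:, 0], cont[:, 0])[0, 1] == pytest.approx(-0.2, abs=0.05)
    ints = sample_apgar(model, g[:, 0], substream(4, "apgar"))
    assert ints.dtype.kind == "i"
    assert ints.min() >= 0 and ints.max() <= 10


def test_apgar_independent_when_uncorrelated(model):
    flat = CohortModel(
        marginals=model.marginals,
        correlations={("apgar1", "apgar5"): 0.8},  # keep mutual, drop AD links
        anterior_fraction=model.anterior_fraction,
        outcome_intercept=model.outcome_intercept,
        outcome_slope=model.outcome_slope,
    )
    g = sample_geometry(flat, 10_000, seed=5)
    cont = sample_apgar(flat, g[:, 0], substream(5, "apgar"), rounded=False)
    assert abs(np.corrcoef(g[:, 0], cont[:, 0])[0, 1]) < 0.05


def test_outcome_gradient_monotone_in_class(cohort10k):
    k = np.array([profile(r).aida_class for r in cohort10k])
    icd = np.array([r.binary_outcome is BinaryOutcome.ICD for r in cohort10k])
    rates = [icd[k == c].mean() for c in range(5)]
    assert all(a <= b for a, b in zip(rates, rates[1:]))
    assert rates[0] < 0.05 and rates[4] > 0.95


def test_outcome_submix_ratios(cohort10k):
    outcomes = [r.delivery_outcome for r in cohort10k]
    n_icd = outcomes.count(DeliveryOutcome.ICD)
    n_fail = outcomes.count(DeliveryOutcome.ICD_AFTER_FAILURE)
    n_ovd = outcomes.count(DeliveryOutcome.OVD)
    n_sp = outcomes.count(DeliveryOutcome.SPONTANEOUS)
    assert n_icd / (n_icd + n_fail) == pytest.approx(56 / 78, abs=0.03)
    assert n_ovd / (n_ovd + n_sp) == pytest.approx(31 / 57, abs=0.03)
    # cohort-wide cesarean fraction near the published 78/135
    assert (n_icd + n_fail) / len(outcomes) == pytest.approx(78 / 135, abs=0.03)


def test_null_slope_makes_outcome_independent_of_class(model, scheme):
    null = CohortModel(
        marginals=model.marginals,
        correlations=model.correlations,
        anterior_fraction=model.anterior_fraction,
        outcome_intercept=0.0,
        outcome_slope=0.0,
    )
    rng = substream(6, "outcome")
    draws_low = [
        assign_outcome(null, (10, 120, 12, 40), scheme, rng) for _ in range(2000)
    ]
    rng = substream(6, "outcome")
    draws_high = [
        assign_outcome(null, (90, 95, 40, 85), scheme, rng) for _ in range(2000)
    ]
    p_low = np.mean([d in (DeliveryOutcome.ICD, DeliveryOutcome.ICD_AFTER_FAILURE)
                     for d in draws_low])
    p_high = np.mean([d in (DeliveryOutcome.ICD, DeliveryOutcome.ICD_AFTER_FAILURE)
                      for d in draws_high])
    assert p_low == pytest.approx(0.5, abs=0.05)
    assert p_low == pytest.approx(p_high, abs=0.05)


def test_anterior_fraction_recovered(cohort10k):
    from aida.records import AsynclitismType

    frac = np.mean(
        [r.asynclitism_type is AsynclitismType.ANTERIOR for r in cohort10k]
    )
    assert frac == pytest.approx(50 / 135, abs=0.02)


def test_marginal_rejects_inverted_bounds():
    with pytest.raises(ValueError):
        Marginal(mean=5, sd=1, lo=10, hi=0)


def test_substreams_are_named_and_stable():
    a = substream(7, "geometry").standard_normal(3)
    b = substream(7, "geometry").standard_normal(3)
    c = substream(7, "outcome").standard_normal(3)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
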