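"""Metrics against brute-force oracles; external and LOCO validation designs."""

import itertools
import warnings

import numpy as np
import pytest

from patternrisk.data import MissingnessPattern
from patternrisk.errors import ValidationDataError
from patternrisk.strategies import available_cases_fit
from patternrisk.synthetic import (
    CohortConfig,
    SyntheticConfig,
    default_true_model,
    generate_multicohort,
)
from patternrisk.validation import (
    ValidationReport,
    auc_bootstrap_ci,
    auc_with_ci,
    calibration_curve,
    cil_with_ci,
    external_validate,
    loco_cv,
    plot_calibration,
    plot_cv,
)


def _pair_counting_auc(risks, outcomes):
    """Exhaustive concordant/discordant/tied pair enumeration."""
    pos = [r for r, y in zip(risks, outcomes) if y == 1]
    neg = [r for r, y in zip(risks, outcomes) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_cil_arithmetic_and_sign_convention():
    cil, ci = cil_with_ci([0.2, 0.4, 0.6], [0, 1, 1])
    assert cil == pytest.approx(100 * (0.4 - 2 / 3))
    assert ci[0] < cil < ci[1]
    # risks equal to the event rate: CIL exactly 0
    cil0, _ = cil_with_ci([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert cil0 == 0.0
    with pytest.raises(ValidationDataError):
        cil_with_ci([], [])


def test_auc_degenerate_scores():
    auc, _ = auc_with_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 100.0
    auc, _ = auc_with_ci([0.4] * 10, [1, 0] * 5)
    assert auc == 50.0
    with pytest.raises(ValidationDataError):
        auc_with_ci([0.2, 0.4], [1, 1])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_auc_matches_exhaustive_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = 150
    risks = np.round(rng.random(n), 2)  # rounding forces ties
    outcomes = (rng.random(n) < 0.4).astype(float)
    auc, (lo, hi) = auc_with_ci(np.clip(risks, 0.01, 0.99), outcomes)
    brute = 100 * _pair_counting_auc(np.clip(risks, 0.01, 0.99), outcomes)
    assert auc == pytest.approx(brute, abs=1e-10)
    assert lo <= auc <= hi


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    risks = np.clip(rng.random(300), 0.01, 0.99)
    outcomes = (rng.random(300) < risks).astype(float)
    a1, _ = auc_with_ci(risks, outcomes)
    transformed = np.clip(1 / (1 + np.exp(-(3 * np.log(risks / (1 - risks)) + 1))), 1e-9, 1 - 1e-9)
    a2, _ = auc_with_ci(transformed, outcomes)
    assert a1 == pytest.approx(a2, abs=1e-10)


def test_delong_and_bootstrap_cis_agree():
    rng = np.random.default_rng(8)
    risks = np.clip(rng.beta(2, 4, 500), 1e-6, 1 - 1e-6)
    outcomes = (rng.random(500) < risks).astype(float)
    auc, (dlo, dhi) = auc_with_ci(risks, outcomes)
    _, (blo, bhi) = auc_bootstrap_ci(risks, outcomes, n_boot=800, seed=1)
    assert abs(dlo - blo) < 2.0 and abs(dhi - bhi) < 2.0


def test_calibration_curve_partitions_and_prevalence():
    rng = np.random.default_rng(2)
    risks = np.clip(rng.random(100), 0.01, 0.99)
    outcomes = (rng.random(100) < risks).astype(float)
    c = calibration_curve(risks, outcomes)
    assert c.counts == [10] * 10
    assert sum(c.counts) == 100
    weighted = np.average(c.observed, weights=c.counts)
    assert weighted == pytest.approx(outcomes.mean())
    assert all(lo <= ob <= hi for lo, ob, hi in zip(c.ci_low, c.observed, c.ci_high))
    with pytest.raises(ValidationDataError):
        calibration_curve(risks[:5], outcomes[:5])


def test_calibration_curve_identical_predictions_degenerate():
    outcomes = np.r_[np.ones(30), np.zeros(70)]
    c = calibration_curve(np.full(100, 0.3), outcomes)
    assert all(m == pytest.approx(0.3) for m in c.mean_predicted)


def test_calibrated_simulation_lies_inside_intervals():
    """Outcomes drawn Bernoulli(risk): each decile's observed proportion
    falls in its 99% Wilson interval around the mean predicted risk."""
    from statsmodels.stats.proportion import proportion_confint

    rng = np.random.default_rng(31)
    risks = np.clip(rng.beta(2, 5, 20_000), 1e-6, 1 - 1e-6)
    outcomes = (rng.random(20_000) < risks).astype(float)
    c = calibration_curve(risks, outcomes)
    for mp, k, n in zip(c.mean_predicted, np.multiply(c.observed, c.counts), c.counts):
        lo, hi = proportion_confint(round(mp * n), n, alpha=0.01, method="wilson")
        assert lo <= k / n <= hi or abs(k / n - mp) < 0.02


@pytest.fixture(scope="module")
def cv_data():
    cfg = SyntheticConfig(
        cohorts=tuple(
            CohortConfig(f"C{i}", 600, sporadic_rates={"volume": 0.25}) for i in range(3)
        ),
        true_model=default_true_model(),
        target_prevalence=0.3,
        seed=13,
    )
    return generate_multicohort(cfg)


def test_external_validate_bookkeeping(cv_data):
    test = cv_data.cohorts[-1]
    rest = cv_data.drop_cohort(test.cohort_id)
    r1 = external_validate("available_cases", rest, test)
    r2 = external_validate("categorization", rest, test)
    assert r1.n_test == r2.n_test == test.n
    assert r1.prevalence == r2.prevalence
    assert r1.n_patterns == 2  # volume observed / missing
    assert r2.n_patterns == 1  # one shared model for all patterns
    with pytest.raises(ValidationDataError):
        external_validate("available_cases", cv_data, test)


def test_external_validate_single_pattern_single_fit(cv_data, schema):
    test = cv_data.cohorts[-1]
    complete = test.frame[test.frame["volume"].notna()].reset_index(drop=True)
    from patternrisk.data import CohortDataset

    sub = CohortDataset("onlyfull", complete, schema)
    rest = cv_data.drop_cohort(test.cohort_id)
    rep = external_validate("available_cases", rest, sub)
    assert rep.n_patterns == 1


def test_loco_cv_folds_partition(cv_data):
    res = loco_cv("available_cases", cv_data)
    assert set(res.reports) == {c.cohort_id for c in cv_data.cohorts}
    assert sum(r.n_test for r in res.reports.values()) == cv_data.n
    s = res.summary
    aucs = [r.auc for r in res.reports.values()]
    assert min(aucs) <= s["auc_median"] <= max(aucs)
    assert s["cil_iqr"][0] <= s["cil_median"] <= s["cil_iqr"][1]


def test_training_self_calibration(cv_data, schema):
    """An intercept-containing fit evaluated on its own training pool has
    CIL numerically zero (the score equation)."""
    pat = MissingnessPattern.from_factors([], schema)
    m = available_cases_fit(cv_data, pat)
    pooled = cv_data.pooled()
    risks = [m.predict({"psa": p, "age": a}) for p, a in zip(pooled["psa"], pooled["age"])]
    cil, _ = cil_with_ci(risks, pooled["outcome"])
    assert abs(cil) < 1e-6


def test_report_serialization_roundtrip(cv_data, tmp_path):
    test = cv_data.cohorts[-1]
    rest = cv_data.drop_cohort(test.cohort_id)
    rep = external_validate("available_cases", rest, test)
    path = tmp_path / "report.json"
    rep.to_json(path)
    import json

    back = ValidationReport.from_dict(json.loads(path.read_text()))
    assert back.to_dict() == rep.to_dict()


def test_plots_write_files(cv_data, tmp_path):
    test = cv_data.cohorts[-1]
    rest = cv_data.drop_cohort(test.cohort_id)
    rep = external_validate("available_cases", rest, test)
    plot_calibration(rep, tmp_path / "cal.png")
    res = loco_cv("available_cases", cv_data)
    plot_cv({"available_cases": res}, "auc", tmp_path / "cv.png")
    assert (tmp_path / "cal.png").stat().st_size > 0
    assert (tmp_path / "cv.png").stat().st_size > 0
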