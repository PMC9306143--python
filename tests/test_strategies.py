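"""The six strategies: recodings, contracts, and strategy-specific behaviour."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from patternrisk.data import (
    CohortDataset,
    MissingnessPattern,
    MultiCohortDataset,
    complete_case_subset,
)
from patternrisk.errors import (
    EnsembleEmptyError,
    FamilyHistoryConsistencyError,
    InsufficientDataError,
    PatternRiskError,
    ValidationDataError,
)
from patternrisk.strategies import (
    STRATEGY_NAMES,
    available_cases_fit,
    categorization_fit,
    categorize_volume,
    cohort_ensemble_fit,
    combine_family_history,
    fit_strategy,
    imputation_fit,
    iterative_bic_fit,
    missing_indicator_fit,
)
from patternrisk.synthetic import (
    CohortConfig,
    SyntheticConfig,
    default_true_model,
    generate_multicohort,
)


@pytest.fixture(scope="module")
def mixed_training():
    """Three cohorts; one never collects volume; sporadic missingness elsewhere."""
    cfg = SyntheticConfig(
        cohorts=(
            CohortConfig("C1", 900, never_collected=frozenset({"volume"}),
                         sporadic_rates={"dre": 0.2}),
            CohortConfig("C2", 900, sporadic_rates={"volume": 0.3, "dre": 0.2}),
            CohortConfig("C3", 900, sporadic_rates={"volume": 0.2}),
        ),
        true_model=default_true_model(),
        target_prevalence=0.3,
        seed=8,
    )
    return generate_multicohort(cfg)


# ---------------------------------------------------------------------------
# recodings
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,level",
    [(25.0, "lt30"), (29.9, "lt30"), (30.0, "30to50"), (40.0, "30to50"),
     (50.0, "30to50"), (50.1, "gt50"), (120.0, "gt50"), (float("nan"), "missing"),
     (None, "missing")],
)
def test_categorize_volume_strata(value, level):
    assert categorize_volume(value) == level


def test_categorize_volume_rejects_nonpositive():
    with pytest.raises(ValidationDataError):
        categorize_volume(-5.0)


@pytest.mark.parametrize(
    "pca2,bca1,level",
    [(1.0, 0.0, "pca2_only"), (0.0, 1.0, "bca1_only"), (1.0, 1.0, "both"),
     (0.0, 0.0, "none"), (float("nan"), float("nan"), "missing")],
)
def test_combine_family_history_levels(pca2, bca1, level):
    assert combine_family_history(pca2, bca1) == level


def test_combine_family_history_half_missing_is_inconsistent():
    with pytest.raises(FamilyHistoryConsistencyError):
        combine_family_history(1.0, float("nan"))


# ---------------------------------------------------------------------------
# available cases
# ---------------------------------------------------------------------------


def test_available_cases_mandatory_pattern_uses_every_record(mixed_training, schema):
    pat = MissingnessPattern.from_factors([], schema)
    m = available_cases_fit(mixed_training, pat)
    assert m.n_obs == mixed_training.n
    assert m.n_cohorts == 3
    assert m.model.term_names == ["intercept", "psa_log2", "age"]


def test_available_cases_matches_complete_case_count(mixed_training, schema):
    pat = MissingnessPattern.from_factors(["volume", "dre"], schema)
    m = available_cases_fit(mixed_training, pat)
    assert m.n_obs == len(complete_case_subset(mixed_training, pat))
    assert m.n_cohorts == 2  # C1 never collects volume


def test_available_cases_uncollected_factor_errors(schema):
    cfg = SyntheticConfig(
        cohorts=(CohortConfig("A", 300, never_collected=frozenset({"volume"})),),
        true_model=default_true_model(), target_prevalence=0.3, seed=0)
    data = generate_multicohort(cfg)
    pat = MissingnessPattern.from_factors(["volume"], data.schema)
    with pytest.raises(InsufficientDataError):
        available_cases_fit(data, pat)


def test_predict_requires_pattern_factors(mixed_training, schema, example_patient):
    pat = MissingnessPattern.from_factors(["volume"], schema)
    m = available_cases_fit(mixed_training, pat)
    q = dict(example_patient)
    q["volume"] = float("nan")
    with pytest.raises(PatternRiskError, match="volume"):
        m.predict(q)


# ---------------------------------------------------------------------------
# iterative BIC
# ---------------------------------------------------------------------------


def test_iterative_bic_drops_sparse_noise_factor_and_grows_pool(schema):
    """A pure-noise factor collected by 1 of 4 cohorts is dropped by the
    selection, and the restarted fit pools strictly more records."""
    collect = CohortConfig("K1", 900)
    never = tuple(
        CohortConfig(f"K{i}", 800, never_collected=frozenset({"fiveari"}))
        for i in (2, 3, 4)
    )
    cfg = SyntheticConfig(
        cohorts=(collect, *never),
        true_model=default_true_model(),
        target_prevalence=0.3,
        seed=9,
    )
    data = generate_multicohort(cfg)
    pat = MissingnessPattern.from_factors(["dre", "fiveari"], schema)
    initial_pool = len(complete_case_subset(data, pat))
    m = iterative_bic_fit(data, pat)
    assert "fiveari" not in m.effective_pattern.observed
    assert m.n_obs > initial_pool
    assert m.n_restarts >= 1
    assert m.effective_pattern.observed <= pat.observed


def test_iterative_bic_fixed_point_on_strong_factors(mixed_training, schema):
    pat = MissingnessPattern.from_factors(["dre"], schema)
    m = iterative_bic_fit(mixed_training, pat)
    # PSA and DRE are strong true effects; they survive selection
    assert "psa" in m.mains and "dre" in m.mains
    for a, b in m.interactions:
        assert a in m.mains and b in m.mains


# ---------------------------------------------------------------------------
# cohort ensemble
# ---------------------------------------------------------------------------


def _manual_cohort(small_schema, cid, n, volume_measured_frac, seed=0):
    rng = np.random.default_rng(seed)
    psa = np.exp(rng.normal(np.log(6), 0.7, n))
    age = np.clip(rng.normal(64, 8, n), 40, 90)
    dre = (rng.random(n) < 0.25).astype(float)
    volume = np.exp(rng.normal(np.log(40), 0.45, n))
    y = (rng.random(n) < 0.3).astype(int)
    k = int(round(n * (1 - volume_measured_frac)))
    volume[:k] = np.nan
    frame = pd.DataFrame(
        {"outcome": y, "psa": psa, "age": age, "dre": dre, "volume": volume,
         "prior_neg_biopsy": (rng.random(n) < 0.2).astype(float)}
    )
    return CohortDataset(cid, frame, small_schema)


def test_ensemble_forty_percent_availability_rule(small_schema):
    pat = MissingnessPattern.from_factors(["volume"], small_schema)
    below = MultiCohortDataset([_manual_cohort(small_schema, "B", 1000, 0.39)])
    m = cohort_ensemble_fit(below, pat)
    assert "volume" not in m.members[0][1].observed  # 39% measured -> excluded
    above = MultiCohortDataset([_manual_cohort(small_schema, "A", 1000, 0.41)])
    m2 = cohort_ensemble_fit(above, pat)
    assert "volume" in m2.members[0][1].observed


def test_ensemble_single_cohort_equals_direct_model(small_training, small_schema):
    single = MultiCohortDataset([small_training.cohorts[0]])
    pat = MissingnessPattern.from_factors(["dre"], small_schema)
    ens = cohort_ensemble_fit(single, pat)
    direct = available_cases_fit(single, pat)
    q = {"psa": 7.0, "age": 66.0, "dre": 1.0}
    assert ens.predict(q) == pytest.approx(direct.predict(q), abs=1e-12)


def test_ensemble_prediction_is_mean_of_member_risks(small_training, small_schema):
    pat = MissingnessPattern.from_factors(["dre"], small_schema)
    ens = cohort_ensemble_fit(small_training, pat)
    q = {"psa": 7.0, "age": 66.0, "dre": 1.0}
    member = ens.member_risks(q)
    assert len(member) == 2
    assert ens.predict(q) == pytest.approx(np.mean(list(member.values())))


def test_ensemble_skips_degenerate_cohorts(small_schema, small_training):
    tiny = _manual_cohort(small_schema, "tiny", 30, 1.0, seed=1)
    tiny.frame["outcome"] = 1  # degenerate outcome -> skipped
    data = MultiCohortDataset([*small_training.cohorts, tiny])
    pat = MissingnessPattern.from_factors(["dre"], small_schema)
    with pytest.warns(UserWarning, match="tiny"):
        m = cohort_ensemble_fit(data, pat)
    assert [cid for cid, _, _ in m.members] == ["A", "B"]
    assert m.skipped and m.skipped[0][0] == "tiny"

    only_tiny = MultiCohortDataset([tiny])
    with pytest.raises(EnsembleEmptyError), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort_ensemble_fit(only_tiny, pat)


# ---------------------------------------------------------------------------
# categorization / missing indicator
# ---------------------------------------------------------------------------


def test_categorization_uses_every_record(mixed_training, schema):
    pat = MissingnessPattern.from_factors([], schema)
    m = categorization_fit(mixed_training, pat)
    assert m.n_obs == mixed_training.n
    # a user supplying only PSA and age is served with everything at "missing"
    r = m.predict({"psa": 6.0, "age": 65.0})
    assert 0.0 < r < 1.0
    assert "volume_30to50" in m.model.term_names
    assert "age" in m.model.term_names  # mandatory continuous stays continuous


def test_categorization_half_pair_input_demoted_to_missing(mixed_training, schema):
    pat = MissingnessPattern.from_factors([], schema)
    m = categorization_fit(mixed_training, pat)
    r = m.predict({"psa": 6.0, "age": 65.0, "fam_pca_2nd": 1.0})
    assert 0.0 < r < 1.0
    assert "fam_pca_2nd" in m.unused_factors({"psa": 6.0, "age": 65.0, "fam_pca_2nd": 1.0})


def test_missing_indicator_volume_terms(mixed_training, schema):
    pat = MissingnessPattern.from_factors([], schema)
    m = missing_indicator_fit(mixed_training, pat)
    assert "volume_log2" in m.model.term_names
    assert "volume_missing" in m.model.term_names
    assert "volume_30to50" not in m.model.term_names
    # differs from categorization only in the volume block
    c = categorization_fit(mixed_training, pat)
    mi_terms = set(m.model.term_names)
    cat_terms = set(c.model.term_names)
    assert {t for t in mi_terms ^ cat_terms if not t.startswith("volume")} == set()


def test_missing_indicator_on_complete_data_drops_indicators(complete_data):
    pat = MissingnessPattern.from_factors([], complete_data.schema)
    with pytest.warns(UserWarning, match="dropped constant"):
        m = missing_indicator_fit(complete_data, pat)
    assert "volume_missing" in m.dropped_terms


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def test_imputation_marginal_fill_at_prediction(mixed_training, schema, example_patient):
    pat = MissingnessPattern.from_factors([], schema)
    m = imputation_fit(mixed_training, pat, m=3, cycles=2, seed=4)
    # volume missing -> filled with the stored training marginal
    q = dict(example_patient)
    q["volume"] = float("nan")
    explicit = dict(example_patient)
    explicit["volume"] = m.marginals["volume"]
    assert m.predict(q) == pytest.approx(m.predict(explicit), abs=1e-12)
    # the stored continuous marginal is the mean on the log2 model scale
    pooled = mixed_training.pooled()
    assert math.log2(m.marginals["volume"]) == pytest.approx(
        np.log2(pooled["volume"].dropna()).mean()
    )


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("strategy", STRATEGY_NAMES)
def test_strategy_contract_grid(strategy, mixed_training, schema, example_patient):
    """Every strategy fits over a pattern grid, predicts inside (0,1), and is
    deterministic under a fixed seed."""
    patterns = [
        [],
        ["dre"],
        ["dre", "volume", "prior_neg_biopsy"],
        list(schema.optional),
    ]
    kwargs = {"m": 3, "cycles": 2} if strategy == "imputation" else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for factors in patterns:
            pat = MissingnessPattern.from_factors(factors, schema)
            m1 = fit_strategy(strategy, mixed_training, pat, seed=5, **kwargs)
            m2 = fit_strategy(strategy, mixed_training, pat, seed=5, **kwargs)
            q = {k: v for k, v in example_patient.items()
                 if k in pat.observed or k in schema.mandatory}
            r1, r2 = m1.predict(q), m2.predict(q)
            assert 0.0 < r1 < 1.0
            assert r1 == r2
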