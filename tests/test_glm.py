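"""Logistic fitting against independent oracles; BIC; stepwise selection."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from patternrisk.errors import (
    DegenerateOutcomeError,
    InsufficientDataError,
    PatternRiskError,
    SeparationError,
)
from patternrisk.glm import (
    FittedLogisticModel,
    bic,
    fit_logistic,
    predict_proba,
    stepwise_bic,
)


def _newton_oracle(X, y, tol=1e-12, max_iter=200):
    """Brute-force oracle: minimise the negative log-likelihood directly."""

    def negll(b):
        eta = X @ b
        return -(y @ eta - np.logaddexp(0, eta).sum())

    def grad(b):
        return -(X.T @ (y - expit(X @ b)))

    res = minimize(negll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": tol, "maxiter": max_iter})
    return res.x


def _sim(seed, n=200, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    beta = rng.normal(0, 0.8, p + 1)
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    return X, y


def test_two_by_two_closed_form():
    """Slope of a saturated binary model equals the contingency log odds ratio."""
    x = np.r_[np.zeros(100), np.ones(100)]
    y = np.r_[np.ones(30), np.zeros(70), np.ones(70), np.zeros(30)]
    m = fit_logistic(np.column_stack([np.ones(200), x]), y, ["intercept", "x"])
    assert m.coef("x") == pytest.approx(np.log(70 * 70 / (30 * 30)), abs=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_fit_matches_newton_oracle_and_statsmodels(seed):
    X, y = _sim(seed)
    m = fit_logistic(X, y)
    oracle = _newton_oracle(X, y)
    assert np.max(np.abs(m.coefficients - oracle)) < 1e-6
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert np.max(np.abs(m.coefficients - ref.params)) < 1e-8
    assert np.max(np.abs(m.covariance - ref.cov_params())) < 1e-6
    assert m.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


def test_degenerate_outcome_error():
    X = np.ones((50, 1))
    with pytest.raises(DegenerateOutcomeError):
        fit_logistic(X, np.ones(50))


def test_minimum_fit_size_guard():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(20), rng.standard_normal(20)])
    y = np.r_[np.ones(10), np.zeros(10)]
    with pytest.raises(InsufficientDataError):
        fit_logistic(X, y)
    # the guard can be lifted for internal search loops
    fit_logistic(X, y, check_min_size=False)


def test_perfect_separation_raises_with_terms():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(100)
    X = np.column_stack([np.ones(100), x])
    y = (x > 0).astype(float)
    with pytest.raises(SeparationError) as exc:
        fit_logistic(X, y, ["intercept", "x"])
    assert exc.value.terms


def test_score_equation_mean_prob_equals_event_rate():
    X, y = _sim(11, n=500)
    m = fit_logistic(X, y)
    p = predict_proba(m, X)
    assert abs(p.mean() - y.mean()) < 1e-8


def test_predict_proba_contract():
    m = FittedLogisticModel(
        term_names=["intercept"],
        coefficients=np.array([0.0]),
        covariance=np.array([[1.0]]),
        log_likelihood=-1.0,
        n_obs=10,
        n_events=5,
        converged=True,
    )
    assert predict_proba(m, np.array([[1.0]]))[0] == 0.5
    # extreme linear predictors stay strictly inside (0, 1)
    m2 = FittedLogisticModel(
        term_names=["intercept", "x"],
        coefficients=np.array([0.0, 100.0]),
        covariance=np.eye(2),
        log_likelihood=-1.0,
        n_obs=10,
        n_events=5,
        converged=True,
    )
    p = predict_proba(m2, np.array([[1.0, 1e6], [1.0, -1e6]]))
    assert 0 < p[1] <= 1e-12 and 1 - 1e-12 <= p[0] < 1
    with pytest.raises(PatternRiskError):
        predict_proba(m2, np.array([[1.0, np.nan]]))


def test_predict_proba_monotone_in_positive_coefficient():
    X, y = _sim(7, n=400, p=1)
    m = fit_logistic(X, y)
    sign = np.sign(m.coefficients[1])
    grid = np.column_stack([np.ones(50), np.linspace(-3, 3, 50)])
    p = predict_proba(m, grid)
    assert np.all(np.diff(p) * sign > 0)


def test_bic_definition_arithmetic():
    m = FittedLogisticModel(
        term_names=["a", "b", "c"],
        coefficients=np.zeros(3),
        covariance=np.eye(3),
        log_likelihood=-10.0,
        n_obs=100,
        n_events=40,
        converged=True,
    )
    assert bic(m) == pytest.approx(20 + 3 * np.log(100))
    m.converged = False
    with pytest.raises(PatternRiskError):
        bic(m)


def test_bic_penalises_pure_noise_term():
    rng = np.random.default_rng(21)
    n = 800
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    y = (rng.random(n) < expit(-0.2 + x)).astype(float)
    base = fit_logistic(np.column_stack([np.ones(n), x]), y)
    bigger = fit_logistic(np.column_stack([np.ones(n), x, noise]), y)
    assert bic(bigger) > bic(base)


def test_fixed_odds_ratio_model_psa_doubling():
    """With the 2-factor deployment model pinned to OR 1.72 per PSA doubling,
    two patients differing only in PSA 4 vs 8 have predicted odds ratio 1.72."""
    m = FittedLogisticModel(
        term_names=["intercept", "psa_log2", "age"],
        coefficients=np.array([-4.0, np.log(1.72), np.log(1.05)]),
        covariance=np.eye(3),
        log_likelihood=-1.0,
        n_obs=100,
        n_events=30,
        converged=True,
    )
    p4 = predict_proba(m, np.array([[1.0, 2.0, 65.0]]))[0]
    p8 = predict_proba(m, np.array([[1.0, 3.0, 65.0]]))[0]
    odds_ratio = (p8 / (1 - p8)) / (p4 / (1 - p4))
    assert odds_ratio == pytest.approx(1.72, abs=1e-10)


# ---------------------------------------------------------------------------
# stepwise BIC
# ---------------------------------------------------------------------------


def _exhaustive_best_bic(X_main, y, factor_terms):
    best = np.inf
    for r in range(len(factor_terms) + 1):
        for sub in itertools.combinations(sorted(factor_terms), r):
            idx = [0] + [i for f in sub for i in factor_terms[f]]
            Xs = X_main[:, idx]
            try:
                m = fit_logistic(Xs, y, check_min_size=False)
            except (SeparationError, DegenerateOutcomeError):
                continue
            best = min(best, -2 * m.log_likelihood + Xs.shape[1] * np.log(len(y)))
    return best


def test_stepwise_no_candidates_returns_intercept_only():
    rng = np.random.default_rng(0)
    n = 200
    X = np.ones((n, 1))
    y = (rng.random(n) < 0.4).astype(float)
    res = stepwise_bic(X, y, {}, allow_interactions=True)
    assert res.selected_factors == ()
    assert res.model.term_names == ["intercept"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_stepwise_matches_exhaustive_search(seed):
    """On <=4 main-effect candidates the stepwise local optimum equals the
    global BIC optimum (no interactions, so the spaces coincide)."""
    rng = np.random.default_rng(seed)
    n = 2000
    Z = rng.standard_normal((n, 4))
    y = (rng.random(n) < expit(-0.3 + 1.0 * Z[:, 0])).astype(float)
    X = np.column_stack([np.ones(n), Z])
    ft = {f"f{j}": [j + 1] for j in range(4)}
    res = stepwise_bic(X, y, ft, allow_interactions=False)
    assert res.selected_factors == ("f0",)
    assert res.bic == pytest.approx(_exhaustive_best_bic(X, y, ft), abs=1e-9)


def test_stepwise_interaction_hierarchy():
    """Interactions only appear with both parent main effects present, and
    are recovered when truly generating the outcome."""
    rng = np.random.default_rng(5)
    n = 4000
    a, b = rng.standard_normal(n), rng.standard_normal(n)
    y = (rng.random(n) < expit(0.5 * a + 0.5 * b + 1.2 * a * b - 0.2)).astype(float)
    X = np.column_stack([np.ones(n), a, b])
    res = stepwise_bic(X, y, {"a": [1], "b": [2]}, allow_interactions=True)
    for pa, pb in res.selected_interactions:
        assert pa in res.selected_factors and pb in res.selected_factors
    assert ("a", "b") in res.selected_interactions
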