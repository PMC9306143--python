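"""Logistic regression core: IRLS fitting, prediction, BIC, stepwise search.

All six missing-data strategies reduce to (possibly many) maximum-likelihood
logistic fits, so the fitter is deliberately small and fast: Fisher scoring /
IRLS with step-halving, convergence on the score (max |X'(y-p)| < 1e-8, so an
intercept model satisfies the score equation essentially exactly — the basis
of the calibration-in-the-large identity on training data), covariance from
the inverse observed information.  Perfect separation surfaces as an explicit
error carrying the diverging terms; callers (e.g. the cohort ensemble) decide
whether to skip.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import (
    DegenerateOutcomeError,
    InsufficientDataError,
    PatternRiskError,
    SeparationError,
)

__all__ = [
    "FittedLogisticModel",
    "fit_logistic",
    "predict_proba",
    "bic",
    "stepwise_bic",
    "MIN_N_OBS",
    "MIN_EVENTS",
]

# minimum fit size: deliberately permissive because small cohorts are kept,
# not excluded, when building cohort-specific models
MIN_N_OBS = 25
MIN_EVENTS = 5

_SCORE_TOL = 1e-8
_LL_TOL = 1e-10
_MAX_ABS_COEF = 40.0  # |log-odds| beyond this is treated as separation
_ETA_CLIP = 36.0  # keeps probabilities inside (~2e-16, 1-2e-16)
_PROB_FLOOR = 1e-12


@dataclass
class FittedLogisticModel:
    """A converged maximum-likelihood logistic fit."""

    term_names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_obs: int
    n_events: int
    converged: bool
    pattern: object = None  # MissingnessPattern of the serving strategy
    coding: str = "raw"

    def __post_init__(self):
        p = len(self.term_names)
        if self.coefficients.shape != (p,):
            raise ValueError("coefficient length does not match terms")
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match terms")

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.term_names.index(term)])

    def odds_ratios(self) -> dict[str, float]:
        return {t: float(np.exp(b)) for t, b in zip(self.term_names, self.coefficients)}

    def to_dict(self) -> dict:
        return {
            "term_names": list(self.term_names),
            "coefficients": [float(b) for b in self.coefficients],
            "covariance": [[float(v) for v in row] for row in self.covariance],
            "log_likelihood": float(self.log_likelihood),
            "n_obs": int(self.n_obs),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
            "coding": self.coding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedLogisticModel":
        return cls(
            term_names=list(d["term_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            n_obs=int(d["n_obs"]),
            n_events=int(d["n_events"]),
            converged=bool(d["converged"]),
            coding=d.get("coding", "raw"),
        )


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    # log-lik in the numerically stable log1p(exp) form
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    term_names: list[str] | None = None,
    *,
    ridge: float = 0.0,
    max_iter: int = 100,
    check_min_size: bool = True,
) -> FittedLogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    ``X`` must contain the intercept column if one is wanted.  Convergence:
    max absolute score component < 1e-8, or relative log-likelihood change
    < 1e-10 once the score is already small.  ``ridge`` adds a tiny lambda*I
    stabiliser to the information matrix (off by default; used for degenerate
    conditionals inside imputation chains).

    Raises
    ------
    DegenerateOutcomeError   if only one outcome class is present
    InsufficientDataError    if below the minimum fit size
    SeparationError          if coefficients diverge (perfect separation)
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    n_events = int(y.sum())
    if n_events == 0 or n_events == n:
        raise DegenerateOutcomeError(
            f"all {n} outcomes are {int(y[0]) if n else '?'}; cannot fit"
        )
    if check_min_size and (n < MIN_N_OBS or n_events < MIN_EVENTS or n - n_events < MIN_EVENTS):
        raise InsufficientDataError(
            f"n={n}, events={n_events}: below minimum fit size "
            f"(n>={MIN_N_OBS}, events and non-events >={MIN_EVENTS})"
        )

    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    info = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        if ridge:
            info = info + ridge * np.eye(p)
        max_score = float(np.max(np.abs(score)))
        if max_score < _SCORE_TOL:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix: {exc}", terms=term_names
            ) from exc
        # step-halving to guarantee likelihood ascent
        step = 1.0
        for _half in range(30):
            cand = beta + step * delta
            ll_new = _loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            big = [t for t, b in zip(term_names, beta) if abs(b) > _MAX_ABS_COEF]
            raise SeparationError(
                "coefficients diverging; data are (quasi-)separated", terms=big
            )
        if abs(ll_new - ll) <= _LL_TOL * (abs(ll) + 1.0) and max_score < 1e-4:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        if float(np.max(np.abs(X.T @ (y - mu)))) < 1e-5:
            converged = True  # flat likelihood, score numerically small
        else:
            raise SeparationError(
                f"IRLS did not converge in {max_iter} iterations", terms=term_names
            )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("information matrix not invertible", terms=term_names) from exc
    return FittedLogisticModel(
        term_names=list(term_names),
        coefficients=beta,
        covariance=cov,
        log_likelihood=_loglik(X, y, beta),
        n_obs=n,
        n_events=n_events,
        converged=True,
    )


def predict_proba(model: FittedLogisticModel, X: np.ndarray) -> np.ndarray:
    """Inverse-logit of the linear predictor, strictly inside (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.term_names):
        raise PatternRiskError(
            f"row has {X.shape[1]} terms, model expects {len(model.term_names)}"
        )
    if np.isnan(X).any():
        raise PatternRiskError(
            "missing term value at prediction; recode or impute upstream"
        )
    p = expit(X @ model.coefficients)
    return np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)


def bic(model: FittedLogisticModel) -> float:
    """-2 log L + p log n, with p the number of estimated coefficients
    (intercept included).  Within one dataset the intercept convention only
    shifts every candidate by a constant, so model ranking is unaffected."""
    if not model.converged:
        raise PatternRiskError("BIC requested for a non-converged model")
    p = len(model.term_names)
    return -2.0 * model.log_likelihood + p * np.log(model.n_obs)


# ---------------------------------------------------------------------------
# Stepwise BIC search with two-way interactions
# ---------------------------------------------------------------------------


def _fast_bic(X: np.ndarray, y: np.ndarray) -> float:
    """BIC of a fit without covariance bookkeeping (search inner loop)."""
    m = fit_logistic(X, y, check_min_size=False)
    return -2.0 * m.log_likelihood + X.shape[1] * np.log(X.shape[0])


@dataclass
class StepwiseResult:
    model: FittedLogisticModel
    selected_factors: tuple[str, ...]
    selected_interactions: tuple[tuple[str, str], ...]
    bic: float
    path: list[tuple[str, float]] = field(default_factory=list)


def stepwise_bic(
    X_main: np.ndarray,
    y: np.ndarray,
    factor_terms: dict[str, list[int]],
    *,
    allow_interactions: bool = True,
    column_names: list[str] | None = None,
) -> StepwiseResult:
    """Bidirectional stepwise model selection minimising BIC.

    ``X_main`` holds the intercept (column 0) and all candidate main-effect
    columns; ``factor_terms`` maps each candidate factor to its column
    indices.  The search starts from the full main-effects model, considers
    one add/drop move per step (two-way interactions only, and only while
    both parent main effects are in the model; dropping a main effect
    cascades to its interactions) and takes the move with the largest BIC
    decrease, ties broken by term-name order.  Stops at a local minimum.
    """
    factors = sorted(factor_terms)
    n = X_main.shape[0]
    if column_names is None:
        column_names = [f"c{j}" for j in range(X_main.shape[1])]

    def interaction_cols(a: str, b: str) -> np.ndarray:
        cols = []
        for i in factor_terms[a]:
            for j in factor_terms[b]:
                cols.append(X_main[:, i] * X_main[:, j])
        return np.column_stack(cols) if cols else np.empty((n, 0))

    def design(mains: tuple[str, ...], inters: tuple[tuple[str, str], ...]):
        idx = [0] + [i for f in mains for i in factor_terms[f]]
        blocks = [X_main[:, idx]]
        names = ["intercept"] + [f"main:{f}:{i}" for f in mains for i in factor_terms[f]]
        for a, b in inters:
            blocks.append(interaction_cols(a, b))
            names += [f"int:{a}*{b}:{k}" for k in range(blocks[-1].shape[1])]
        return np.column_stack(blocks), names

    cache: dict[tuple, float] = {}

    def score_state(mains, inters) -> float:
        key = (mains, inters)
        if key not in cache:
            Xd, _ = design(mains, inters)
            try:
                cache[key] = _fast_bic(Xd, y)
            except (SeparationError, DegenerateOutcomeError):
                cache[key] = np.inf
        return cache[key]

    mains: tuple[str, ...] = tuple(factors)
    inters: tuple[tuple[str, str], ...] = ()
    current = score_state(mains, inters)
    path = [("start", current)]

    while True:
        moves: list[tuple[str, tuple, tuple]] = []
        # add a main effect not in the model
        for f in factors:
            if f not in mains:
                moves.append((f"+{f}", tuple(sorted(mains + (f,))), inters))
        # drop a main effect (cascading its interactions)
        for f in mains:
            new_mains = tuple(m for m in mains if m != f)
            new_inters = tuple(t for t in inters if f not in t)
            moves.append((f"-{f}", new_mains, new_inters))
        if allow_interactions:
            for a, b in itertools.combinations(sorted(mains), 2):
                if (a, b) not in inters:
                    moves.append((f"+{a}*{b}", mains, tuple(sorted(inters + ((a, b),)))))
            for a, b in inters:
                moves.append((f"-{a}*{b}", mains, tuple(t for t in inters if t != (a, b))))

        best_label, best_bic, best_state = None, current, (mains, inters)
        for label, m2, i2 in sorted(moves, key=lambda mv: mv[0]):
            b = score_state(m2, i2)
            if b < best_bic - 1e-9:
                best_label, best_bic, best_state = label, b, (m2, i2)
        if best_label is None:
            break
        mains, inters = best_state
        current = best_bic
        path.append((best_label, current))

    Xd, _ = design(mains, inters)
    term_names = ["intercept"]
    for f in mains:
        term_names += [column_names[i] for i in factor_terms[f]]
    for a, b in inters:
        term_names += [
            f"{column_names[i]}*{column_names[j]}"
            for i in factor_terms[a]
            for j in factor_terms[b]
        ]
    model = fit_logistic(Xd, y, term_names, check_min_size=False)
    return StepwiseResult(
        model=model,
        selected_factors=mains,
        selected_interactions=inters,
        bic=current,
        path=path,
    )
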