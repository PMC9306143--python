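"""The six missing-data strategies behind one fit/predict contract.

Each strategy maps (training multi-cohort data, query missingness pattern)
to a prediction engine tailored to that pattern:

``available_cases``
    Pool records complete on the query pattern across cohorts, fit a
    main-effects logistic model (the "2^k submodels" method).
``iterative_bic``
    Available cases plus bidirectional stepwise BIC selection with two-way
    interactions; whenever a factor is dropped entirely the procedure
    restarts on the larger pool complete on the surviving factors.
``cohort_ensemble``
    One model per cohort on the intersection of the query pattern with the
    cohort's available factors (measured in >= 40% of participants);
    prediction is the unweighted mean of per-cohort risks.
``categorization``
    One model on *all* records: continuous prostate volume stratified to
    < 30 / 30-50 / > 50 cc plus "missing"; every optional factor gains an
    explicit missing level; the jointly-collected family-history pair is
    combined into a single factor to avoid collinear missing indicators.
``missing_indicator``
    As categorization, except volume stays continuous with a missing
    indicator and a zero-filled value term (their product with the
    indicator's complement).
``imputation``
    MICE on the pooled training set (30 imputations x 10 cycles), one full
    12-factor fit per completed dataset, coefficients pooled by averaging
    (Rubin point estimate); at prediction, missing user inputs are filled
    with training-set marginals (mean for continuous, modal level for
    binary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    FAMILY_HISTORY_PAIR,
    CohortDataset,
    FactorSpec,
    MissingnessPattern,
    MultiCohortDataset,
    RiskFactorSchema,
    complete_case_subset,
    encode_design,
)
from .errors import (
    DegenerateOutcomeError,
    EncodingError,
    EnsembleEmptyError,
    FamilyHistoryConsistencyError,
    InsufficientDataError,
    PatternRiskError,
    SeparationError,
    ValidationDataError,
)
from .glm import FittedLogisticModel, fit_logistic, predict_proba, stepwise_bic
from .mice import DEFAULT_CYCLES, DEFAULT_M, mice_impute

__all__ = [
    "PatternModel",
    "available_cases_fit",
    "iterative_bic_fit",
    "cohort_ensemble_fit",
    "categorization_fit",
    "missing_indicator_fit",
    "imputation_fit",
    "fit_strategy",
    "predict_for_patient",
    "categorize_volume",
    "combine_family_history",
    "encode_with_missing_levels",
    "STRATEGY_NAMES",
    "PATTERN_DEPENDENT",
    "ENSEMBLE_AVAILABILITY_THRESHOLD",
    "VOLUME_BREAKS",
]

STRATEGY_NAMES = (
    "available_cases",
    "iterative_bic",
    "cohort_ensemble",
    "categorization",
    "missing_indicator",
    "imputation",
)

#: strategies whose fitted model depends on the query pattern (the other
#: three fit one model on all data and adapt only at prediction time)
PATTERN_DEPENDENT = frozenset({"available_cases", "iterative_bic", "cohort_ensemble"})

#: a factor counts as available in a cohort if measured in >= 40% of records
ENSEMBLE_AVAILABILITY_THRESHOLD = 0.40

#: prostate-volume strata (cc); both breakpoints belong to the middle stratum
VOLUME_BREAKS = (30.0, 50.0)
VOLUME_LEVELS = ("lt30", "30to50", "gt50", "missing")
FAMILY_HISTORY_LEVELS = ("none", "pca2_only", "bca1_only", "both", "missing")


# ---------------------------------------------------------------------------
# Recoding operations
# ---------------------------------------------------------------------------


def categorize_volume(value) -> str:
    """Stratify prostate volume: < 30, [30, 50], > 50 cc, or missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "missing"
    v = float(value)
    if v <= 0:
        raise ValidationDataError(f"prostate volume must be > 0 cc, got {v}")
    if v < VOLUME_BREAKS[0]:
        return "lt30"
    if v <= VOLUME_BREAKS[1]:
        return "30to50"
    return "gt50"


def combine_family_history(second_degree_pca, first_degree_bca) -> str:
    """Combine the jointly-collected family-history pair into one factor.

    The two inputs (0/1/NaN) must be jointly observed or jointly missing --
    cohorts collect them together or not at all, and separate missing
    indicators would be collinear.
    """
    m2 = second_degree_pca is None or (
        isinstance(second_degree_pca, float) and math.isnan(second_degree_pca)
    )
    m1 = first_degree_bca is None or (
        isinstance(first_degree_bca, float) and math.isnan(first_degree_bca)
    )
    if m2 != m1:
        raise FamilyHistoryConsistencyError(
            "second-degree prostate and first-degree breast family history "
            "must be jointly observed or jointly missing"
        )
    if m2:
        return "missing"
    p2, b1 = int(second_degree_pca), int(first_degree_bca)
    return {(0, 0): "none", (1, 0): "pca2_only", (0, 1): "bca1_only", (1, 1): "both"}[(p2, b1)]


def _has_family_pair(schema: RiskFactorSchema) -> bool:
    return all(f in schema for f in FAMILY_HISTORY_PAIR)


def encode_with_missing_levels(frame: pd.DataFrame, schema: RiskFactorSchema, coding: str):
    """Encode all factors with explicit missing levels (no row exclusion).

    Returns ``(X, term_names, factor_of_term)``.  Mandatory factors stay
    continuous/binary (they are never missing).  Optional binaries get a
    non-reference dummy (0 when missing) plus a missing dummy.  Prostate
    volume is stratified (``categorized``) or given a missing indicator with
    a zero-filled log2 value term (``missing_indicator``).  The
    family-history pair is coded additively -- one main effect each, "both"
    activating both, plus a single shared missing dummy -- so that with fully
    complete data the coding collapses exactly onto the raw binary coding.
    """
    if coding not in ("categorized", "missing_indicator"):
        raise ValueError(f"unknown coding {coding!r}")
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    factor_of: list[str] = ["intercept"]
    pair = FAMILY_HISTORY_PAIR if _has_family_pair(schema) and not schema[FAMILY_HISTORY_PAIR[0]].mandatory else ()
    pair_done = False

    def add(col, name, factor):
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
        factor_of.append(factor)

    for spec in schema.factors:
        v = frame[spec.name].to_numpy(dtype=float)
        miss = np.isnan(v)
        if spec.mandatory:
            if miss.any():
                raise EncodingError(f"mandatory factor {spec.name} has missing values")
            if spec.kind == "continuous":
                t = np.log2(v) if spec.transform == "log2" else v
                add(t, f"{spec.name}_log2" if spec.transform == "log2" else spec.name, spec.name)
            else:
                add(v, f"{spec.name}_{spec.levels[1]}", spec.name)
            continue
        if spec.name in pair:
            if pair_done:
                continue
            v2 = frame[pair[0]].to_numpy(dtype=float)
            v1 = frame[pair[1]].to_numpy(dtype=float)
            m2, m1 = np.isnan(v2), np.isnan(v1)
            if (m2 != m1).any():
                bad = int(np.nonzero(m2 != m1)[0][0])
                raise FamilyHistoryConsistencyError(
                    f"row {bad}: family-history pair half-missing"
                )
            add(np.where(m2, 0.0, v2), f"{pair[0]}_yes", pair[0])
            add(np.where(m1, 0.0, v1), f"{pair[1]}_yes", pair[1])
            add(m2.astype(float), "famhx_missing", pair[0])
            pair_done = True
            continue
        if spec.kind == "binary":
            add(np.where(miss, 0.0, v), f"{spec.name}_{spec.levels[1]}", spec.name)
            add(miss.astype(float), f"{spec.name}_missing", spec.name)
        elif spec.kind == "categorical":
            ints = np.where(miss, -1, v).astype(int)
            for j, lev in enumerate(spec.levels[1:], start=1):
                add((ints == j).astype(float), f"{spec.name}_{lev}", spec.name)
            add(miss.astype(float), f"{spec.name}_missing", spec.name)
        else:  # optional continuous
            if spec.name != "volume":
                raise EncodingError(
                    f"no stratification rule for optional continuous factor {spec.name}"
                )
            if coding == "categorized":
                levels = np.array([categorize_volume(x) for x in v])
                for lev in ("30to50", "gt50", "missing"):
                    add((levels == lev).astype(float), f"volume_{lev}", "volume")
            else:
                if np.any(v[~miss] <= 0):
                    raise EncodingError("volume must be > 0 cc")
                add(np.where(miss, 0.0, np.log2(np.where(miss, 1.0, v))), "volume_log2", "volume")
                add(miss.astype(float), "volume_missing", "volume")
    return np.column_stack(cols), names, factor_of


# ---------------------------------------------------------------------------
# Patient value handling
# ---------------------------------------------------------------------------


def _clean_values(values, schema: RiskFactorSchema) -> dict[str, float]:
    """Validate raw user inputs; returns name -> float with NaN for missing."""
    out: dict[str, float] = {}
    unknown = set(values) - set(schema.factor_names)
    if unknown:
        raise ValidationDataError(f"unknown risk factors supplied: {sorted(unknown)}")
    for spec in schema.factors:
        v = values.get(spec.name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            if spec.mandatory:
                raise ValidationDataError(f"mandatory factor {spec.name} not supplied")
            out[spec.name] = float("nan")
            continue
        v = float(v)
        if spec.kind == "binary" and v not in (0.0, 1.0):
            raise ValidationDataError(f"{spec.name} must be 0/1, got {v}")
        if spec.kind == "continuous" and spec.transform == "log2" and v <= 0:
            raise ValidationDataError(f"{spec.name} must be > 0, got {v}")
        if spec.name == "age" and not (18.0 <= v <= 120.0):
            raise ValidationDataError(f"age outside [18, 120]: {v}")
        out[spec.name] = v
    return out


def _encode_factor_value(spec: FactorSpec, v: float) -> list[float]:
    if math.isnan(v):
        raise PatternRiskError(
            f"factor {spec.name} is required by this model but was not supplied"
        )
    if spec.kind == "continuous":
        return [math.log2(v) if spec.transform == "log2" else v]
    if spec.kind == "binary":
        return [v]
    levels = spec.levels
    return [1.0 if int(v) == j else 0.0 for j in range(1, len(levels))]


def _raw_row(values: dict[str, float], schema: RiskFactorSchema, factors) -> np.ndarray:
    row = [1.0]
    for name in schema.factor_names:
        if name in factors:
            row.extend(_encode_factor_value(schema[name], values[name]))
    return np.array(row)


# ---------------------------------------------------------------------------
# Pattern models
# ---------------------------------------------------------------------------


@dataclass
class PatternModel:
    """Common surface of all six strategies: metadata + ``predict``."""

    strategy: str
    schema: RiskFactorSchema
    query_pattern: MissingnessPattern
    effective_pattern: MissingnessPattern
    notes: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        raise NotImplementedError

    @property
    def n_cohorts(self) -> int:
        raise NotImplementedError

    def predict(self, values) -> float:
        raise NotImplementedError

    def unused_factors(self, values) -> tuple[str, ...]:
        """Supplied factors that do not influence this model's prediction."""
        supplied = {
            k
            for k, v in values.items()
            if v is not None and not (isinstance(v, float) and math.isnan(v))
        }
        return tuple(sorted(supplied - self.effective_pattern.observed))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict, schema: RiskFactorSchema) -> "PatternModel":
        cls = _MODEL_CLASSES[d["strategy"]]
        return cls._from_dict(d, schema)

    def _base_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "query_pattern": list(self.query_pattern.key()),
            "effective_pattern": list(self.effective_pattern.key()),
            "notes": list(self.notes),
        }

    @classmethod
    def _base_kwargs(cls, d: dict, schema: RiskFactorSchema) -> dict:
        return {
            "strategy": d["strategy"],
            "schema": schema,
            "query_pattern": MissingnessPattern.from_factors(d["query_pattern"], schema),
            "effective_pattern": MissingnessPattern.from_factors(d["effective_pattern"], schema),
            "notes": list(d.get("notes", [])),
        }


@dataclass
class AvailableCasesModel(PatternModel):
    model: FittedLogisticModel = None
    contributing_cohorts: int = 0

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_cohorts(self) -> int:
        return self.contributing_cohorts

    def predict(self, values) -> float:
        vals = _clean_values(values, self.schema)
        row = _raw_row(vals, self.schema, self.effective_pattern.observed)
        return float(predict_proba(self.model, row)[0])

    def to_dict(self) -> dict:
        d = self._base_dict()
        d["model"] = self.model.to_dict()
        d["contributing_cohorts"] = self.contributing_cohorts
        return d

    @classmethod
    def _from_dict(cls, d, schema):
        return cls(
            **cls._base_kwargs(d, schema),
            model=FittedLogisticModel.from_dict(d["model"]),
            contributing_cohorts=int(d["contributing_cohorts"]),
        )


def available_cases_fit(
    training: MultiCohortDataset, pattern: MissingnessPattern
) -> AvailableCasesModel:
    """Pool complete cases on the pattern across cohorts; fit main effects."""
    schema = training.schema
    df = complete_case_subset(training, pattern)
    if df.empty:
        raise InsufficientDataError(
            f"no complete cases for pattern {pattern.key()}"
        )
    X, names = encode_design(df, schema, pattern, "raw")
    y = df["outcome"].to_numpy(dtype=float)
    try:
        model = fit_logistic(X, y, names)
    except (InsufficientDataError, DegenerateOutcomeError) as exc:
        raise InsufficientDataError(
            f"pattern {pattern.key()}: {exc}"
        ) from exc
    model.pattern = pattern
    return AvailableCasesModel(
        strategy="available_cases",
        schema=schema,
        query_pattern=pattern,
        effective_pattern=pattern,
        model=model,
        contributing_cohorts=int(df["cohort_id"].nunique()),
    )


@dataclass
class IterativeBICModel(PatternModel):
    model: FittedLogisticModel = None
    mains: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    contributing_cohorts: int = 0
    n_restarts: int = 0

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_cohorts(self) -> int:
        return self.contributing_cohorts

    def predict(self, values) -> float:
        vals = _clean_values(values, self.schema)
        enc = {f: _encode_factor_value(self.schema[f], vals[f]) for f in self.mains}
        row = [1.0]
        for f in self.mains:
            row.extend(enc[f])
        for a, b in self.interactions:
            row.extend(x * z for x in enc[a] for z in enc[b])
        return float(predict_proba(self.model, np.array(row))[0])

    def to_dict(self) -> dict:
        d = self._base_dict()
        d["model"] = self.model.to_dict()
        d["mains"] = list(self.mains)
        d["interactions"] = [list(t) for t in self.interactions]
        d["contributing_cohorts"] = self.contributing_cohorts
        d["n_restarts"] = self.n_restarts
        return d

    @classmethod
    def _from_dict(cls, d, schema):
        return cls(
            **cls._base_kwargs(d, schema),
            model=FittedLogisticModel.from_dict(d["model"]),
            mains=tuple(d["mains"]),
            interactions=tuple(tuple(t) for t in d["interactions"]),
            contributing_cohorts=int(d["contributing_cohorts"]),
            n_restarts=int(d.get("n_restarts", 0)),
        )


MAX_BIC_RESTARTS = 12


def iterative_bic_fit(
    training: MultiCohortDataset,
    pattern: MissingnessPattern,
    *,
    allow_interactions: bool = True,
) -> IterativeBICModel:
    """Stepwise-BIC selection with restarts on the growing complete-case pool.

    Whenever the stepwise search drops a factor entirely, the candidate set
    shrinks to the selected factors and the search restarts on the (weakly
    larger) pool complete on the survivors; terminates at a fixed point or
    after 12 rounds.
    """
    schema = training.schema
    candidates = set(pattern.observed)
    restarts = 0
    history: list[frozenset] = []
    while True:
        pool_pattern = MissingnessPattern.from_factors(candidates, schema)
        df = complete_case_subset(training, pool_pattern)
        if df.empty:
            raise InsufficientDataError(f"no complete cases for pattern {pool_pattern.key()}")
        X, names = encode_design(df, schema, pool_pattern, "raw")
        y = df["outcome"].to_numpy(dtype=float)
        # map candidate factors to design columns (raw: schema order)
        factor_terms: dict[str, list[int]] = {}
        idx = 1
        for f in pool_pattern.ordered(schema):
            width = len(_encode_factor_value(schema[f], 1.0)) if schema[f].kind != "continuous" else 1
            if f in candidates:
                factor_terms[f] = list(range(idx, idx + width))
            idx += width
        if (df["outcome"].sum() < 5) or (len(df) - df["outcome"].sum() < 5) or len(df) < 25:
            raise InsufficientDataError(
                f"pattern {pool_pattern.key()}: pool of {len(df)} below minimum fit size"
            )
        try:
            res = stepwise_bic(
                X, y, factor_terms, allow_interactions=allow_interactions, column_names=names
            )
        except (DegenerateOutcomeError, SeparationError) as exc:
            raise InsufficientDataError(f"pattern {pool_pattern.key()}: {exc}") from exc
        selected = frozenset(res.selected_factors)
        if selected == frozenset(candidates) or restarts >= MAX_BIC_RESTARTS or selected in history:
            break
        history.append(frozenset(candidates))
        candidates = set(selected)
        restarts += 1
    model = res.model
    model.pattern = pattern
    effective = MissingnessPattern.from_factors(selected, schema)
    return IterativeBICModel(
        strategy="iterative_bic",
        schema=schema,
        query_pattern=pattern,
        effective_pattern=effective,
        model=model,
        mains=res.selected_factors,
        interactions=res.selected_interactions,
        contributing_cohorts=int(df["cohort_id"].nunique()),
        n_restarts=restarts,
    )


@dataclass
class CohortEnsembleModel(PatternModel):
    members: list[tuple[str, MissingnessPattern, FittedLogisticModel]] = field(
        default_factory=list
    )
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return sum(m.n_obs for _, _, m in self.members)

    @property
    def n_cohorts(self) -> int:
        return len(self.members)

    def predict(self, values) -> float:
        vals = _clean_values(values, self.schema)
        risks = []
        for _, cpat, model in self.members:
            row = _raw_row(vals, self.schema, cpat.observed)
            risks.append(float(predict_proba(model, row)[0]))
        return float(np.mean(risks))

    def member_risks(self, values) -> dict[str, float]:
        vals = _clean_values(values, self.schema)
        return {
            cid: float(predict_proba(model, _raw_row(vals, self.schema, cpat.observed))[0])
            for cid, cpat, model in self.members
        }

    def to_dict(self) -> dict:
        d = self._base_dict()
        d["members"] = [
            {"cohort_id": cid, "pattern": list(p.key()), "model": m.to_dict()}
            for cid, p, m in self.members
        ]
        d["skipped"] = [list(t) for t in self.skipped]
        return d

    @classmethod
    def _from_dict(cls, d, schema):
        members = [
            (
                e["cohort_id"],
                MissingnessPattern.from_factors(e["pattern"], schema),
                FittedLogisticModel.from_dict(e["model"]),
            )
            for e in d["members"]
        ]
        return cls(
            **cls._base_kwargs(d, schema),
            members=members,
            skipped=[tuple(t) for t in d.get("skipped", [])],
        )


def cohort_ensemble_fit(
    training: MultiCohortDataset, pattern: MissingnessPattern
) -> CohortEnsembleModel:
    """Per-cohort models on (query pattern) ∩ (cohort availability); mean risk.

    Cohorts failing the minimum-size or separation checks are skipped with a
    warning; if every cohort is skipped the ensemble is empty and errors.
    """
    schema = training.schema
    members, skipped = [], []
    for cohort in training.cohorts:
        frac_measured = cohort.frame[list(schema.factor_names)].notna().mean()
        avail = {
            f
            for f in pattern.observed
            if frac_measured[f] >= ENSEMBLE_AVAILABILITY_THRESHOLD
        }
        cpat = MissingnessPattern.from_factors(avail, schema)
        cols = [f for f in schema.factor_names if f in cpat]
        sub = cohort.frame[cohort.frame[cols].notna().all(axis=1)].reset_index(drop=True)
        try:
            if sub.empty:
                raise InsufficientDataError("no complete cases")
            X, names = encode_design(sub, schema, cpat, "raw")
            model = fit_logistic(X, sub["outcome"].to_numpy(dtype=float), names)
        except (InsufficientDataError, DegenerateOutcomeError, SeparationError) as exc:
            skipped.append((cohort.cohort_id, str(exc)))
            warnings.warn(
                f"cohort {cohort.cohort_id} skipped from ensemble: {exc}",
                stacklevel=2,
            )
            continue
        model.pattern = cpat
        members.append((cohort.cohort_id, cpat, model))
    if not members:
        raise EnsembleEmptyError(
            f"every cohort skipped for pattern {pattern.key()}: {skipped}"
        )
    effective = MissingnessPattern.from_factors(
        set().union(*(p.observed for _, p, _ in members)), schema
    )
    return CohortEnsembleModel(
        strategy="cohort_ensemble",
        schema=schema,
        query_pattern=pattern,
        effective_pattern=effective,
        members=members,
        skipped=skipped,
    )


@dataclass
class _AllDataModel(PatternModel):
    """Shared machinery for the categorization / missing-indicator engines."""

    model: FittedLogisticModel = None
    all_terms: list[str] = field(default_factory=list)
    factor_of: list[str] = field(default_factory=list)
    kept: list[int] = field(default_factory=list)
    dropped_terms: list[str] = field(default_factory=list)
    contributing_cohorts: int = 0
    coding: str = "categorized"

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_cohorts(self) -> int:
        return self.contributing_cohorts

    def _patient_frame(self, values) -> tuple[pd.DataFrame, list[str]]:
        vals = _clean_values(values, self.schema)
        notes = []
        if _has_family_pair(self.schema):
            a, b = FAMILY_HISTORY_PAIR
            if math.isnan(vals[a]) != math.isnan(vals[b]):
                supplied = a if not math.isnan(vals[a]) else b
                notes.append(
                    f"{supplied} ignored: family-history pair must be supplied together"
                )
                vals[a] = vals[b] = float("nan")
        return pd.DataFrame([vals]), notes

    def predict(self, values) -> float:
        frame, _ = self._patient_frame(values)
        X, names, factor_of = encode_with_missing_levels(frame, self.schema, self.coding)
        # a level unseen in training has no coefficient: remap its factor to
        # the missing level rather than silently treating it as reference
        dropped = set(self.dropped_terms)
        for _ in range(len(dropped) + 1):
            hit = next(
                (
                    j
                    for j, name in enumerate(names)
                    if name in dropped
                    and X[0, j] != 0.0
                    and not name.endswith("_missing")
                ),
                None,
            )
            if hit is None:
                break
            frame.loc[0, factor_of[hit]] = np.nan
            warnings.warn(
                f"level {names[hit]} unseen in training; treated as missing",
                stacklevel=2,
            )
            X, names, factor_of = encode_with_missing_levels(
                frame, self.schema, self.coding
            )
        row = X[0, self.kept]
        return float(predict_proba(self.model, row)[0])

    def unused_factors(self, values) -> tuple[str, ...]:
        _, notes = self._patient_frame(values)
        out = set(super().unused_factors(values))
        for n in notes:
            out.add(n.split()[0])
        return tuple(sorted(out))

    def to_dict(self) -> dict:
        d = self._base_dict()
        d.update(
            model=self.model.to_dict(),
            all_terms=list(self.all_terms),
            factor_of=list(self.factor_of),
            kept=[int(i) for i in self.kept],
            dropped_terms=list(self.dropped_terms),
            contributing_cohorts=self.contributing_cohorts,
            coding=self.coding,
        )
        return d

    @classmethod
    def _from_dict(cls, d, schema):
        return cls(
            **cls._base_kwargs(d, schema),
            model=FittedLogisticModel.from_dict(d["model"]),
            all_terms=list(d["all_terms"]),
            factor_of=list(d["factor_of"]),
            kept=[int(i) for i in d["kept"]],
            dropped_terms=list(d["dropped_terms"]),
            contributing_cohorts=int(d["contributing_cohorts"]),
            coding=d["coding"],
        )


class CategorizationModel(_AllDataModel):
    pass


class MissingIndicatorModel(_AllDataModel):
    pass


def _all_data_fit(
    training: MultiCohortDataset,
    pattern: MissingnessPattern,
    coding: str,
    cls,
    strategy: str,
):
    schema = training.schema
    pooled = training.pooled()
    X, names, factor_of = encode_with_missing_levels(pooled, schema, coding)
    # constant non-intercept columns (e.g. an empty level) carry no information
    keep, dropped = [0], []
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            dropped.append(names[j])
        else:
            keep.append(j)
    if dropped:
        warnings.warn(
            f"{strategy}: dropped constant terms {dropped}", stacklevel=2
        )
    model = fit_logistic(
        X[:, keep], pooled["outcome"].to_numpy(dtype=float), [names[j] for j in keep]
    )
    model.coding = coding
    full = MissingnessPattern.from_factors(schema.factor_names, schema)
    model.pattern = full
    return cls(
        strategy=strategy,
        schema=schema,
        query_pattern=pattern,
        effective_pattern=full,
        model=model,
        all_terms=names,
        factor_of=factor_of,
        kept=keep,
        dropped_terms=dropped,
        contributing_cohorts=len(training.cohorts),
        coding=coding,
    )


def categorization_fit(
    training: MultiCohortDataset, pattern: MissingnessPattern
) -> CategorizationModel:
    """One model on every record, all factors recoded with missing levels."""
    return _all_data_fit(training, pattern, "categorized", CategorizationModel, "categorization")


def missing_indicator_fit(
    training: MultiCohortDataset, pattern: MissingnessPattern
) -> MissingIndicatorModel:
    """Categorization, but volume stays continuous + a missing indicator."""
    return _all_data_fit(
        training, pattern, "missing_indicator", MissingIndicatorModel, "missing_indicator"
    )


@dataclass
class ImputationModel(PatternModel):
    model: FittedLogisticModel = None
    marginals: dict[str, float] = field(default_factory=dict)
    m: int = DEFAULT_M
    cycles: int = DEFAULT_CYCLES
    seed: int = 0
    contributing_cohorts: int = 0

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_cohorts(self) -> int:
        return self.contributing_cohorts

    def predict(self, values) -> float:
        vals = _clean_values(values, self.schema)
        for f, fill in self.marginals.items():
            if math.isnan(vals[f]):
                vals[f] = fill
        row = _raw_row(vals, self.schema, set(self.schema.factor_names))
        return float(predict_proba(self.model, row)[0])

    def to_dict(self) -> dict:
        d = self._base_dict()
        d.update(
            model=self.model.to_dict(),
            marginals={k: float(v) for k, v in self.marginals.items()},
            m=self.m,
            cycles=self.cycles,
            seed=self.seed,
            contributing_cohorts=self.contributing_cohorts,
        )
        return d

    @classmethod
    def _from_dict(cls, d, schema):
        return cls(
            **cls._base_kwargs(d, schema),
            model=FittedLogisticModel.from_dict(d["model"]),
            marginals=dict(d["marginals"]),
            m=int(d["m"]),
            cycles=int(d["cycles"]),
            seed=int(d["seed"]),
            contributing_cohorts=int(d["contributing_cohorts"]),
        )


def training_marginals(training: MultiCohortDataset) -> dict[str, float]:
    """Prediction-time fill values from observed training values only:
    mean on the model scale for continuous factors (geometric-type mean for
    log2-transformed ones), most frequent level for binary factors."""
    schema = training.schema
    pooled = training.pooled()
    out = {}
    for spec in schema.factors:
        if spec.mandatory:
            continue
        obs = pooled[spec.name].dropna().to_numpy(dtype=float)
        if spec.kind == "continuous":
            if spec.transform == "log2":
                out[spec.name] = float(np.exp2(np.mean(np.log2(obs))))
            else:
                out[spec.name] = float(np.mean(obs))
        else:
            out[spec.name] = float(1.0 if obs.mean() > 0.5 else 0.0)
    return out


def imputation_fit(
    training: MultiCohortDataset,
    pattern: MissingnessPattern,
    *,
    m: int = DEFAULT_M,
    cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
) -> ImputationModel:
    """MICE on the pooled training set; Rubin-pooled full-factor model.

    Fits the full main-effects model on each of ``m`` completed datasets and
    averages coefficient vectors (the Rubin point estimate; between- plus
    within-imputation covariance is stored).  Prediction fills factors the
    user did not supply from training-set marginals, then applies the pooled
    model.
    """
    schema = training.schema
    pooled = training.pooled()
    completed = mice_impute(pooled, schema, m=m, cycles=cycles, seed=seed)
    full = MissingnessPattern.from_factors(schema.factor_names, schema)
    fits = []
    for df in completed:
        X, names = encode_design(df, schema, full, "raw")
        fits.append(fit_logistic(X, df["outcome"].to_numpy(dtype=float), names))
    B = np.stack([f.coefficients for f in fits])
    coef = B.mean(axis=0)
    within = np.mean([f.covariance for f in fits], axis=0)
    if m > 1:
        centered = B - coef
        between = centered.T @ centered / (m - 1)
        cov = within + (1.0 + 1.0 / m) * between
    else:
        cov = within
    pooled_model = FittedLogisticModel(
        term_names=fits[0].term_names,
        coefficients=coef,
        covariance=cov,
        log_likelihood=float(np.mean([f.log_likelihood for f in fits])),
        n_obs=fits[0].n_obs,
        n_events=fits[0].n_events,
        converged=True,
        pattern=full,
    )
    return ImputationModel(
        strategy="imputation",
        schema=schema,
        query_pattern=pattern,
        effective_pattern=full,
        model=pooled_model,
        marginals=training_marginals(training),
        m=m,
        cycles=cycles,
        seed=seed,
        contributing_cohorts=len(training.cohorts),
    )


_MODEL_CLASSES = {
    "available_cases": AvailableCasesModel,
    "iterative_bic": IterativeBICModel,
    "cohort_ensemble": CohortEnsembleModel,
    "categorization": CategorizationModel,
    "missing_indicator": MissingIndicatorModel,
    "imputation": ImputationModel,
}


def fit_strategy(
    name: str,
    training: MultiCohortDataset,
    pattern: MissingnessPattern,
    *,
    seed: int = 0,
    **kwargs,
) -> PatternModel:
    """Fit any of the six strategies by name for one query pattern."""
    if name == "available_cases":
        return available_cases_fit(training, pattern, **kwargs)
    if name == "iterative_bic":
        return iterative_bic_fit(training, pattern, **kwargs)
    if name == "cohort_ensemble":
        return cohort_ensemble_fit(training, pattern, **kwargs)
    if name == "categorization":
        return categorization_fit(training, pattern, **kwargs)
    if name == "missing_indicator":
        return missing_indicator_fit(training, pattern, **kwargs)
    if name == "imputation":
        return imputation_fit(training, pattern, seed=seed, **kwargs)
    raise ValueError(f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}")


def predict_for_patient(pattern_model: PatternModel, values) -> float:
    """Predicted risk of clinically significant cancer, as a proportion."""
    return pattern_model.predict(values)
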