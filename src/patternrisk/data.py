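"""Domain types, CSV ingestion and design-matrix encoding.

The package predicts clinically significant prostate cancer (Gleason grade
group >= 2 on biopsy) from up to 12 risk factors.  Two factors are mandatory
for every patient -- serum PSA (ng/mL) and age (years) -- and ten are
optional: digital rectal exam (DRE), prostate volume (cc), prior negative
biopsy, 5-alpha-reductase-inhibitor use, prior PSA screen, African ancestry,
Hispanic ethnicity, and first-degree prostate-, second-degree prostate- and
first-degree breast-cancer family history.  Missing cells are stored as NaN;
values are kept on their natural scale and transformed (log2 for PSA and
volume) only at encoding time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EncodingError, SchemaError, ValidationDataError

__all__ = [
    "FactorSpec",
    "RiskFactorSchema",
    "PatientRecord",
    "CohortDataset",
    "MultiCohortDataset",
    "MissingnessPattern",
    "default_schema",
    "read_cohort_csv",
    "write_cohort_csv",
    "missingness_summary",
    "complete_case_subset",
    "encode_design",
    "FAMILY_HISTORY_PAIR",
]

#: the two factors that are jointly collected or jointly missing
FAMILY_HISTORY_PAIR = ("fam_pca_2nd", "fam_bca_1st")

AGE_RANGE = (18.0, 120.0)


@dataclass(frozen=True)
class FactorSpec:
    """One risk factor: its type, encoding transform and level labels."""

    name: str
    kind: str = "continuous"  # continuous | binary | categorical
    transform: str = "none"  # none | log2
    mandatory: bool = False
    levels: tuple[str, ...] = ()  # (reference, ...) for binary/categorical

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise SchemaError(f"unknown factor kind {self.kind!r} for {self.name}")
        if self.transform not in ("none", "log2"):
            raise SchemaError(f"unknown transform {self.transform!r} for {self.name}")
        if self.kind == "continuous" and self.levels:
            raise SchemaError(f"continuous factor {self.name} cannot declare levels")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary factor {self.name} needs exactly 2 levels")
        if self.kind == "categorical":
            if not self.levels:
                raise SchemaError(f"categorical factor {self.name} needs levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"duplicate levels for factor {self.name}")


@dataclass(frozen=True)
class RiskFactorSchema:
    """Ordered collection of factor descriptors shared by all cohorts."""

    factors: tuple[FactorSpec, ...]

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise SchemaError("factor names must be unique")
        n_mand = sum(f.mandatory for f in self.factors)
        if n_mand < 1:
            raise SchemaError("schema needs at least one mandatory factor")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def mandatory(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.mandatory)

    @property
    def optional(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if not f.mandatory)

    def __getitem__(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    def to_yaml(self, path) -> None:
        doc = {
            "factors": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "transform": f.transform,
                    "mandatory": f.mandatory,
                    "levels": list(f.levels),
                }
                for f in self.factors
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RiskFactorSchema":
        doc = yaml.safe_load(Path(path).read_text())
        try:
            factors = tuple(
                FactorSpec(
                    name=d["name"],
                    kind=d.get("kind", "continuous"),
                    transform=d.get("transform", "none"),
                    mandatory=bool(d.get("mandatory", False)),
                    levels=tuple(d.get("levels") or ()),
                )
                for d in doc["factors"]
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema file {path}: {exc}") from exc
        return cls(factors)


def default_schema() -> RiskFactorSchema:
    """The 12-factor prostate-biopsy schema (2 mandatory, 10 optional).

    Binary factors are stored as 0/1 with 0 the reference ("no"/"normal");
    PSA and prostate volume enter models on the log2 scale (odds ratio per
    doubling), age per year untransformed.
    """
    yn = ("no", "yes")
    return RiskFactorSchema(
        (
            FactorSpec("psa", "continuous", "log2", mandatory=True),
            FactorSpec("age", "continuous", "none", mandatory=True),
            FactorSpec("dre", "binary", levels=("normal", "abnormal")),
            FactorSpec("volume", "continuous", "log2"),
            FactorSpec("prior_neg_biopsy", "binary", levels=yn),
            FactorSpec("fiveari", "binary", levels=yn),
            FactorSpec("prior_psa_screen", "binary", levels=yn),
            FactorSpec("african_ancestry", "binary", levels=yn),
            FactorSpec("hispanic", "binary", levels=yn),
            FactorSpec("fam_pca_1st", "binary", levels=yn),
            FactorSpec("fam_pca_2nd", "binary", levels=yn),
            FactorSpec("fam_bca_1st", "binary", levels=yn),
        )
    )


@dataclass(frozen=True)
class MissingnessPattern:
    """The subset of factors observed for a query patient.

    Always contains the mandatory factors; hashable so pattern-model caches
    and libraries can key on it.
    """

    observed: frozenset[str]

    @classmethod
    def from_factors(cls, factors: Iterable[str], schema: RiskFactorSchema) -> "MissingnessPattern":
        obs = set(factors) | set(schema.mandatory)
        unknown = obs - set(schema.factor_names)
        if unknown:
            raise ValidationDataError(f"unknown factors in pattern: {sorted(unknown)}")
        return cls(frozenset(obs))

    @classmethod
    def from_values(cls, values: Mapping[str, float], schema: RiskFactorSchema) -> "MissingnessPattern":
        """Derive the pattern from a value mapping (NaN/None = missing)."""
        obs = [
            k
            for k, v in values.items()
            if k in schema and v is not None and not (isinstance(v, float) and math.isnan(v))
        ]
        return cls.from_factors(obs, schema)

    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.observed))

    def optional_key(self, schema: RiskFactorSchema) -> tuple[str, ...]:
        return tuple(sorted(self.observed - set(schema.mandatory)))

    def ordered(self, schema: RiskFactorSchema) -> tuple[str, ...]:
        """Pattern factors in schema order (the deterministic term order)."""
        return tuple(n for n in schema.factor_names if n in self.observed)

    def __contains__(self, name: str) -> bool:
        return name in self.observed

    def __le__(self, other: "MissingnessPattern") -> bool:
        return self.observed <= other.observed


@dataclass(frozen=True)
class PatientRecord:
    """One biopsy: cohort, binary outcome and factor values (NaN = missing)."""

    cohort_id: str
    outcome: int
    values: Mapping[str, float]

    def pattern(self, schema: RiskFactorSchema) -> MissingnessPattern:
        return MissingnessPattern.from_values(dict(self.values), schema)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _validate_row(row: Mapping[str, float], schema: RiskFactorSchema) -> list[str]:
    """Return invariant-violation messages for one row (empty = valid)."""
    problems = []
    y = row.get("outcome")
    if _is_missing(y):
        problems.append("outcome is missing")
    elif y not in (0, 1, 0.0, 1.0):
        problems.append(f"outcome must be 0/1, got {y!r}")
    for spec in schema.factors:
        v = row.get(spec.name)
        if _is_missing(v):
            if spec.mandatory:
                problems.append(f"mandatory factor {spec.name} is missing")
            continue
        if spec.kind == "continuous":
            if spec.transform == "log2" and v <= 0:
                problems.append(f"{spec.name} must be > 0, got {v}")
            if spec.name == "age" and not (AGE_RANGE[0] <= v <= AGE_RANGE[1]):
                problems.append(f"age outside [{AGE_RANGE[0]:g}, {AGE_RANGE[1]:g}]: {v}")
        elif spec.kind == "binary":
            if v not in (0, 1, 0.0, 1.0):
                problems.append(f"{spec.name} must be 0/1, got {v!r}")
    return problems


@dataclass
class CohortDataset:
    """One cohort's biopsies as a DataFrame with columns
    ``outcome`` + the schema's factors (NaN = missing)."""

    cohort_id: str
    frame: pd.DataFrame
    schema: RiskFactorSchema
    diagnostics: list[str] = field(default_factory=list)
    #: pre-erasure truth, set by the synthetic generator only
    complete_frame: pd.DataFrame | None = None

    def __post_init__(self):
        missing_cols = {"outcome", *self.schema.factor_names} - set(self.frame.columns)
        if missing_cols:
            raise SchemaError(f"cohort {self.cohort_id} lacks columns {sorted(missing_cols)}")
        if len(self.frame) < 1:
            raise ValidationDataError(f"cohort {self.cohort_id} is empty")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def prevalence(self) -> float:
        return float(self.frame["outcome"].mean())

    def records(self) -> Iterator[PatientRecord]:
        for _, row in self.frame.iterrows():
            yield PatientRecord(
                cohort_id=self.cohort_id,
                outcome=int(row["outcome"]),
                values={n: row[n] for n in self.schema.factor_names},
            )

    def validate(self) -> None:
        for i, row in self.frame.iterrows():
            problems = _validate_row(row, self.schema)
            if problems:
                raise ValidationDataError(
                    f"cohort {self.cohort_id} row {i}: " + "; ".join(problems)
                )


@dataclass
class MultiCohortDataset:
    """Several cohorts sharing one schema."""

    cohorts: list[CohortDataset]

    def __post_init__(self):
        if not self.cohorts:
            raise ValidationDataError("need at least one cohort")
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ValidationDataError(f"duplicate cohort ids: {ids}")

    @property
    def schema(self) -> RiskFactorSchema:
        return self.cohorts[0].schema

    @property
    def n(self) -> int:
        return sum(c.n for c in self.cohorts)

    def pooled(self) -> pd.DataFrame:
        """All records, stable order (cohort order then row order), with a
        ``cohort_id`` column."""
        frames = []
        for c in self.cohorts:
            f = c.frame.copy()
            f.insert(0, "cohort_id", c.cohort_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def drop_cohort(self, cohort_id: str) -> "MultiCohortDataset":
        kept = [c for c in self.cohorts if c.cohort_id != cohort_id]
        return MultiCohortDataset(kept)


# ---------------------------------------------------------------------------
# CSV ingestion / emission
# ---------------------------------------------------------------------------

_LEVEL_ALIASES = {"no": 0.0, "yes": 1.0, "normal": 0.0, "abnormal": 1.0}


def read_cohort_csv(
    path,
    schema: RiskFactorSchema,
    *,
    na_sentinels: Sequence[str] = ("", "NA"),
    cohort_id: str | None = None,
    on_invalid: str = "drop",
) -> CohortDataset:
    """Read one cohort CSV into a validated :class:`CohortDataset`.

    The file must name ``outcome`` and every schema factor in its header
    (``cohort_id`` optional if given as an argument).  Missing cells are empty
    or any of ``na_sentinels``.  Binary cells may be 0/1 or level labels
    ("yes"/"no", "normal"/"abnormal").  Rows violating record invariants are
    rejected; diagnostics (row-indexed messages) are attached to the result,
    or raised if ``on_invalid="raise"``.
    """
    if on_invalid not in ("drop", "raise"):
        raise ValueError("on_invalid must be 'drop' or 'raise'")
    raw = pd.read_csv(path, dtype=str, na_values=list(na_sentinels), keep_default_na=False)
    required = {"outcome", *schema.factor_names}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {sorted(missing_cols)}")
    if cohort_id is None:
        if "cohort_id" not in raw.columns:
            raise SchemaError(f"{path}: no cohort_id column and none supplied")
        ids = raw["cohort_id"].dropna().unique()
        if len(ids) != 1:
            raise SchemaError(f"{path}: expected a single cohort_id, found {list(ids)}")
        cohort_id = str(ids[0])

    diagnostics: list[str] = []
    numeric = pd.DataFrame(index=raw.index)
    bad_rows: set[int] = set()
    for col in ["outcome", *schema.factor_names]:
        cells = raw[col]
        if col != "outcome" and col in schema and schema[col].kind in ("binary",):
            cells = cells.map(lambda s: _LEVEL_ALIASES.get(s.strip().lower(), s) if isinstance(s, str) else s)
        parsed = pd.to_numeric(cells, errors="coerce")
        unparsed = parsed.isna() & cells.notna()
        for i in raw.index[unparsed]:
            diagnostics.append(f"row {i}: cannot parse {col}={raw.at[i, col]!r} as a number")
            bad_rows.add(i)
        numeric[col] = parsed

    for i, row in numeric.iterrows():
        if i in bad_rows:
            continue
        problems = _validate_row(row, schema)
        if problems:
            diagnostics.append(f"row {i}: " + "; ".join(problems))
            bad_rows.add(i)

    if diagnostics and on_invalid == "raise":
        raise ValidationDataError(f"{path}: invalid rows:\n" + "\n".join(diagnostics))

    kept = numeric.drop(index=sorted(bad_rows)).reset_index(drop=True)
    if kept.empty:
        raise ValidationDataError(f"{path}: no valid rows remain")
    return CohortDataset(cohort_id=cohort_id, frame=kept, schema=schema, diagnostics=diagnostics)


def write_cohort_csv(dataset: CohortDataset, path, *, na_rep: str = "") -> None:
    """Write a cohort back to CSV; round-trips values and missingness."""
    out = dataset.frame.copy()
    out.insert(0, "cohort_id", dataset.cohort_id)
    out.to_csv(path, index=False, na_rep=na_rep)


# ---------------------------------------------------------------------------
# Missingness accounting
# ---------------------------------------------------------------------------


def missingness_summary(data: MultiCohortDataset) -> pd.DataFrame:
    """Fraction of missing values per (cohort, factor).

    Mandatory factors report 0 by the record invariant.  Mirrors the by-cohort
    missing-data profile used to characterise heterogeneous collection.
    """
    rows = {}
    for c in data.cohorts:
        rows[c.cohort_id] = {
            name: float(c.frame[name].isna().mean()) for name in data.schema.factor_names
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(data.schema.factor_names)]


def complete_case_subset(data: MultiCohortDataset, pattern: MissingnessPattern) -> pd.DataFrame:
    """Pool records complete on every factor in ``pattern`` across cohorts.

    This is the data-assembly step of the available-cases ("2^k submodels")
    method: each query pattern gets the largest pool of biopsies fully
    observed on exactly the factors the query supplies.  Order is stable
    (cohort order, then row order).  May be empty; the downstream fit decides.
    """
    pooled = data.pooled()
    cols = [n for n in data.schema.factor_names if n in pattern]
    mask = pooled[cols].notna().all(axis=1) if cols else pd.Series(True, index=pooled.index)
    return pooled[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Design-matrix encoding
# ---------------------------------------------------------------------------


def _term_name(spec: FactorSpec) -> str:
    if spec.kind == "continuous":
        return f"{spec.name}_log2" if spec.transform == "log2" else spec.name
    return f"{spec.name}_{spec.levels[1]}"


def term_name_for(schema: RiskFactorSchema, factor: str) -> str:
    """Deterministic main-effect term name for a factor (binary: non-reference
    level suffix; continuous: transform suffix)."""
    return _term_name(schema[factor])


def _encode_continuous(spec: FactorSpec, values: np.ndarray) -> np.ndarray:
    if spec.transform == "log2":
        if np.any(values[~np.isnan(values)] <= 0):
            raise EncodingError(f"{spec.name}: log2 transform requires positive values")
        return np.log2(values)
    return values


def encode_design(
    frame: pd.DataFrame,
    schema: RiskFactorSchema,
    pattern: MissingnessPattern,
    coding: str = "raw",
):
    """Encode records into (design matrix, term names).

    ``coding="raw"``: intercept + one term per pattern factor in schema order;
    rows must be complete on the pattern.  The ``categorized`` and
    ``missing_indicator`` codings recode missing values into explicit levels
    and always span the full factor set; they live in
    :mod:`patternrisk.strategies` and are dispatched from here.
    """
    if coding == "raw":
        names = ["intercept"]
        cols = [np.ones(len(frame))]
        for spec in schema.factors:
            if spec.name not in pattern:
                continue
            values = frame[spec.name].to_numpy(dtype=float)
            if np.isnan(values).any():
                raise EncodingError(
                    f"raw coding requires complete data on {spec.name}"
                )
            if spec.kind == "continuous":
                cols.append(_encode_continuous(spec, values))
                names.append(_term_name(spec))
            elif spec.kind == "binary":
                bad = ~np.isin(values, (0.0, 1.0))
                if bad.any():
                    raise EncodingError(f"{spec.name}: non-binary value present")
                cols.append(values)
                names.append(_term_name(spec))
            else:  # categorical: dummies against the first (reference) level
                levels = spec.levels
                ints = values.astype(int)
                if np.any((ints < 0) | (ints >= len(levels))):
                    raise EncodingError(f"{spec.name}: unknown categorical level code")
                for j, lev in enumerate(levels[1:], start=1):
                    cols.append((ints == j).astype(float))
                    names.append(f"{spec.name}_{lev}")
        return np.column_stack(cols), names
    if coding in ("categorized", "missing_indicator"):
        from .strategies import encode_with_missing_levels

        X, names, _ = encode_with_missing_levels(frame, schema, coding)
        return X, names
    raise ValueError(f"unknown coding {coding!r}")
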