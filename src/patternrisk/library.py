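"""Deployment side: the pre-fitted pattern-submodel library.

For a schema with k optional factors the builder enumerates all 2^k subsets
and fits one submodel per subset (1,024 models for the 10-factor prostate
schema), so an end-user supplying any combination of risk factors is served
by the model fit to the largest complete-case pool for exactly those
factors.  The default strategy is available cases -- the method selected for
online deployment on calibration grounds -- but any of the six can be built
for experimentation.  Libraries serialize to JSON (coefficients round-trip
bit-identically) with provenance: a digest of the training data, the build
seed and a timestamp.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .data import MissingnessPattern, MultiCohortDataset, RiskFactorSchema
from .errors import (
    LibraryLoadError,
    PatternRiskError,
    UnservedPatternError,
    ValidationDataError,
)
from .strategies import PATTERN_DEPENDENT, PatternModel, fit_strategy

__all__ = [
    "PatternModelLibrary",
    "RiskQuery",
    "RiskAnswer",
    "build_pattern_library",
    "save_library",
    "load_library",
    "predict_risk",
]

_FORMAT_VERSION = 1


def _pattern_key(optional_factors) -> str:
    return ",".join(sorted(optional_factors))


def training_digest(training: MultiCohortDataset) -> str:
    """Stable digest of the training data (values and missingness)."""
    h = hashlib.sha256()
    for c in training.cohorts:
        h.update(c.cohort_id.encode())
        h.update(c.frame.to_csv(index=False).encode())
    return h.hexdigest()


@dataclass
class RiskQuery:
    """End-user inputs: mandatory PSA (ng/mL) and age (years) plus any
    subset of the optional factors."""

    psa: float
    age: float
    optional: dict[str, float] = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        return {"psa": self.psa, "age": self.age, **self.optional}


@dataclass
class RiskAnswer:
    """A served prediction with transparency metadata."""

    risk_percent: float
    pattern: tuple[str, ...]
    n_obs: int
    n_cohorts: int
    odds_ratios: dict[str, float]
    unused_factors: tuple[str, ...] = ()

    @property
    def risk_display(self) -> str:
        return f"{self.risk_percent:.2f}%"


@dataclass
class PatternModelLibrary:
    """2^k pre-fitted submodels keyed by canonical optional-factor pattern."""

    strategy: str
    schema: RiskFactorSchema
    entries: dict[str, PatternModel]
    unserved: dict[str, str]
    provenance: dict

    @property
    def n_patterns(self) -> int:
        return len(self.entries) + len(self.unserved)

    def lookup(self, optional_factors) -> PatternModel:
        key = _pattern_key(optional_factors)
        if key in self.entries:
            return self.entries[key]
        if key in self.unserved:
            suggestion = self._nearest_served(set(optional_factors))
            hint = f"; nearest served pattern: {suggestion!r}" if suggestion is not None else ""
            raise UnservedPatternError(
                f"pattern {key!r} has no usable model ({self.unserved[key]}){hint}",
                suggestion=suggestion,
            )
        raise UnservedPatternError(f"pattern {key!r} not in library")

    def _nearest_served(self, wanted: set[str]) -> str | None:
        best = None
        for key in self.entries:
            factors = set(key.split(",")) if key else set()
            if factors <= wanted and (best is None or len(factors) > len(best.split(",") if best else [])):
                best = key
        return best


def build_pattern_library(
    training: MultiCohortDataset,
    strategy: str = "available_cases",
    *,
    seed: int = 0,
    optional_factors=None,
    **fit_kwargs,
) -> PatternModelLibrary:
    """Fit a submodel for every subset of the optional factors.

    Patterns that cannot be fit (insufficient complete cases, separation)
    are stored as explicit unserved entries with the reason.  The
    mandatory-only pattern failing is a hard error: it uses every training
    record, so a library without it is unusable.
    """
    schema = training.schema
    optional = tuple(optional_factors) if optional_factors is not None else schema.optional
    entries: dict[str, PatternModel] = {}
    unserved: dict[str, str] = {}
    shared = None  # pattern-independent strategies fit once, reuse everywhere
    for r in range(len(optional) + 1):
        for subset in itertools.combinations(optional, r):
            pattern = MissingnessPattern.from_factors(subset, schema)
            key = _pattern_key(subset)
            try:
                if strategy in PATTERN_DEPENDENT:
                    entries[key] = fit_strategy(
                        strategy, training, pattern, seed=seed, **fit_kwargs
                    )
                else:
                    if shared is None:
                        shared = fit_strategy(
                            strategy, training, pattern, seed=seed, **fit_kwargs
                        )
                    entries[key] = shared
            except PatternRiskError as exc:
                if r == 0:
                    raise PatternRiskError(
                        f"mandatory-only pattern failed to fit: {exc}"
                    ) from exc
                unserved[key] = str(exc)
    provenance = {
        "training_digest": training_digest(training),
        "seed": seed,
        "built_at": datetime.now(timezone.utc).isoformat(),
        "n_training": training.n,
        "n_cohorts": len(training.cohorts),
    }
    return PatternModelLibrary(
        strategy=strategy,
        schema=schema,
        entries=entries,
        unserved=unserved,
        provenance=provenance,
    )


def save_library(library: PatternModelLibrary, path) -> None:
    doc = {
        "format_version": _FORMAT_VERSION,
        "strategy": library.strategy,
        "schema": {
            "factors": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "transform": f.transform,
                    "mandatory": f.mandatory,
                    "levels": list(f.levels),
                }
                for f in library.schema.factors
            ]
        },
        "provenance": library.provenance,
        "entries": {k: m.to_dict() for k, m in library.entries.items()},
        "unserved": library.unserved,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_library(path) -> PatternModelLibrary:
    from .data import FactorSpec

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise LibraryLoadError(f"cannot read library {path}: {exc}") from exc
    try:
        if doc["format_version"] != _FORMAT_VERSION:
            raise LibraryLoadError(
                f"library format {doc['format_version']} != {_FORMAT_VERSION}"
            )
        schema = RiskFactorSchema(
            tuple(
                FactorSpec(
                    name=f["name"],
                    kind=f["kind"],
                    transform=f["transform"],
                    mandatory=f["mandatory"],
                    levels=tuple(f["levels"]),
                )
                for f in doc["schema"]["factors"]
            )
        )
        entries = {
            k: PatternModel.from_dict(d, schema) for k, d in doc["entries"].items()
        }
        return PatternModelLibrary(
            strategy=doc["strategy"],
            schema=schema,
            entries=entries,
            unserved=dict(doc["unserved"]),
            provenance=dict(doc["provenance"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise LibraryLoadError(f"malformed library {path}: {exc}") from exc


def predict_risk(library: PatternModelLibrary, query: RiskQuery) -> RiskAnswer:
    """Serve one end-user query from the library.

    The supplied factor set is canonicalized to a pattern key; the matching
    submodel predicts; the answer reports the model's training support and
    odds ratios, and names any supplied factor the model did not use.
    """
    values = query.values()
    supplied = {
        k
        for k, v in values.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    }
    unknown = supplied - set(library.schema.factor_names)
    if unknown:
        raise ValidationDataError(f"unknown risk factors: {sorted(unknown)}")
    optional = supplied - set(library.schema.mandatory)
    model = library.lookup(optional)
    risk = model.predict(values)
    return RiskAnswer(
        risk_percent=100.0 * risk,
        pattern=tuple(sorted(supplied)),
        n_obs=model.n_obs,
        n_cohorts=model.n_cohorts,
        odds_ratios=(
            model.model.odds_ratios() if hasattr(model, "model") and model.model else {}
        ),
        unused_factors=model.unused_factors(values),
    )
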