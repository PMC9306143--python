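"""Accuracy metrics and validation designs.

Calibration-in-the-large (CIL) is the mean predicted risk minus the observed
event rate, reported as a signed percentage (negative = under-prediction),
with a normal-approximation CI on the per-patient differences.  Discrimination
is the area under the ROC curve (Mann-Whitney concordance, ties 1/2),
reported as a percentage with a DeLong CI (a seeded bootstrap is available as
a cross-check).  Calibration-in-the-small is a decile calibration curve with
Wilson pointwise intervals.

Two validation designs: external validation on a held-out cohort, applying
the chosen strategy separately to each patient's missingness pattern (with
per-pattern model caching), and leave-one-cohort-out cross-validation
summarised by the median and IQR of CIL and AUC across folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .data import CohortDataset, MissingnessPattern, MultiCohortDataset
from .errors import PatternRiskError, ValidationDataError
from .strategies import PATTERN_DEPENDENT, PatternModel, fit_strategy

__all__ = [
    "cil_with_ci",
    "auc_with_ci",
    "auc_bootstrap_ci",
    "calibration_curve",
    "CalibrationCurve",
    "ValidationReport",
    "CVResult",
    "external_validate",
    "loco_cv",
    "plot_calibration",
    "plot_cv",
]

_Z95 = 1.959963984540054


def _check_vectors(risks, outcomes):
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if risks.size == 0 or risks.shape != outcomes.shape:
        raise ValidationDataError("risks and outcomes must be equal-length, non-empty")
    if np.any((risks <= 0) | (risks >= 1)):
        raise ValidationDataError("risks must lie strictly in (0, 1)")
    if not np.all(np.isin(outcomes, (0.0, 1.0))):
        raise ValidationDataError("outcomes must be binary")
    return risks, outcomes


def cil_with_ci(risks, outcomes) -> tuple[float, tuple[float, float]]:
    """Calibration-in-the-large: 100 * (mean risk - event rate), with 95% CI
    from the standard error of the mean per-patient difference."""
    risks, outcomes = _check_vectors(risks, outcomes)
    diff = risks - outcomes
    cil = 100.0 * float(diff.mean())
    se = 100.0 * float(diff.std(ddof=1) / np.sqrt(diff.size)) if diff.size > 1 else 0.0
    return cil, (cil - _Z95 * se, cil + _Z95 * se)


def _delong_variance(risks: np.ndarray, outcomes: np.ndarray) -> float:
    """DeLong's variance of the AUC via midrank placements."""
    from scipy.stats import rankdata

    pos = risks[outcomes == 1.0]
    neg = risks[outcomes == 0.0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # placement values: fraction of the other class each point beats
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_with_ci(risks, outcomes) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (ties 1/2) as a percentage, DeLong 95% CI."""
    risks, outcomes = _check_vectors(risks, outcomes)
    if outcomes.min() == outcomes.max():
        raise ValidationDataError("both outcome classes required for AUC")
    auc = 100.0 * float(roc_auc_score(outcomes, risks))
    se = 100.0 * float(np.sqrt(_delong_variance(risks, outcomes)))
    lo = max(0.0, auc - _Z95 * se)
    hi = min(100.0, auc + _Z95 * se)
    return auc, (lo, hi)


def auc_bootstrap_ci(
    risks, outcomes, *, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Percentile-bootstrap AUC CI, seeded; cross-check for the DeLong CI."""
    risks, outcomes = _check_vectors(risks, outcomes)
    rng = np.random.default_rng(seed)
    n = len(risks)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        y = outcomes[idx]
        if y.min() == y.max():
            continue
        stats.append(roc_auc_score(y, risks[idx]))
    auc = 100.0 * float(roc_auc_score(outcomes, risks))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return auc, (100.0 * float(lo), 100.0 * float(hi))


@dataclass
class CalibrationCurve:
    """Observed vs predicted risk by predicted-risk decile."""

    mean_predicted: list[float]
    observed: list[float]
    ci_low: list[float]
    ci_high: list[float]
    counts: list[int]

    def to_dict(self) -> dict:
        return {
            "mean_predicted": self.mean_predicted,
            "observed": self.observed,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "counts": self.counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**{k: list(v) for k, v in d.items()})


def calibration_curve(risks, outcomes, n_bins: int = 10) -> CalibrationCurve:
    """Equal-count bins on the stably sorted predicted risks; per-bin mean
    predicted risk, observed event proportion and Wilson 95% interval.
    Any remainder after integer division is spread over the leading bins."""
    risks, outcomes = _check_vectors(risks, outcomes)
    n = len(risks)
    if n < n_bins:
        raise ValidationDataError(f"need at least {n_bins} points, got {n}")
    order = np.argsort(risks, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    mean_pred, obs, lo, hi, counts = [], [], [], [], []
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        start += size
        r, y = risks[idx], outcomes[idx]
        k = int(y.sum())
        ci = proportion_confint(k, size, alpha=0.05, method="wilson")
        mean_pred.append(float(r.mean()))
        obs.append(k / size)
        lo.append(float(ci[0]))
        hi.append(float(ci[1]))
        counts.append(size)
    return CalibrationCurve(mean_pred, obs, lo, hi, counts)


@dataclass
class ValidationReport:
    """CIL, AUC and a calibration curve for one strategy on one test set."""

    strategy: str
    cil: float
    cil_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    calibration: CalibrationCurve
    n_test: int
    prevalence: float
    n_patterns: int = 0
    unserved: list[dict] = field(default_factory=list)
    risks: np.ndarray | None = None
    outcomes: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "cil": self.cil,
            "cil_ci": list(self.cil_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "calibration": self.calibration.to_dict(),
            "n_test": self.n_test,
            "prevalence": self.prevalence,
            "n_patterns": self.n_patterns,
            "unserved": self.unserved,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            strategy=d["strategy"],
            cil=d["cil"],
            cil_ci=tuple(d["cil_ci"]),
            auc=d["auc"],
            auc_ci=tuple(d["auc_ci"]),
            calibration=CalibrationCurve.from_dict(d["calibration"]),
            n_test=d["n_test"],
            prevalence=d["prevalence"],
            n_patterns=d.get("n_patterns", 0),
            unserved=list(d.get("unserved", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        return (
            f"{self.strategy}: CIL {self.cil:+.1f}% "
            f"({self.cil_ci[0]:+.1f}, {self.cil_ci[1]:+.1f}), "
            f"AUC {self.auc:.1f}% ({self.auc_ci[0]:.1f}, {self.auc_ci[1]:.1f}), "
            f"n={self.n_test}, prevalence {100 * self.prevalence:.1f}%"
        )


def predict_cohort(
    strategy: str,
    training: MultiCohortDataset,
    test: CohortDataset,
    *,
    seed: int = 0,
    model_cache: dict | None = None,
    **fit_kwargs,
):
    """Per-patient tailored predictions for a whole test cohort.

    Derives each patient's missingness pattern, fits (or reuses from cache)
    the strategy's model for that pattern, and predicts.  Returns
    ``(risks, outcomes, kept_index, unserved, cache)``; patients whose
    pattern cannot be served are reported, never silently dropped.
    """
    schema = training.schema
    cache = model_cache if model_cache is not None else {}
    risks, outcomes, kept, unserved = [], [], [], []
    pattern_dependent = strategy in PATTERN_DEPENDENT
    for i, row in test.frame.iterrows():
        values = {f: row[f] for f in schema.factor_names}
        pattern = MissingnessPattern.from_values(values, schema)
        key = pattern.key() if pattern_dependent else ("__all__",)
        if key not in cache:
            try:
                cache[key] = fit_strategy(
                    strategy, training, pattern, seed=seed, **fit_kwargs
                )
            except PatternRiskError as exc:
                cache[key] = exc
        entry = cache[key]
        if isinstance(entry, Exception):
            unserved.append({"row": int(i), "pattern": list(pattern.key()), "reason": str(entry)})
            continue
        risks.append(entry.predict(values))
        outcomes.append(float(row["outcome"]))
        kept.append(int(i))
    return np.asarray(risks), np.asarray(outcomes), kept, unserved, cache


def external_validate(
    strategy: str,
    training: MultiCohortDataset,
    test: CohortDataset,
    *,
    seed: int = 0,
    n_bins: int = 10,
    **fit_kwargs,
) -> ValidationReport:
    """Validate one strategy on a held-out cohort, per-patient tailored."""
    if any(c.cohort_id == test.cohort_id for c in training.cohorts):
        raise ValidationDataError(
            f"test cohort {test.cohort_id} also appears in training"
        )
    risks, outcomes, _, unserved, cache = predict_cohort(
        strategy, training, test, seed=seed, **fit_kwargs
    )
    if unserved:
        warnings.warn(
            f"{strategy}: {len(unserved)} of {test.n} patients unserved", stacklevel=2
        )
    if risks.size == 0:
        raise PatternRiskError(f"{strategy}: no patient could be served")
    cil, cil_ci = cil_with_ci(risks, outcomes)
    auc, auc_ci = auc_with_ci(risks, outcomes)
    curve = calibration_curve(risks, outcomes, n_bins=n_bins)
    n_patterns = sum(1 for v in cache.values() if isinstance(v, PatternModel))
    return ValidationReport(
        strategy=strategy,
        cil=cil,
        cil_ci=cil_ci,
        auc=auc,
        auc_ci=auc_ci,
        calibration=curve,
        n_test=int(risks.size),
        prevalence=float(outcomes.mean()),
        n_patterns=n_patterns,
        unserved=unserved,
        risks=risks,
        outcomes=outcomes,
    )


@dataclass
class CVResult:
    """Leave-one-cohort-out cross-validation: one report per held-out cohort."""

    strategy: str
    reports: dict[str, ValidationReport]
    failed: dict[str, str] = field(default_factory=dict)

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.reports.values()])

    @property
    def summary(self) -> dict[str, float]:
        out = {}
        for metric in ("cil", "auc"):
            v = self._values(metric)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            out[f"{metric}_median"] = float(med)
            out[f"{metric}_iqr"] = (float(q1), float(q3))
        return out

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
            "failed": dict(self.failed),
            "summary": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.summary.items()
            },
        }


def loco_cv(
    strategy: str, training: MultiCohortDataset, *, seed: int = 0, **fit_kwargs
) -> CVResult:
    """Leave-one-cohort-out CV: each cohort in turn is the test set.

    A fold that fails entirely is recorded as failed with a warning; the
    median/IQR summary covers completed folds.
    """
    if len(training.cohorts) < 2:
        raise ValidationDataError("LOCO CV needs at least 2 cohorts")
    reports: dict[str, ValidationReport] = {}
    failed: dict[str, str] = {}
    for held_out in training.cohorts:
        rest = training.drop_cohort(held_out.cohort_id)
        try:
            reports[held_out.cohort_id] = external_validate(
                strategy, rest, held_out, seed=seed, **fit_kwargs
            )
        except PatternRiskError as exc:
            failed[held_out.cohort_id] = str(exc)
            warnings.warn(
                f"LOCO fold {held_out.cohort_id} failed: {exc}", stacklevel=2
            )
    if not reports:
        raise PatternRiskError("every LOCO fold failed")
    return CVResult(strategy=strategy, reports=reports, failed=failed)


# ---------------------------------------------------------------------------
# Plots (no acceptance weight; shapes follow the validation figures)
# ---------------------------------------------------------------------------


def plot_calibration(report: ValidationReport, path) -> None:
    """Decile calibration curve with shaded pointwise 95% intervals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = report.calibration
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], color="black", lw=1)
    ax.plot(c.mean_predicted, c.observed, marker="o", color="tab:blue")
    ax.fill_between(c.mean_predicted, c.ci_low, c.ci_high, alpha=0.25, color="tab:blue")
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Observed proportion")
    ax.set_title(report.strategy)
    lim = max(max(c.mean_predicted), max(c.ci_high)) * 1.05
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cv(results: dict[str, CVResult], metric: str, path) -> None:
    """Violin + box summary of a metric across LOCO folds, one row per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(results)
    data = [results[s]._values(metric) for s in names]
    fig, ax = plt.subplots(figsize=(6, 0.8 + 0.6 * len(names)))
    ax.violinplot(data, vert=False, showmedians=True)
    ax.boxplot(data, vert=False, widths=0.15)
    ax.set_yticks(range(1, len(names) + 1), names)
    ax.set_xlabel(f"{metric.upper()} (%)")
    for i, v in enumerate(data, start=1):
        ax.text(float(np.median(v)), i + 0.25, f"{np.median(v):.1f}", ha="center", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
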