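"""Repetition harness: set sizing, paired learner comparison, percentile summaries.

Set sizes follow the events-per-free-parameter rule: with N free parameters
(the 15 predictor categories), X events per parameter and event prevalence P,
the training set holds round(N*X/P) records; validation and test sets each
hold round(200/P) records, giving about 200 events for threshold selection
and testing.  Each repetition draws the three sets disjointly from the
cohort, fits both learners on the same training set, selects each learner's
cut-off on the same validation set, evaluates on the same test set and
records the paired difference in mistriage rates.  Across repetitions the
median and 2.5/97.5 percentiles summarize every metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import learners, metrics, preprocess, thresholding
from .cohort import generate_cohort
from .exceptions import SizingError, UnfittableError
from .io import ExperimentConfig, JsonlLogger
from .thresholding import CutoffDecision, CutoffRule

LEARNER_NAMES = ("logreg", "xgboost")
METRIC_FIELDS = (
    "threshold",
    "undertriage",
    "overtriage",
    "sensitivity",
    "specificity",
    "auc",
    "cal_slope",
    "cal_intercept",
)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SizingSpec:
    n_free_parameters: int
    events_per_parameter: int
    prevalence: float
    training_size: int
    validation_size: int
    test_size: int

    @property
    def total(self) -> int:
        return self.training_size + self.validation_size + self.test_size


def compute_sizes(
    N: int = preprocess.N_FREE_PARAMETERS, X: int = 10, P: float = 0.21
) -> SizingSpec:
    """Training size N*X/P, validation and test sizes 200/P, rounded half up."""
    if N < 1 or X < 1:
        raise ValueError("N and X must be positive integers")
    if not (0.0 < P < 1.0):
        raise ValueError("prevalence P must lie in (0, 1)")
    vt = _round_half_up(200.0 / P)
    return SizingSpec(
        n_free_parameters=N,
        events_per_parameter=X,
        prevalence=P,
        training_size=_round_half_up(N * X / P),
        validation_size=vt,
        test_size=vt,
    )


@dataclass
class EncodedCohort:
    """Eligible cohort in model-ready form (11 design columns + outcome)."""

    name: str
    X: np.ndarray
    y: np.ndarray

    @classmethod
    def from_records(cls, name: str, records: pd.DataFrame) -> "EncodedCohort":
        X, y = preprocess.design_matrix(records)
        return cls(name=name, X=X, y=y)

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class LearnerResult:
    cutoff: CutoffDecision
    metrics: metrics.TriageMetrics


@dataclass
class RepetitionResult:
    repetition_index: int
    learners: dict[str, LearnerResult]
    difference_undertriage: float  # logistic - boosted
    difference_overtriage: float

    def rows(self, cohort: str, epp: int) -> list[dict]:
        out = []
        for name, res in self.learners.items():
            m = res.metrics
            out.append(
                {
                    "cohort": cohort,
                    "epp": epp,
                    "rep": self.repetition_index,
                    "learner": name,
                    "threshold": res.cutoff.threshold,
                    "undertriage": m.undertriage,
                    "overtriage": m.overtriage,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "auc": m.auc,
                    "cal_slope": m.calibration_slope,
                    "cal_intercept": m.calibration_intercept,
                }
            )
        return out


def _disjoint_draw(
    rng: np.random.Generator, y: np.ndarray, sizing: SizingSpec, max_attempts: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Disjoint train/validation/test indices, all three two-class.

    The whole partition is redrawn (up to ``max_attempts``) when any set is
    single-class, which at realistic prevalences essentially never triggers.
    """
    n = len(y)
    t, v, s = sizing.training_size, sizing.validation_size, sizing.test_size
    if t + v + s > n:
        raise SizingError(
            f"cohort of {n} too small for disjoint draw of {t}+{v}+{s} records"
        )
    for attempt in range(max_attempts):
        perm = rng.permutation(n)
        train, val, test = perm[:t], perm[t : t + v], perm[t + v : t + v + s]
        if all(np.unique(y[part]).size == 2 for part in (train, val, test)):
            return train, val, test, attempt
    raise UnfittableError(f"no two-class partition found in {max_attempts} attempts")


def run_repetition(
    cohort: EncodedCohort,
    sizing: SizingSpec,
    seed: int | np.random.SeedSequence,
    repetition_index: int = 0,
    bootstrap_reps: int = 1000,
    search_budget: int = 30,
    cv_folds: int = 5,
    shrink_mode: str = "default",
    rule: CutoffRule = CutoffRule(),
    log: JsonlLogger | None = None,
) -> RepetitionResult:
    """One paired training/thresholding/testing pass for both learners."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_draw, s_logreg, s_xgb = ss.spawn(3)

    train, val, test, attempts = _disjoint_draw(
        np.random.default_rng(s_draw), cohort.y, sizing
    )
    if attempts and log:
        log.log("warning", "simulation", "partition_redrawn", attempts=attempts)
    X, y = cohort.X, cohort.y

    logreg = learners.fit_shrunken_logistic(
        X[train], y[train], B=bootstrap_reps, seed=s_logreg, mode=shrink_mode
    )
    xgb = learners.fit_boosted_trees(
        X[train], y[train], X[val], y[val],
        budget=search_budget, seed=s_xgb, cv_folds=cv_folds,
    )

    results: dict[str, LearnerResult] = {}
    for name, model in (("logreg", logreg), ("xgboost", xgb)):
        val_probs = learners.predict_probability(model, X[val])
        cutoff = thresholding.select_cutoff(val_probs, y[val], rule)
        test_probs = learners.predict_probability(model, X[test])
        m = metrics.evaluate(test_probs, y[test], cutoff.threshold)
        results[name] = LearnerResult(cutoff=cutoff, metrics=m)

    return RepetitionResult(
        repetition_index=repetition_index,
        learners=results,
        difference_undertriage=results["logreg"].metrics.undertriage
        - results["xgboost"].metrics.undertriage,
        difference_overtriage=results["logreg"].metrics.overtriage
        - results["xgboost"].metrics.overtriage,
    )


@dataclass
class SimulationSummary:
    """Median and 2.5/97.5 percentiles per metric across repetitions."""

    n_repetitions: int
    per_learner: dict[str, dict[str, dict[str, float]]]
    differences: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "n_repetitions": self.n_repetitions,
            "per_learner": self.per_learner,
            "differences": self.differences,
        }


def _percentile_summary(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=np.float64)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return {"median": float("nan"), "p2_5": float("nan"), "p97_5": float("nan")}
    lo, med, hi = np.percentile(finite, [2.5, 50.0, 97.5], method="linear")
    return {"median": float(med), "p2_5": float(lo), "p97_5": float(hi)}


def summarize(results: list[RepetitionResult]) -> SimulationSummary:
    """Aggregate repetition results; quantiles by linear interpolation."""
    if not results:
        raise ValueError("cannot summarize zero repetitions")
    per_learner: dict[str, dict[str, dict[str, float]]] = {}
    for name in results[0].learners:
        fields = {
            "threshold": [r.learners[name].cutoff.threshold for r in results],
            "undertriage": [r.learners[name].metrics.undertriage for r in results],
            "overtriage": [r.learners[name].metrics.overtriage for r in results],
            "sensitivity": [r.learners[name].metrics.sensitivity for r in results],
            "specificity": [r.learners[name].metrics.specificity for r in results],
            "auc": [r.learners[name].metrics.auc for r in results],
            "cal_slope": [r.learners[name].metrics.calibration_slope for r in results],
            "cal_intercept": [r.learners[name].metrics.calibration_intercept for r in results],
        }
        per_learner[name] = {k: _percentile_summary(np.array(v)) for k, v in fields.items()}
    differences = {
        "undertriage": _percentile_summary(
            np.array([r.difference_undertriage for r in results])
        ),
        "overtriage": _percentile_summary(
            np.array([r.difference_overtriage for r in results])
        ),
    }
    return SimulationSummary(
        n_repetitions=len(results), per_learner=per_learner, differences=differences
    )


def _load_cohort_entry(entry, seed: np.random.SeedSequence, log: JsonlLogger) -> EncodedCohort:
    if isinstance(entry, tio.CohortFromCsv):
        records = tio.read_cohort_csv(entry.csv)
    else:
        records = generate_cohort(entry.spec, int(seed.generate_state(1)[0] % 2**31))
    eligible, report = preprocess.filter_eligible(records)
    log.log("info", "preprocess", "eligibility", cohort=entry.name, **report.as_dict())
    return EncodedCohort.from_records(entry.name, eligible)


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, dict]:
    """Full experiment loop over cohorts x events-per-parameter x repetitions.

    Writes ``repetitions.csv`` (one row per repetition per learner),
    ``summary.json`` (per-cell percentile tables and paired differences),
    ``manifest.json`` and ``run_log.jsonl`` into ``out_dir``.  Cells whose
    sizing exceeds the cohort are skipped with a recorded reason.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = JsonlLogger(out_dir / "run_log.jsonl")
    tio.write_manifest(config, out_dir)

    root = np.random.SeedSequence(config.master_seed)
    cohort_seeds = root.spawn(len(config.cohorts))

    rows: list[dict] = []
    summary: dict = {"cells": []}
    for entry, cseed in zip(config.cohorts, cohort_seeds):
        gen_seed, rep_root = cseed.spawn(2)
        cohort = _load_cohort_entry(entry, gen_seed, log)
        prevalence = float(np.mean(cohort.y))
        for epp in config.epp_levels:
            sizing = compute_sizes(preprocess.N_FREE_PARAMETERS, epp, prevalence)
            cell = {
                "cohort": entry.name,
                "epp": epp,
                "prevalence": prevalence,
                "sizing": {
                    "training": sizing.training_size,
                    "validation": sizing.validation_size,
                    "test": sizing.test_size,
                },
            }
            if sizing.total > len(cohort):
                cell["status"] = "skipped"
                cell["reason"] = (
                    f"requires {sizing.total} records, cohort has {len(cohort)}"
                )
                log.log("warning", "simulation", "cell_skipped", **cell)
                summary["cells"].append(cell)
                continue
            rep_seeds = rep_root.spawn(config.repetitions)
            results, failures = [], 0
            for i, rseed in enumerate(rep_seeds):
                try:
                    rep = run_repetition(
                        cohort, sizing, rseed, repetition_index=i,
                        bootstrap_reps=config.bootstrap_reps,
                        search_budget=config.search_budget,
                        cv_folds=config.cv_folds,
                        shrink_mode=config.shrink_mode,
                        log=log,
                    )
                except UnfittableError as exc:
                    failures += 1
                    log.log("error", "simulation", "repetition_failed",
                            cohort=entry.name, epp=epp, rep=i, error=str(exc))
                    continue
                results.append(rep)
                rows.extend(rep.rows(entry.name, epp))
            if results:
                cell["status"] = "completed"
                cell["n_failed"] = failures
                cell["summary"] = summarize(results).to_dict()
            else:
                cell["status"] = "all_repetitions_failed"
            summary["cells"].append(cell)

    frame = pd.DataFrame(rows, columns=["cohort", "epp", "rep", "learner", *METRIC_FIELDS])
    # shortest round-trip float repr so rates survive the CSV byte-exactly
    frame.to_csv(
        out_dir / "repetitions.csv", index=False, lineterminator="\n",
        float_format=lambda v: repr(float(v)),
    )
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", encoding="utf-8"
    )
    return frame, summary
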