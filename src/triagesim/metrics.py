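"""Performance measures: mistriage rates, discrimination and calibration.

Undertriage is the false-negative rate (major-trauma patients classified
minor) and overtriage the false-positive rate (minor-trauma patients
classified major); sensitivity and specificity are stored as their exact
complements.  Discrimination is the Mann-Whitney AUC with ties counted one
half.  Calibration regresses the observed outcomes on the logit of the
predicted probabilities: the slope comes from a two-parameter logistic fit
(slope 1 = perfectly calibrated spread) and the calibration-in-the-large
intercept from an intercept-only logistic fit with the logit as fixed offset
(0 = correct average risk).  Probabilities are clipped to
``[1e-6, 1 - 1e-6]`` before the logit because tree ensembles can emit hard
0/1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata

from .exceptions import UndefinedRateError, UndefinedSlopeError

PROB_CLIP = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with major trauma as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, outcomes: np.ndarray, predictions: np.ndarray) -> "ConfusionCounts":
        outcomes = np.asarray(outcomes, dtype=np.int64)
        predictions = np.asarray(predictions, dtype=np.int64)
        return cls(
            tp=int(np.sum((outcomes == 1) & (predictions == 1))),
            fn=int(np.sum((outcomes == 1) & (predictions == 0))),
            fp=int(np.sum((outcomes == 0) & (predictions == 1))),
            tn=int(np.sum((outcomes == 0) & (predictions == 0))),
        )


@dataclass
class TriageMetrics:
    """One learner's test-set performance for a single repetition."""

    undertriage: float
    overtriage: float
    sensitivity: float
    specificity: float
    auc: float = float("nan")
    calibration_slope: float = float("nan")
    calibration_intercept: float = float("nan")
    # free intercept of the slope model, kept as a secondary diagnostic
    calibration_slope_model_intercept: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def triage_rates(counts: ConfusionCounts) -> TriageMetrics:
    """Mistriage rates from counts; complements are exact by construction."""
    n_major = counts.tp + counts.fn
    n_minor = counts.fp + counts.tn
    if n_major < 1 or n_minor < 1:
        raise UndefinedRateError("both classes must be present to compute rates")
    undertriage = counts.fn / n_major
    overtriage = counts.fp / n_minor
    return TriageMetrics(
        undertriage=undertriage,
        overtriage=overtriage,
        sensitivity=1.0 - undertriage,
        specificity=1.0 - overtriage,
    )


def auc(probs: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney AUC (rank statistic, ties counted half)."""
    probs = np.asarray(probs, dtype=np.float64)
    outcomes = np.asarray(outcomes, dtype=np.int64)
    n_pos = int(np.sum(outcomes == 1))
    n_neg = int(np.sum(outcomes == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRateError("AUC undefined with a single class")
    ranks = rankdata(probs)
    rank_sum = float(np.sum(ranks[outcomes == 1]))
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def calibration(
    probs: np.ndarray, outcomes: np.ndarray, clip: float = PROB_CLIP
) -> tuple[float, float, float]:
    """Calibration slope and calibration-in-the-large intercept.

    Returns ``(slope, intercept, slope_model_intercept)``.  The slope is the
    coefficient of a logistic regression of outcomes on the clipped logit of
    the probabilities; the intercept comes from an intercept-only logistic fit
    with that logit as fixed offset.
    """
    probs = np.asarray(probs, dtype=np.float64)
    outcomes = np.asarray(outcomes, dtype=np.int64)
    if np.unique(outcomes).size < 2:
        raise UndefinedRateError("calibration undefined with a single outcome class")
    lp = logit(np.clip(probs, clip, 1.0 - clip))
    if np.ptp(lp) == 0.0:
        raise UndefinedSlopeError("linear predictor has zero variance")
    slope_fit = sm.GLM(outcomes, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    slope_model_intercept, slope = (float(c) for c in slope_fit.params)
    offset_fit = sm.GLM(
        outcomes, np.ones((len(outcomes), 1)), offset=lp, family=sm.families.Binomial()
    ).fit()
    intercept = float(offset_fit.params[0])
    return slope, intercept, slope_model_intercept


def evaluate(
    probs: np.ndarray, outcomes: np.ndarray, threshold: float
) -> TriageMetrics:
    """Full metric set for one learner on one test set.

    Calibration can be genuinely undefined (e.g. a constant classifier); those
    fields stay NaN rather than aborting the repetition.
    """
    predictions = (np.asarray(probs, dtype=np.float64) >= threshold).astype(np.int64)
    m = triage_rates(ConfusionCounts.from_predictions(outcomes, predictions))
    m.auc = auc(probs, outcomes)
    try:
        m.calibration_slope, m.calibration_intercept, m.calibration_slope_model_intercept = (
            calibration(probs, outcomes)
        )
    except UndefinedSlopeError:
        pass
    return m
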