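"""Probability cut-off selection under the undertriage/overtriage rule.

A record is classified as major trauma when its predicted probability is
greater than or equal to the threshold.  Thresholds are searched over an
inclusive grid (default 0 to 1 in steps of 0.001, 1001 points).  The primary
branch keeps thresholds with validation undertriage <= 5% and among them
minimizes overtriage, following the trauma-system guidance of at most 5%
undertriage; if no threshold attains that, the fallback keeps thresholds with
overtriage strictly below 50% and minimizes undertriage.  Ties are broken
toward the largest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedRateError


@dataclass(frozen=True)
class CutoffRule:
    undertriage_ceiling: float = 0.05
    overtriage_ceiling: float = 0.50
    grid_start: float = 0.0
    grid_end: float = 1.0
    grid_step: float = 0.001

    def __post_init__(self):
        if not (0.0 <= self.undertriage_ceiling <= 1.0 and 0.0 <= self.overtriage_ceiling <= 1.0):
            raise ValueError("ceilings must lie in [0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    def grid(self) -> np.ndarray:
        """Inclusive threshold grid, decimal-rounded so e.g. 0.2 is exact."""
        n = int(round((self.grid_end - self.grid_start) / self.grid_step))
        return np.round(self.grid_start + self.grid_step * np.arange(n + 1), 12)


@dataclass(frozen=True)
class CutoffDecision:
    threshold: float
    rule_branch: str  # "primary" | "fallback"
    validation_undertriage: float
    validation_overtriage: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "rule_branch": self.rule_branch,
            "validation_undertriage": self.validation_undertriage,
            "validation_overtriage": self.validation_overtriage,
        }


def _grid_rates(
    probs: np.ndarray, outcomes: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Undertriage and overtriage at every grid threshold (classify at p >= t)."""
    major = np.sort(probs[outcomes == 1])
    minor = np.sort(probs[outcomes == 0])
    if major.size == 0 or minor.size == 0:
        raise UndefinedRateError("both outcome classes required to evaluate the grid")
    # false negatives at t: majors with p < t; false positives: minors with p >= t
    undertriage = np.searchsorted(major, grid, side="left") / major.size
    overtriage = (minor.size - np.searchsorted(minor, grid, side="left")) / minor.size
    return undertriage, overtriage


def select_cutoff(
    probs: np.ndarray, outcomes: np.ndarray, rule: CutoffRule = CutoffRule()
) -> CutoffDecision:
    """Brute-force gridsearch for the constrained optimal threshold."""
    probs = np.asarray(probs, dtype=np.float64)
    outcomes = np.asarray(outcomes, dtype=np.int64)
    grid = rule.grid()
    undertriage, overtriage = _grid_rates(probs, outcomes, grid)

    feasible = undertriage <= rule.undertriage_ceiling
    if feasible.any():
        branch = "primary"
        objective = np.where(feasible, overtriage, np.inf)
    else:
        branch = "fallback"
        # always non-empty: above max(probs) nothing is classified major
        feasible = overtriage < rule.overtriage_ceiling
        objective = np.where(feasible, undertriage, np.inf)
    best = objective.min()
    # ties broken toward the largest threshold
    idx = int(np.flatnonzero(objective == best)[-1])
    return CutoffDecision(
        threshold=float(grid[idx]),
        rule_branch=branch,
        validation_undertriage=float(undertriage[idx]),
        validation_overtriage=float(overtriage[idx]),
    )


def apply_cutoff(probs: np.ndarray, threshold: float) -> np.ndarray:
    """Binary classification: major trauma iff probability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return (np.asarray(probs, dtype=np.float64) >= threshold).astype(np.int64)
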