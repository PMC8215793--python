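"""Eligibility filtering, Revised-Trauma-Score categorization and dummy encoding.

Predictors are the first prehospital vital signs (systolic blood pressure,
respiratory rate, Glasgow Coma Scale) categorized into the standard RTS bands,
plus a binary age predictor split at 57 years.  Records are stored as a
15-indicator vector (5 GCS + 4 RR + 4 SBP + 2 age categories); for model
fitting one reference level per predictor (the physiologically best band) is
dropped, giving an 11-column design matrix plus intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import CategorizationError

# Canonical category order follows the registry summary-table layout.
GCS_CATEGORIES: tuple[str, ...] = ("13-15", "9-12", "6-8", "4-5", "3")
GCS_BOUNDS: tuple[tuple[int, int], ...] = ((13, 15), (9, 12), (6, 8), (4, 5), (3, 3))
RR_CATEGORIES: tuple[str, ...] = ("30-67", "10-29", "6-9", "0-5")
RR_BOUNDS: tuple[tuple[int, int], ...] = ((30, 67), (10, 29), (6, 9), (0, 5))
SBP_CATEGORIES: tuple[str, ...] = ("90-300", "76-89", "50-75", "1-49")
SBP_BOUNDS: tuple[tuple[int, int], ...] = ((90, 300), (76, 89), (50, 75), (1, 49))
AGE_CATEGORIES: tuple[str, ...] = ("<57", ">=57")
AGE_THRESHOLD = 57

# Severity ranking (best -> worst) as canonical-order indices.  For RR the
# best band per the RTS is 10-29 (normal rate), not the first-listed 30-67.
GCS_SEVERITY_ORDER: tuple[int, ...] = (0, 1, 2, 3, 4)
RR_SEVERITY_ORDER: tuple[int, ...] = (1, 0, 2, 3)
SBP_SEVERITY_ORDER: tuple[int, ...] = (0, 1, 2, 3)

# Reference level (dropped in the design matrix) = best category per block.
REFERENCE_INDEX = {"gcs": 0, "rr": 1, "sbp": 0, "age": 0}

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"gcs_{c}" for c in GCS_CATEGORIES]
    + [f"rr_{c}" for c in RR_CATEGORIES]
    + [f"sbp_{c}" for c in SBP_CATEGORIES]
    + [f"age_{c}" for c in AGE_CATEGORIES]
)

_BLOCKS = (
    ("gcs", GCS_CATEGORIES),
    ("rr", RR_CATEGORIES),
    ("sbp", SBP_CATEGORIES),
    ("age", AGE_CATEGORIES),
)
_BLOCK_OFFSETS = {"gcs": 0, "rr": 5, "sbp": 9, "age": 13}

DESIGN_COLUMNS: tuple[str, ...] = tuple(
    f"{block}_{cats[i]}"
    for block, cats in _BLOCKS
    for i in range(len(cats))
    if i != REFERENCE_INDEX[block]
)

N_FREE_PARAMETERS = len(FEATURE_COLUMNS)  # total category count used for sizing


class PatientRecord(NamedTuple):
    """One registry row; vitals may be None (missing)."""

    age: int
    sbp: int | None
    rr: int | None
    gcs: int | None
    major_trauma: int


@dataclass(frozen=True)
class FeatureVector:
    """Categorized form of an eligible record (one label per predictor block)."""

    gcs_cat: str
    rr_cat: str
    sbp_cat: str
    age_cat: str


@dataclass
class EligibilityReport:
    """Exclusion bookkeeping; each record is attributed to its first failing rule
    in the fixed order: age, SBP > 300, SBP = 0, RR > 67, missing."""

    n_input: int = 0
    n_excluded_age: int = 0
    n_excluded_sbp_high: int = 0
    n_excluded_sbp_zero: int = 0
    n_excluded_rr_high: int = 0
    n_excluded_missing: int = 0
    n_included: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _bin_index(value: int, bounds: tuple[tuple[int, int], ...], name: str) -> int:
    for i, (lo, hi) in enumerate(bounds):
        if lo <= value <= hi:
            return i
    raise CategorizationError(f"{name} value {value} outside every category")


def categorize(record: PatientRecord) -> FeatureVector:
    """Map an eligible record onto its RTS category labels.

    Categories are inclusive integer ranges; age >= 57 falls in the elderly
    band.  Raises :class:`CategorizationError` for values no band covers
    (only possible on unfiltered input).
    """
    if record.sbp is None or record.rr is None or record.gcs is None:
        raise CategorizationError("cannot categorize a record with missing vitals")
    return FeatureVector(
        gcs_cat=GCS_CATEGORIES[_bin_index(int(record.gcs), GCS_BOUNDS, "gcs")],
        rr_cat=RR_CATEGORIES[_bin_index(int(record.rr), RR_BOUNDS, "rr")],
        sbp_cat=SBP_CATEGORIES[_bin_index(int(record.sbp), SBP_BOUNDS, "sbp")],
        age_cat=AGE_CATEGORIES[1 if record.age >= AGE_THRESHOLD else 0],
    )


def encode(fv: FeatureVector) -> np.ndarray:
    """15-indicator encoding, one hot per predictor block (exactly 4 ones)."""
    vec = np.zeros(len(FEATURE_COLUMNS), dtype=np.int8)
    vec[_BLOCK_OFFSETS["gcs"] + GCS_CATEGORIES.index(fv.gcs_cat)] = 1
    vec[_BLOCK_OFFSETS["rr"] + RR_CATEGORIES.index(fv.rr_cat)] = 1
    vec[_BLOCK_OFFSETS["sbp"] + SBP_CATEGORIES.index(fv.sbp_cat)] = 1
    vec[_BLOCK_OFFSETS["age"] + AGE_CATEGORIES.index(fv.age_cat)] = 1
    return vec


def decode(vec: np.ndarray) -> FeatureVector:
    """Inverse of :func:`encode`; requires exactly one indicator per block."""
    vec = np.asarray(vec)
    labels = {}
    for block, cats in _BLOCKS:
        off = _BLOCK_OFFSETS[block]
        sub = vec[off : off + len(cats)]
        hot = np.flatnonzero(sub)
        if hot.size != 1:
            raise CategorizationError(f"{block} block must have exactly one indicator set")
        labels[block] = cats[int(hot[0])]
    return FeatureVector(
        gcs_cat=labels["gcs"], rr_cat=labels["rr"], sbp_cat=labels["sbp"], age_cat=labels["age"]
    )


def filter_eligible(records: pd.DataFrame) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply the study eligibility criteria.

    Retained records satisfy age >= 16, 1 <= SBP <= 300, RR <= 67 and have no
    missing vitals.  Exclusions are attributed to the first failing rule in
    the order age, SBP > 300, SBP = 0, RR > 67, missing; the retained set does
    not depend on that order.
    """
    report = EligibilityReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), report

    age = records["age"].to_numpy()
    sbp = records["sbp"]
    rr = records["rr"]
    gcs = records["gcs"]

    missing = sbp.isna() | rr.isna() | gcs.isna()
    sbp_f = sbp.fillna(-1).to_numpy(dtype=float)
    rr_f = rr.fillna(-1).to_numpy(dtype=float)

    bad_age = age < 16
    bad_sbp_high = sbp_f > 300
    bad_sbp_zero = sbp_f == 0
    bad_rr_high = rr_f > 67
    bad_missing = missing.to_numpy()

    remaining = np.ones(len(records), dtype=bool)
    for rule, mask in (
        ("n_excluded_age", bad_age),
        ("n_excluded_sbp_high", bad_sbp_high),
        ("n_excluded_sbp_zero", bad_sbp_zero),
        ("n_excluded_rr_high", bad_rr_high),
        ("n_excluded_missing", bad_missing),
    ):
        hit = remaining & mask
        setattr(report, rule, int(hit.sum()))
        remaining &= ~mask

    report.n_included = int(remaining.sum())
    return records.loc[remaining].reset_index(drop=True), report


def _categorize_columns(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Vectorized category indices (canonical order) for an eligible frame."""
    out: dict[str, np.ndarray] = {}
    for name, bounds in (("gcs", GCS_BOUNDS), ("rr", RR_BOUNDS), ("sbp", SBP_BOUNDS)):
        vals = records[name].to_numpy(dtype=float)
        idx = np.full(len(records), -1, dtype=np.int64)
        for i, (lo, hi) in enumerate(bounds):
            idx[(vals >= lo) & (vals <= hi)] = i
        if (idx < 0).any():
            bad = records[name].iloc[int(np.argmax(idx < 0))]
            raise CategorizationError(f"{name} value {bad} outside every category")
        out[name] = idx
    out["age"] = (records["age"].to_numpy() >= AGE_THRESHOLD).astype(np.int64)
    return out


def encode_frame(records: pd.DataFrame) -> np.ndarray:
    """(n, 15) indicator matrix for an eligible cohort frame."""
    idx = _categorize_columns(records)
    n = len(records)
    mat = np.zeros((n, len(FEATURE_COLUMNS)), dtype=np.int8)
    rows = np.arange(n)
    for block in ("gcs", "rr", "sbp", "age"):
        mat[rows, _BLOCK_OFFSETS[block] + idx[block]] = 1
    return mat


def design_matrix(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Model-fitting form: 11 non-reference dummies (columns
    :data:`DESIGN_COLUMNS`) and the binary outcome."""
    full = encode_frame(records)
    keep = [i for i, col in enumerate(FEATURE_COLUMNS) if col in DESIGN_COLUMNS]
    X = full[:, keep].astype(np.float64)
    y = records["major_trauma"].to_numpy(dtype=np.int64)
    return X, y
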