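"""Synthetic trauma-registry cohort generator.

Real trauma registries (hospital trauma databases summarised only by their
printed category proportions) are restricted-access, so this module generates
cohorts whose categorical marginals for GCS, respiratory rate and systolic
blood pressure, age quartiles and major-trauma prevalence match a supplied
specification, with a *known* logistic ground-truth outcome model so that
calibration and shrinkage behaviour can be verified by parameter recovery.

Mechanics
---------
* Vital-sign categories are drawn either independently from their marginals
  or, in ``latent_severity`` mode, by thresholding a single shared standard
  normal severity score with per-vital cut points chosen to preserve the
  marginals exactly.
* Raw vital values are drawn uniformly over the assigned category's integer
  range; age comes from a piecewise-linear quantile function through the
  specified quartiles with linear tails to 16 and 100 years.
* The outcome is Bernoulli with logit equal to an intercept plus one
  log-odds weight per category; the intercept is calibrated by root finding
  so the population prevalence equals ``prevalence_target`` exactly (the
  category joint distribution is enumerable in both correlation modes).
* Randomness is split into named child streams of a single master seed
  (categories, raw values, age, outcome, missingness) so every draw is
  reproducible and independent.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from . import preprocess as pp
from .exceptions import (
    InvalidSpecError,
    UndefinedProbabilityError,
    UnattainablePrevalenceError,
)

COHORT_COLUMNS = ("age", "sbp", "rr", "gcs", "major_trauma")


class OutcomeCoefficients(BaseModel):
    """Log-odds weight per category (canonical order); intercept is calibrated.

    Defaults are monotone in physiological severity: 0 for the best band of
    each vital (GCS 13-15, RR 10-29, SBP 90-300, age <57) and increasing steps
    for worse bands, sized to give a ground-truth AUC in the 0.6-0.75 range
    typical of vital-sign triage models.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    gcs: tuple[float, float, float, float, float] = (0.0, 0.8, 1.6, 2.4, 3.0)
    # canonical RR order is (30-67, 10-29, 6-9, 0-5); 10-29 is the best band
    rr: tuple[float, float, float, float] = (0.7, 0.0, 1.4, 2.1)
    sbp: tuple[float, float, float, float] = (0.0, 0.7, 1.4, 2.1)
    age: tuple[float, float] = (0.0, 0.5)


class CohortSpec(BaseModel):
    """Full description of a synthetic cohort's distributions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_patients: int = Field(ge=1)
    prevalence_target: float = Field(gt=0.0, lt=1.0)
    gcs_marginals: tuple[float, float, float, float, float]
    rr_marginals: tuple[float, float, float, float]
    sbp_marginals: tuple[float, float, float, float]
    age_quartiles: tuple[float, float, float]
    outcome_coefficients: OutcomeCoefficients = OutcomeCoefficients()
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    correlation_mode: Literal["independent", "latent_severity"] = "independent"

    @field_validator("gcs_marginals", "rr_marginals", "sbp_marginals")
    @classmethod
    def _check_marginals(cls, v):
        if any(p < 0 for p in v):
            raise ValueError("marginal probabilities must be non-negative")
        if sum(v) <= 0:
            raise ValueError("marginals must have positive total mass")
        return v

    @field_validator("age_quartiles")
    @classmethod
    def _check_quartiles(cls, v):
        q1, q2, q3 = v
        if not (16 <= q1 <= q2 <= q3 <= 100):
            raise ValueError("age quartiles must be non-decreasing within [16, 100]")
        return v


def ntdb_like_spec(n_patients: int = 368_810, **overrides) -> CohortSpec:
    """US national trauma databank-like cohort: prevalence 0.21, age 51 [30, 69]."""
    defaults = dict(
        n_patients=n_patients,
        prevalence_target=0.21,
        gcs_marginals=(0.9098, 0.0384, 0.0175, 0.0061, 0.0283),
        rr_marginals=(0.0191, 0.9677, 0.0063, 0.0021),
        sbp_marginals=(0.9707, 0.0192, 0.0091, 0.0011),
        age_quartiles=(30.0, 51.0, 69.0),
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def swetrau_like_spec(n_patients: int = 16_547, **overrides) -> CohortSpec:
    """Swedish trauma registry-like cohort: prevalence 0.12, age 41 [25, 59]."""
    defaults = dict(
        n_patients=n_patients,
        prevalence_target=0.12,
        gcs_marginals=(0.9173, 0.0401, 0.018, 0.009, 0.0156),
        rr_marginals=(0.0543, 0.9407, 0.0036, 0.0011),
        sbp_marginals=(0.9798, 0.0126, 0.0068, 0.0007),
        age_quartiles=(25.0, 41.0, 59.0),
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def _normalized(marginals) -> np.ndarray:
    """Printed proportions are rounded and rarely sum to exactly 1; rescale."""
    arr = np.asarray(marginals, dtype=float)
    total = arr.sum()
    if total <= 0 or (arr < 0).any():
        raise InvalidSpecError("marginals must be non-negative with positive mass")
    return arr / total


# ---------------------------------------------------------------------------
# Age quantile function


def _age_knots(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    q1, q2, q3 = spec.age_quartiles
    u = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    a = np.array([16.0, q1, q2, q3, 100.0])
    return u, a


def sample_ages(spec: CohortSpec, u: np.ndarray) -> np.ndarray:
    """Piecewise-linear quantile transform, rounded to whole years in [16, 100]."""
    uk, ak = _age_knots(spec)
    ages = np.interp(u, uk, ak)
    return np.clip(np.rint(ages), 16, 100).astype(np.int64)


def _age_elderly_probability(spec: CohortSpec) -> float:
    """P(age >= 57) under the quantile model (with integer rounding)."""
    uk, ak = _age_knots(spec)
    # round(Q(u)) >= 57  <=>  Q(u) >= 56.5
    cut = 56.5
    if cut <= ak[0]:
        return 1.0
    if cut >= ak[-1]:
        return 0.0
    return 1.0 - float(np.interp(cut, ak, uk))


# ---------------------------------------------------------------------------
# Joint category distribution (exact, both correlation modes)


def _severity_thresholds(marginals: np.ndarray, order: tuple[int, ...]) -> np.ndarray:
    """Interior z cut points for one vital, best category at low z."""
    p_sorted = marginals[list(order)]
    cum = np.cumsum(p_sorted)[:-1]
    return norm.ppf(np.clip(cum, 0.0, 1.0))


def _joint_category_distribution(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """All (gcs, rr, sbp) canonical index triples with their probabilities."""
    g = _normalized(spec.gcs_marginals)
    r = _normalized(spec.rr_marginals)
    s = _normalized(spec.sbp_marginals)
    if spec.correlation_mode == "independent":
        prob = np.einsum("i,j,k->ijk", g, r, s).ravel()
        gi, ri, si = np.meshgrid(
            np.arange(5), np.arange(4), np.arange(4), indexing="ij"
        )
        triples = np.stack([gi.ravel(), ri.ravel(), si.ravel()], axis=1)
        keep = prob > 0
        return triples[keep], prob[keep]

    # latent_severity: each vital's category is a deterministic bin of a shared
    # standard-normal z, so the joint is piecewise constant between thresholds.
    orders = (pp.GCS_SEVERITY_ORDER, pp.RR_SEVERITY_ORDER, pp.SBP_SEVERITY_ORDER)
    thresh = [
        _severity_thresholds(m, o) for m, o in zip((g, r, s), orders)
    ]
    edges = np.unique(np.concatenate([[-np.inf], *thresh, [np.inf]]))
    cdf = norm.cdf(edges)
    weights = np.diff(cdf)
    mids = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo):
            mids.append(hi - 1.0)
        elif np.isinf(hi):
            mids.append(lo + 1.0)
        else:
            mids.append(0.5 * (lo + hi))
    mids = np.asarray(mids)
    triples = np.empty((len(mids), 3), dtype=np.int64)
    for v, (t, order) in enumerate(zip(thresh, orders)):
        sev = np.searchsorted(t, mids, side="left")
        triples[:, v] = np.asarray(order)[sev]
    keep = weights > 0
    return triples[keep], weights[keep]


def _category_logits(spec: CohortSpec, triples: np.ndarray) -> np.ndarray:
    co = spec.outcome_coefficients
    return (
        np.asarray(co.gcs)[triples[:, 0]]
        + np.asarray(co.rr)[triples[:, 1]]
        + np.asarray(co.sbp)[triples[:, 2]]
    )


def calibrate_intercept(spec: CohortSpec) -> float:
    """Intercept making the population prevalence equal ``prevalence_target``.

    The marginal outcome probability is enumerated exactly over the joint
    category distribution and the two age bands, then solved for the intercept
    by Brent's method.  Deterministic given the spec.
    """
    triples, weights = _joint_category_distribution(spec)
    logits = _category_logits(spec, triples)
    p_old = _age_elderly_probability(spec)
    age_coef = np.asarray(spec.outcome_coefficients.age)

    def prevalence(c: float) -> float:
        p = (1.0 - p_old) * expit(c + logits + age_coef[0]) + p_old * expit(
            c + logits + age_coef[1]
        )
        return float(np.dot(weights, p))

    lo, hi = -40.0, 40.0
    if not (prevalence(lo) < spec.prevalence_target < prevalence(hi)):
        raise UnattainablePrevalenceError(
            f"prevalence {spec.prevalence_target} not attainable for these coefficients"
        )
    return float(brentq(lambda c: prevalence(c) - spec.prevalence_target, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# Generation


def _draw_categories(
    spec: CohortSpec, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    g = _normalized(spec.gcs_marginals)
    r = _normalized(spec.rr_marginals)
    s = _normalized(spec.sbp_marginals)
    if spec.correlation_mode == "independent":
        return {
            "gcs": rng.choice(5, size=n, p=g),
            "rr": rng.choice(4, size=n, p=r),
            "sbp": rng.choice(4, size=n, p=s),
        }
    z = rng.standard_normal(n)
    out = {}
    for name, m, order in (
        ("gcs", g, pp.GCS_SEVERITY_ORDER),
        ("rr", r, pp.RR_SEVERITY_ORDER),
        ("sbp", s, pp.SBP_SEVERITY_ORDER),
    ):
        t = _severity_thresholds(m, order)
        sev = np.searchsorted(t, z, side="left")
        out[name] = np.asarray(order)[sev]
    return out


def _draw_values_in_bins(
    rng: np.random.Generator, idx: np.ndarray, bounds
) -> np.ndarray:
    lo = np.asarray([b[0] for b in bounds])[idx]
    hi = np.asarray([b[1] for b in bounds])[idx]
    u = rng.random(len(idx))
    return (lo + np.floor(u * (hi - lo + 1))).astype(np.int64)


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Generate ``spec.n_patients`` synthetic patient records.

    Returns a DataFrame with columns ``age, sbp, rr, gcs, major_trauma``
    (vitals as nullable Int64 when missingness is enabled).  Identical spec
    and seed reproduce the cohort exactly.
    """
    n = spec.n_patients
    ss = np.random.SeedSequence(seed)
    s_cat, s_val, s_age, s_out, s_miss = [np.random.default_rng(c) for c in ss.spawn(5)]

    cats = _draw_categories(spec, s_cat, n)
    sbp = _draw_values_in_bins(s_val, cats["sbp"], pp.SBP_BOUNDS)
    rr = _draw_values_in_bins(s_val, cats["rr"], pp.RR_BOUNDS)
    gcs = _draw_values_in_bins(s_val, cats["gcs"], pp.GCS_BOUNDS)
    age = sample_ages(spec, s_age.random(n))
    age_idx = (age >= pp.AGE_THRESHOLD).astype(np.int64)

    co = spec.outcome_coefficients
    intercept = calibrate_intercept(spec)
    logit = (
        intercept
        + np.asarray(co.gcs)[cats["gcs"]]
        + np.asarray(co.rr)[cats["rr"]]
        + np.asarray(co.sbp)[cats["sbp"]]
        + np.asarray(co.age)[age_idx]
    )
    outcome = (s_out.random(n) < expit(logit)).astype(np.int64)

    df = pd.DataFrame(
        {
            "age": age,
            "sbp": pd.array(sbp, dtype="Int64"),
            "rr": pd.array(rr, dtype="Int64"),
            "gcs": pd.array(gcs, dtype="Int64"),
            "major_trauma": outcome,
        }
    )
    if spec.missing_rate > 0:
        for col in ("sbp", "rr", "gcs"):
            mask = s_miss.random(n) < spec.missing_rate
            df.loc[mask, col] = pd.NA
    return df


def true_probability(spec: CohortSpec, record: pp.PatientRecord) -> float:
    """Ground-truth outcome probability for one complete record."""
    if record.sbp is None or record.rr is None or record.gcs is None:
        raise UndefinedProbabilityError("true probability undefined with missing vitals")
    fv = pp.categorize(record)
    co = spec.outcome_coefficients
    logit = (
        calibrate_intercept(spec)
        + co.gcs[pp.GCS_CATEGORIES.index(fv.gcs_cat)]
        + co.rr[pp.RR_CATEGORIES.index(fv.rr_cat)]
        + co.sbp[pp.SBP_CATEGORIES.index(fv.sbp_cat)]
        + co.age[pp.AGE_CATEGORIES.index(fv.age_cat)]
    )
    return float(expit(logit))


def true_probabilities(spec: CohortSpec, records: pd.DataFrame) -> np.ndarray:
    """Vectorized ground-truth probabilities for a complete-record frame."""
    if records[["sbp", "rr", "gcs"]].isna().any().any():
        raise UndefinedProbabilityError("true probability undefined with missing vitals")
    idx = pp._categorize_columns(records)
    co = spec.outcome_coefficients
    logit = (
        calibrate_intercept(spec)
        + np.asarray(co.gcs)[idx["gcs"]]
        + np.asarray(co.rr)[idx["rr"]]
        + np.asarray(co.sbp)[idx["sbp"]]
        + np.asarray(co.age)[idx["age"]]
    )
    return expit(logit)
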