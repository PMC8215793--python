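import numpy as np
import pandas as pd
import pytest

import triagesim as ts


@pytest.fixture(scope="session")
def balanced_spec():
    """Spec with well-populated categories so every dummy column has support."""
    return ts.CohortSpec(
        n_patients=3000,
        prevalence_target=0.3,
        gcs_marginals=(0.30, 0.25, 0.20, 0.15, 0.10),
        rr_marginals=(0.25, 0.40, 0.20, 0.15),
        sbp_marginals=(0.40, 0.25, 0.20, 0.15),
        age_quartiles=(30.0, 50.0, 70.0),
    )


@pytest.fixture(scope="session")
def balanced_cohort(balanced_spec):
    return ts.generate_cohort(balanced_spec, 424242)


@pytest.fixture(scope="session")
def balanced_design(balanced_cohort):
    return ts.design_matrix(balanced_cohort)


@pytest.fixture(scope="session")
def swetrau_100k():
    spec = ts.swetrau_like_spec(n_patients=100_000)
    return spec, ts.generate_cohort(spec, 20_000)


def make_record(age=40, sbp=120, rr=16, gcs=15, major_trauma=0):
    return ts.PatientRecord(age=age, sbp=sbp, rr=rr, gcs=gcs, major_trauma=major_trauma)


@pytest.fixture
def record_factory():
    return make_record


def records_frame(rows):
    """Build a cohort frame from (age, sbp, rr, gcs, major_trauma) tuples;
    None encodes a missing vital."""
    df = pd.DataFrame(rows, columns=["age", "sbp", "rr", "gcs", "major_trauma"])
    for col in ("sbp", "rr", "gcs"):
        df[col] = pd.array(
            [pd.NA if v is None else int(v) for v in df[col]], dtype="Int64"
        )
    return df


@pytest.fixture
def frame_factory():
    return records_frame
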