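import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lsmatch import Cohort, SimConfig, generate_cohort


def make_cohort(
    arms,
    X=None,
    binary_ids=None,
    age=None,
    index_day=0,
    exposure_end=400,
    observation_end=600,
    events=None,
):
    """Hand-built cohort for toy tests."""
    n = len(arms)
    subjects = pd.DataFrame(
        {
            "arm": list(arms),
            "index_day": np.broadcast_to(index_day, n).copy(),
            "exposure_end_day": np.broadcast_to(exposure_end, n).copy(),
            "observation_end_day": np.broadcast_to(observation_end, n).copy(),
        },
        index=pd.RangeIndex(n, name="subject_id"),
    )
    if age is not None:
        subjects["age"] = age
    if X is None:
        X = np.zeros((n, 0))
    X = np.atleast_2d(np.asarray(X))
    if binary_ids is None:
        binary_ids = [f"x_{j:04d}" for j in range(X.shape[1])]
    if events is None:
        events = pd.DataFrame(columns=["subject_id", "outcome_id", "event_day"])
    else:
        events = pd.DataFrame(events, columns=["subject_id", "outcome_id", "event_day"])
    return Cohort(
        subjects=subjects,
        X=sp.csr_matrix(X),
        binary_ids=np.asarray(binary_ids, dtype=object),
        events=events,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Confounded 2,000-subject cohort with moderately common covariates."""
    return generate_cohort(
        SimConfig(
            n_subjects=2000,
            n_binary_covariates=30,
            n_confounders=6,
            n_negative_controls=8,
            prevalence_range=(0.02, 0.3),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Unconfounded cohort: treatment independent of all covariates."""
    return generate_cohort(
        SimConfig(
            n_subjects=6000,
            n_binary_covariates=20,
            n_confounders=4,
            treatment_coefficients=0.0,
            treatment_age_coefficient=0.0,
            n_negative_controls=10,
            prevalence_range=(0.02, 0.3),
            seed=23,
        )
    )
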