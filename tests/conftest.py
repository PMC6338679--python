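import dataclasses

import numpy as np
import pytest

from lccr import CohortSpec, TrajectoryParams, generate_cohort
from lccr.pipeline import extract_cohort, qc_filter


@pytest.fixture(scope="session")
def noiseless_params() -> TrajectoryParams:
    return TrajectoryParams().noiseless()


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_params):
    """Small fully deterministic cohort: no noise, no motion, no jitter."""
    spec = CohortSpec(n_subjects=40, seed=123)
    subjects, table = generate_cohort(spec, noiseless_params)
    return subjects, table


@pytest.fixture(scope="session")
def multiseed_records():
    """Twenty 605-subject phantom cohorts (default params, no motion),
    extracted and QC-filtered; the basis for the stochastic recovery and
    power checks. Only the per-subject record arrays are kept."""
    out = []
    params = dataclasses.replace(TrajectoryParams(), motion_fraction=0.0)
    for seed in range(20):
        subjects, _ = generate_cohort(CohortSpec(n_subjects=605, seed=seed), params)
        records = extract_cohort(subjects)
        records, _ = qc_filter(records)
        out.append({
            "age": records["age_years"].to_numpy(),
            "whole": records["cr_mean_whole"].to_numpy(),
            "rostral": records["cr_mean_rostral"].to_numpy(),
            "caudal": records["cr_mean_caudal"].to_numpy(),
        })
    return out
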