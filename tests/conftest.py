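"""Shared fixtures: heavy simulation studies are session-scoped so the
recovery/model-comparison computations run once and feed several tests."""

import logging

import numpy as np
import pytest

from seizdcm.experiments import (patient1_recovery_study, null_data_study,
                                 stationary_control_study)
from seizdcm.model_space import ModelSpec
from seizdcm.synthetic_data import patient1_like, simulate_spectra
from seizdcm.variational_laplace import invert

logging.getLogger("seizdcm").setLevel(logging.ERROR)

STUDY_SEED = 1234


@pytest.fixture(scope="session")
def p1_study():
    """Ten-replicate recovery and model-comparison study (patient1-like)."""
    return patient1_recovery_study(seed=STUDY_SEED, n_replicates=10)


@pytest.fixture(scope="session")
def null_study():
    """Full vs null model on ten stationary datasets."""
    return null_data_study(seed=STUDY_SEED, n_replicates=10)


@pytest.fixture(scope="session")
def stationary_control():
    return stationary_control_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def p1_inversion():
    """One patient1-like dataset with its ground truth and full-model posterior."""
    scenario = patient1_like(seed=42)
    data, truth = simulate_spectra(scenario)
    post = invert(data, ModelSpec.full())
    return {"scenario": scenario, "data": data, "truth": truth, "posterior": post}
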