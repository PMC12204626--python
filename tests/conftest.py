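"""Shared fixtures: model defaults and the expensive synthetic studies.

Heavy artefacts (the four-condition count dataset, the event-timing dataset)
are session-scoped so the cross-representation checks and the inference
studies share one copy.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenoadapt.likelihoods import SolverOptions, ThetaVector
from phenoadapt.model_core import ModelSpec
from phenoadapt.pde import PhenotypeGrid
from phenoadapt import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRUE_PARAMS = {
    "gamma1": 0.15,
    "gamma2": -0.3,
    "gamma3": 0.1,
    "gamma4": 0.1,
    "nu": 0.4,
    "beta": 0.05,
}


@pytest.fixture(scope="session")
def true_params():
    return dict(TRUE_PARAMS)


@pytest.fixture(scope="session")
def default_spec():
    return ModelSpec()


@pytest.fixture(scope="session")
def fast_opts():
    return SolverOptions.fast()


@pytest.fixture(scope="session")
def coarse_opts():
    """Settings for sampling loops: coarser but validated unbiased in the
    likelihood-surface comparisons."""
    return SolverOptions(
        grid=PhenotypeGrid(n_nodes=151),
        pde_dt=0.04,
        rate_step=0.14,
        cme_n_max=160,
        cme_dt=0.02,
    )


@pytest.fixture(scope="session")
def count_data_seed1(default_spec):
    """The four-condition count study at the default design, seed 1."""
    return sd.generate_count_data(sd.default_design(), default_spec, rng_seed=1)


@pytest.fixture(scope="session")
def event_data(default_spec):
    """The event-timing study: 10,000 initial cells, 200 bins of 0.035 d."""
    return sd.generate_event_data(default_spec, rng_seed=5)


@pytest.fixture(scope="session")
def count_theta():
    return ThetaVector(
        free_names=("gamma1", "gamma2", "gamma3", "gamma4", "nu", "beta")
    )
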