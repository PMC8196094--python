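import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from pestmix import catalog as cat
from pestmix.design import assemble_design, build_design_z
from pestmix.exposure import ExposureWindow, Residence
from pestmix.simulate import SimulationConfig, simulate_study

JAN1 = dt.date(2000, 1, 1)
DEC31 = dt.date(2000, 12, 31)


@pytest.fixture
def home():
    """A residence at the origin occupied throughout 2000."""
    return Residence("P1", 0.0, 0.0, JAN1, DEC31)


@pytest.fixture
def year_window():
    return ExposureWindow("P1", "prenatal", JAN1, DEC31)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by design/sampler tests."""
    return simulate_study(SimulationConfig(n_subjects=150, seed=42))


@pytest.fixture(scope="session")
def small_design(small_study):
    pests = cat.prenatal_pesticides()
    return assemble_design(
        small_study.exposures,
        small_study.covariates,
        small_study.outcomes,
        "prenatal",
        "maternal",
        "score",
        pests,
    )


@pytest.fixture(scope="session")
def primary_z(small_design):
    return build_design_z(small_design.x_names, cat.default_catalog(), variant="primary")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
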