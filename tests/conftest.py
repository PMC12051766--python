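import dataclasses

import numpy as np
import pytest

from istpdose import (
    CohortConfig,
    PhysicalDecay,
    PopulationPrior,
    default_svalue_fixture,
    generate_cohort,
)


@pytest.fixture(scope="session")
def decay():
    return PhysicalDecay.lu177()


@pytest.fixture(scope="session")
def prior():
    return PopulationPrior.default_fixture()


@pytest.fixture(scope="session")
def mono_prior():
    """A2 = 0 everywhere: pure mono-exponential washout."""
    return PopulationPrior(
        {o: (0.0, 0.0) for o in ("left_kidney", "right_kidney", "liver", "spleen")}
    )


@pytest.fixture(scope="session")
def svalues():
    return default_svalue_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 10-patient cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=10, seed=42))


@pytest.fixture(scope="session")
def noiseless_mono_cohort(mono_prior):
    """Noise-free mono-exponential cohort with every early scan time present."""
    cfg = CohortConfig(
        n_patients=8,
        seed=5,
        noise_cv=0.0,
        schedule_pool_hours=(2.0, 20.0, 43.0, 69.0, 144.0),
        schedule_weights=(1.0, 1.0, 1.0, 1.0, 1.0),
        n_timepoints_range=(5, 5),
    )
    return generate_cohort(cfg, prior=mono_prior)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
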