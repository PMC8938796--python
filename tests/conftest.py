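import numpy as np
import pytest

from spectromics.decompose import decompose
from spectromics.phantom import (
    PhantomSpec,
    make_sensitivity_model,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def sensitivity():
    return make_sensitivity_model()


@pytest.fixture(scope="session")
def noiseless_subject(sensitivity):
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor_semiaxes_vox=(8.0, 7.0, 7.5),
        noise_sd=0.0,
        eid_noise_sd=0.0,
        seed=11,
    )
    return spec, simulate_subject(spec, sensitivity)


@pytest.fixture(scope="session")
def noisy_subject(sensitivity):
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor_semiaxes_vox=(8.0, 7.0, 7.5),
        seed=12,
    )
    return spec, simulate_subject(spec, sensitivity)


@pytest.fixture(scope="session")
def small_cohort(sensitivity):
    """Tiny 2+2 cohort on small grids for structural checks."""
    base = PhantomSpec(grid_shape=(24, 24, 24), tumor_semiaxes_vox=(6.0, 5.0, 5.5))
    return simulate_cohort(2, 2, seed=5, base_spec=base, A=sensitivity)


@pytest.fixture(scope="session")
def small_cohort_tables(small_cohort):
    from spectromics.features import extract_cohort

    maps = [decompose(s.spectral, make_sensitivity_model()) for s in small_cohort.subjects]
    return extract_cohort(small_cohort, maps=maps)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
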