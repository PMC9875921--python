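import numpy as np
import pytest

import ssmnet as sn


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast cohort: 8+8 subjects on a 12^3 grid, 8 parcels."""
    return sn.CohortSpec(n_patients=8, n_controls=8, shape=(12, 12, 12),
                         n_parcels=8, seed=7)


@pytest.fixture(scope="session")
def small_inputs(small_spec):
    mask, atlas, modules, truth = sn.make_default_cohort_inputs(small_spec)
    return small_spec, mask, atlas, modules, truth


@pytest.fixture(scope="session")
def small_cohort(small_inputs):
    spec, mask, atlas, modules, truth = small_inputs
    return sn.simulate_cohort(spec, truth, seed=11)


@pytest.fixture(scope="session")
def default_inputs():
    """The default derivation cohort conditions (20+20, 24^3, 20 parcels)."""
    spec = sn.CohortSpec(seed=1)
    mask, atlas, modules, truth = sn.make_default_cohort_inputs(spec)
    return spec, mask, atlas, modules, truth


@pytest.fixture(scope="session")
def default_cohort(default_inputs):
    spec, mask, atlas, modules, truth = default_inputs
    return sn.simulate_cohort(spec, truth, seed=42)


@pytest.fixture(scope="session")
def default_derivation(default_cohort):
    coh = default_cohort
    return coh, sn.derive_pattern(coh.raw, coh.is_patient)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
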