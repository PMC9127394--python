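import numpy as np
import pytest

import pseudomod as pm


@pytest.fixture(scope="session")
def default_spec():
    return pm.PhantomSpec()


@pytest.fixture(scope="session")
def base_anatomy(default_spec):
    """(labels, mask) of the undeformed phantom."""
    return pm.make_base_labels(default_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return pm.PhantomSpec(tissue_sd={1: 0.0, 2: 0.0, 3: 0.0},
                          noise_sd=0.0, bias_amplitude=0.0,
                          deform_sd_vox=0.0)


@pytest.fixture(scope="session")
def target_subject(default_spec):
    return pm.make_target(default_spec, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def full_mask(shape=(12, 12, 12)):
    return pm.BinaryMask(np.ones(shape, dtype=bool))
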