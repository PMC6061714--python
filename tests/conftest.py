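import numpy as np
import pytest

import rtshift as rt


@pytest.fixture(scope="session")
def spec():
    return rt.DesignSpec.two_factor_default(center_replicates=5)


@pytest.fixture(scope="session")
def design(spec):
    return rt.build_design(spec)


@pytest.fixture(scope="session")
def truth_clean(spec):
    """Noiseless, latent-free ground truth: exact-recovery oracle."""
    return rt.default_ground_truth(spec, noise_sd=0.0, n_latent=0, seed=42)


@pytest.fixture(scope="session")
def ds_clean(design, truth_clean):
    return rt.simulate_retention(design, truth_clean, seed=42)


@pytest.fixture(scope="session")
def truth_default(spec):
    """Study-condition truth: noise 0.03 min, one latent uncontrolled factor."""
    return rt.default_ground_truth(spec, seed=42)


@pytest.fixture(scope="session")
def ds_default(design, truth_default):
    return rt.simulate_retention(design, truth_default, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
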