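import numpy as np
import pytest

from thetamark import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded 17-patient cohort with the planted theta effect."""
    cohort, truth = synthetic.gen_cohort(synthetic.SimConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def pure_var_recording():
    """300-s two-channel recording from the pure generating VAR (no 1/f)."""
    cfg = synthetic.SimConfig(seed=1, duration=300.0, noise_sd=0.0)
    return synthetic.gen_coupled_recording(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
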