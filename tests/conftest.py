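import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cycleplate.simulate import NoiseModel, PhenotypeState, UNTREATED_MIXTURE, sample_population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def noiseless():
    """Noise model with every stochastic term switched off."""
    return NoiseModel(dna_cv=0.0, area_cv=0.0, readout_cv=0.0, rng_seed=0)


@pytest.fixture
def default_noise():
    """Default staining/readout noise (6 % DNA CV)."""
    return NoiseModel(rng_seed=0)


@pytest.fixture
def control_sample(default_noise):
    """Pooled vehicle-control cells for reference estimation."""
    return sample_population(
        UNTREATED_MIXTURE, 3000, default_noise, rng=np.random.default_rng(1234)
    )


@pytest.fixture
def five_state_mixture():
    """A mixture covering every cell-cycle bin, with known weights."""
    return (
        (PhenotypeState("subG1"), 0.10),
        (PhenotypeState("G1"), 0.30),
        (PhenotypeState("S"), 0.20),
        (PhenotypeState("G2M"), 0.30),
        (PhenotypeState("endoredup"), 0.10),
    )
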