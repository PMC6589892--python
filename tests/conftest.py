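import numpy as np
import pytest

from imprintseq.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with imprinting and reference bias, reused across tests."""
    cfg = SimulationConfig(
        n_genes=200,
        n_samples=30,
        imprinted_fraction=0.05,
        ref_bias_genes=4,
        ref_bias_strength=0.95,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
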