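import numpy as np
import pytest

from wsinet import SimulationConfig


@pytest.fixture
def small_config():
    """Tiny but structurally complete study configuration."""
    return SimulationConfig(
        n_genes=60,
        n_replicates_per_contrast=4,
        frac_immune_module=0.1,
        base_fc_appwt=2.0,
        delta_bk=1.0,
        delta_hoe=-1.0,
        noise_sd=0.3,
        n_interactions=120,
        hub_exponent=1.5,
        human_correlation=0.5,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
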