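import pytest

from fretquant.synthdata import SimConfig, SpilloverTruth


@pytest.fixture
def base_config() -> SimConfig:
    """Default study conditions at a modest sample size."""
    return SimConfig(seed=0, n_cells=2000)


@pytest.fixture
def clean_config() -> SimConfig:
    """Noise-free, background-free, unmixed conditions for exact checks."""
    return SimConfig(
        seed=0,
        n_cells=500,
        p_transfected=1.0,
        mixing=SpilloverTruth.identity(),
        autofl_mu=None,
        noise_cv=0.0,
        doublet_fraction=0.0,
    )
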