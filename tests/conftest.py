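import numpy as np
import pytest

from mapc_gibbsos.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete benchmark configuration."""
    return SimulationConfig(
        n_foreground=40, n_background=60, n_tfs=24, n_samples=16,
        n_modules=2, snr_db=10.0, fp_ratio=1.0, binding_degree=3,
        tfs_per_module=5, bg_binding_degree=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
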