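import numpy as np
import pytest

from reposyn import SimConfig


@pytest.fixture
def small_config():
    """Small planted-truth configuration for fast unit tests."""
    return SimConfig(seed=11, n_genes=200, n_samples_per_group=4, n_systems=3,
                     core_up_size=15, core_down_size=15, effect_logfc=2.0,
                     dropout_prob=0.2, noise_sd=0.5, n_perturbagens=12,
                     conditions_per_perturbagen=12, n_cell_lines=3,
                     reverser_ids=("CP0002", "CP0007"), reverser_strength=2.0)


@pytest.fixture
def default_config():
    """Benchmark-scale configuration (the package defaults)."""
    return SimConfig(seed=5)


@pytest.fixture
def dose_grid():
    return np.geomspace(0.25, 4.0, 6)
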