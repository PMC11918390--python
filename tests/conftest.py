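import numpy as np
import pytest

from ironblock import Model, default_config
from ironblock.block import (BlockAssayConfig, basal_state, block_curve,
                             control_readout)

_H = 3600.0


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def model(cfg):
    return Model(cfg)


@pytest.fixture(scope="session")
def basal(model):
    """Basal steady state (luminal iron clamped at the dietary baseline)."""
    return basal_state(model)


@pytest.fixture(scope="session")
def coarse_assay():
    """A 61-point interval grid: the full 300-point grid is reserved for
    production runs."""
    return BlockAssayConfig(intervals=np.linspace(0.0, 72 * _H, 61))


@pytest.fixture(scope="session")
def baseline_curve(model, coarse_assay, basal):
    return block_curve(model, coarse_assay, basal=basal)


@pytest.fixture(scope="session")
def control(model, coarse_assay, basal):
    """(uptake, transfer) readout of the no-loading-dose control."""
    return control_readout(model, coarse_assay, basal=basal)


def random_states(model, n, seed=0, scale=10.0):
    """Random positive states spanning several orders of magnitude around
    biologically plausible intensive values."""
    rng = np.random.default_rng(seed)
    base = np.maximum(model.initial_amounts(), model.species_size * 1e-12)
    for _ in range(n):
        factors = scale ** rng.uniform(-1.0, 1.0, size=base.shape)
        yield base * factors
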