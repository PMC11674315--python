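import numpy as np
import pytest

import axogrow as ax


@pytest.fixture(scope="session")
def small_layout():
    """Perturbed 10-node layout on a unit-ish circle for cheap tests."""
    return ax.perturb_nodes(ax.place_nodes(5.0, 10), 1.0, seed=7)


@pytest.fixture(scope="session")
def default_layout_seeded():
    """Full-scale 84-node layout with the default radius."""
    return ax.default_layout(radius=30.0, n_nodes=84, rho=1.0, seed=3)


@pytest.fixture(scope="session")
def small_model_network(default_layout_seeded):
    """A reduced-axon-count model network reused across statistics tests."""
    cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=20_000, seed=5)
    return ax.build_network(ax.simulate_axons(default_layout_seeded, cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
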