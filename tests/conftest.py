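import numpy as np
import pytest

from nicheshift import geo_io, maxent, synthetic


@pytest.fixture
def geometry():
    return geo_io.GridGeometry(n_rows=20, n_cols=30, x_min=-5.0, y_min=38.0,
                               cell_size=0.1)


@pytest.fixture
def small_scenario():
    """A 60x60 seven-layer landscape with two taxa occupying opposite
    climate gradients, confined to a patchy soil mask."""
    cfg = synthetic.ScenarioConfig(grid_rows=60, grid_cols=60, seed=0)
    cfg.niches["tax_a"] = synthetic.TrueNiche(
        "tax_a", 0.0,
        beta_linear=np.array([2.0, 0, 0, 0, -1.0, 0, 0.5]),
        beta_quadratic=np.array([-1.0, 0, 0, 0, 0, 0, 0]),
    )
    cfg.niches["tax_b"] = synthetic.TrueNiche(
        "tax_b", 0.0,
        beta_linear=np.array([-2.0, 0, 0, 0, 1.0, 0, -0.5]),
        beta_quadratic=np.array([-1.0, 0, 0, 0, 0, 0, 0]),
    )
    cfg.n_occurrences = {"tax_a": 60, "tax_b": 60}
    cfg.era_shifts = {
        "lgm": np.array([-3.0, 0.5, -2.0, 1.0, 1.5, -0.5, 0.8]),
        "mid_holocene": np.array([-1.0, 0.2, -0.7, 0.3, 0.5, -0.2, 0.3]),
    }
    return cfg


@pytest.fixture
def small_stack(small_scenario):
    return synthetic.generate_layers(small_scenario, seed=0)


@pytest.fixture
def small_background(small_stack):
    return maxent.sample_background(small_stack, n=1500, seed=42)
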