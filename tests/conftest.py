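import numpy as np
import pytest

from cdksize import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """A modest population config used across tests."""
    return syn.SimConfig(seed=1, n_cells=200)


@pytest.fixture
def rendered_cell(small_config):
    """One rendered cell image with known ground truth (N/C=2, level=400)."""
    rng = np.random.default_rng(7)
    _, truth = syn.simulate_population(small_config)
    row = truth.iloc[0].copy()
    row["true_nc"] = 2.0
    row["true_level_au"] = 400.0
    img = syn.render_cell_image(row, small_config, rng=rng)
    return img, row, small_config
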