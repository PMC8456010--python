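"""Shared fixtures: a small ground-truthed synthetic study."""

import numpy as np
import pandas as pd
import pytest

import nichepheno as nf
from nichepheno import geodata as gd


@pytest.fixture(scope="session")
def small_config():
    return nf.LandscapeConfig(grid_shape=(60, 60), n_layers=12, seed=0)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(stack, sites, truth, traits) on a 60x60 grid, 12 layers, seed 0."""
    return nf.simulate_study(small_config)


@pytest.fixture(scope="session")
def sdm_inputs(small_study):
    """Presence/background environment tables from the small study."""
    stack, sites, truth, _ = small_study
    pres_pts = nf.sample_presences(stack, truth.true_suitability, 260, 11)
    pres = gd.extract_env(pres_pts, stack)
    cells = stack.cell_table()
    return stack, truth, pres, cells


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_groups():
    """Three groups of 8 with one discriminating and one null trait."""
    rng = np.random.default_rng(7)
    rows = []
    for g, shift in zip("ABC", (0.0, 1.5, 3.0)):
        for _ in range(8):
            rows.append({"population_id": g, "sex": "hen",
                         "signal": shift + rng.normal(0, 1.0),
                         "null": rng.normal(0, 1.0)})
    return pd.DataFrame(rows)
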