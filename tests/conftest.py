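import numpy as np
import pandas as pd
import pytest

from deprivdiff import SimulationConfig, simulate_region


@pytest.fixture(scope="session")
def small_region():
    """A 20x20 synthetic region at the default study conditions (seed 11)."""
    table, graph = simulate_region(SimulationConfig(grid_rows=20, grid_cols=20, seed=11))
    return table, graph


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def series_pair(rng):
    """A correlated (imd, ald)-like pair of series on 40 areas."""
    ids = [f"a{i:02d}" for i in range(40)]
    imd = pd.Series(rng.gamma(2.0, 10.0, 40), index=ids)
    ald = pd.Series(0.7 * imd.to_numpy() + rng.normal(0, 4.0, 40), index=ids)
    return imd, ald
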