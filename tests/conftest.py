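import numpy as np
import pandas as pd
import pytest

from ecobarriers import cost_paths as cp
from ecobarriers import pair_assembly as pa
from ecobarriers.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact mid-latitude world shared by read-only tests."""
    cfg = WorldConfig(
        grid_n_lat=12,
        grid_n_lon=16,
        lat_range=(10.0, 58.0),
        lon_range=(0.0, 64.0),
        years=20,
        n_societies=40,
        seed=12345,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_graph(small_world):
    return cp.build_graph(small_world.th)


@pytest.fixture(scope="session")
def small_barriers(small_world, small_graph):
    pairs = pa.nearest_pairs(small_world.societies, k=10)
    th = cp.node_env_values(small_graph, small_world.th)
    ai = cp.node_env_values(small_graph, small_world.ai)
    elev = cp.node_env_values(small_graph, small_world.elevation)
    return cp.compute_pair_barriers(
        small_world.societies, pairs, small_graph, th, ai, elev
    )


@pytest.fixture
def societies_on_line():
    """Twelve societies on a meridian for neighbourhood-statistic fixtures."""
    n = 12
    return pd.DataFrame(
        {
            "id": [f"P{k:02d}" for k in range(n)],
            "lat": np.linspace(0.0, 11.0, n),
            "lon": np.zeros(n),
        }
    )
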