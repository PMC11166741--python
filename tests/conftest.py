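import numpy as np
import pytest

from surfage.graphops import coarsen_graph
from surfage.synthetic_cortex import (
    SimulationConfig,
    make_icosphere,
    mesh_adjacency,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def ico1():
    return make_icosphere(1, hemispheres=2)  # 84 vertices


@pytest.fixture(scope="session")
def ico2():
    return make_icosphere(2, hemispheres=2)  # 324 vertices


@pytest.fixture(scope="session")
def ico3():
    return make_icosphere(3, hemispheres=2)  # 1,284 vertices


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort at level-2 resolution for unit tests."""
    cfg = SimulationConfig(n_subjects=60, mesh_level=2, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def hierarchy2(ico2):
    return coarsen_graph(mesh_adjacency(ico2), 3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
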