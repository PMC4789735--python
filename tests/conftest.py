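import numpy as np
import pytest

from junctionlab.geometry import default_templates, idealized_geometry
from junctionlab.topology import (
    build_topology,
    core_marker_index_pairs,
    synthetic_junction_sequences,
)


@pytest.fixture(scope="session")
def j34_topology():
    """Full-size junction: four 34-nt strands, 17-bp arms."""
    return build_topology(synthetic_junction_sequences(17), 17)


@pytest.fixture(scope="session")
def toy_topology():
    """Small junction (5-bp arms) for cheap structural tests."""
    return build_topology(synthetic_junction_sequences(5), 5)


@pytest.fixture(scope="session")
def marker_pairs(j34_topology):
    return core_marker_index_pairs(j34_topology)


@pytest.fixture(scope="session")
def templates(j34_topology):
    return default_templates(j34_topology)


@pytest.fixture(scope="session")
def all_templates(j34_topology):
    return {
        name: idealized_geometry(j34_topology, name)
        for name in ("open_planar", "open_tetrahedral", "iso_I", "iso_II")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
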