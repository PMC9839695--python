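import numpy as np
import pytest

from molhnn.hypergraph import (
    Conformation, ExclusionRule, build_chain_topology,
)
from molhnn.synthetic import SyntheticConfig, chain_coordinates, generate_chain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain5():
    """5-atom chain, default exclusion (1-2/1-3/1-4 pairs excluded)."""
    return build_chain_topology(5, charges=[0.1, -0.1, 0.1, -0.1, 0.1])


def random_chain_conformation(topology, rng, width=0.4):
    """A geometrically valid conformation of a chain topology."""
    n = topology.n_atoms
    bonds = 1.5 + 0.05 * rng.standard_normal(n - 1)
    angles = np.clip(1.9 + width * rng.standard_normal(n - 2), 0.3, np.pi - 0.3)
    dihedrals = rng.uniform(-np.pi, np.pi, max(n - 3, 0))
    return Conformation(chain_coordinates(bonds, angles, dihedrals)[0])


@pytest.fixture
def chain5_conf(chain5, rng):
    return random_chain_conformation(chain5, rng)


@pytest.fixture
def tri_config():
    return SyntheticConfig(n_residues=3, n_samples=200, seed=11)


@pytest.fixture
def tri_topology(tri_config):
    return generate_chain(tri_config)
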