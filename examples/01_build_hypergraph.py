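"""Represent one conformation of a small chain as a molecular hypergraph.

Each force-field interaction becomes a hyperedge with a 5-slot feature
vector (bond flag, Coulomb force, van der Waals force, angle, dihedral);
only the slot matching the interaction kind is filled.
"""

import numpy as np

from molhnn import build_hypergraph, representation_size
from molhnn.hypergraph import Conformation
from molhnn.synthetic import SyntheticConfig, generate_chain, sample_ensemble

config = SyntheticConfig(n_residues=3, seed=0)
topology = generate_chain(config)
coords = sample_ensemble(topology, config, n_samples=1).coords[0]
H = build_hypergraph(topology, Conformation(coords))

print(f"{H.n_vertices} atoms, {H.n_hyperedges} hyperedges")
for kind in ("bond", "coulomb", "vdw", "angle", "dihedral"):
    n = sum(e.kind == kind for e in H.hyperedges)
    print(f"  {kind:9s} {n:3d}")
print("first angle hyperedge features:",
      np.round(next(e for e in H.hyperedges if e.kind == "angle").features, 3))
print("storage for one conformation:", representation_size(H), "floats")
# The angle feature (slot 4) is the valence angle in radians; every other
# slot is exactly zero because a hyperedge encodes one interaction kind.
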