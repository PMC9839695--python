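"""Run hypergraph message passing and flatten the learned representation.

Two layers exchange sigmoid-activated messages between atoms and
interaction hyperedges; the result is one hidden vector per atom and
per hyperedge, concatenated into a single conformation fingerprint.
"""

import numpy as np

from molhnn import HnnConfig, HnnModel
from molhnn.hmpnn import run_layers
from molhnn.pooling import flatten_representation
from molhnn.synthetic import SyntheticConfig, generate_chain, sample_ensemble
from molhnn.transfer import featurize

config = SyntheticConfig(n_residues=3, seed=0)
topology = generate_chain(config)
data = featurize(topology, sample_ensemble(topology, config, 2).coords)

model = HnnModel(HnnConfig(d_h=16, n_layers=2, seed=0))
state = run_layers(data.X0, data.W[0], data.B, model.detached_layers())
x = flatten_representation(state)

print("vertex representations:", state.X.shape)      # (9 atoms, 16)
print("hyperedge representations:", state.W.shape)   # (51 edges, 16)
print("flattened fingerprint length:", x.size)       # 9*16 + 51*16 = 960
print("fingerprint excerpt:", np.round(x[:6], 4))
# The fingerprint length scales with molecule size — the pooling layer
# (example 03) maps it to a fixed-size vector for classification.
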