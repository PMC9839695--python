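"""Interest-point pooling: compare molecules of different sizes.

A sliding cosine window against K-means "points of interest" turns a
variable-length fingerprint into a fixed 3k vector (min/mean/max of the
window similarities per point), so one classifier head serves both a
3-residue and a 10-residue chain.
"""

import numpy as np

from molhnn.pooling import pool, select_points_of_interest, sliding_similarity

rng = np.random.default_rng(0)

# worked example: three windows of [1,0] slide over [1,0,0,1]
v = sliding_similarity(np.array([1.0, 0, 0, 1]), np.array([1.0, 0]))
print("window similarities:", v)            # [1, 0, 0]
print("pooled (min, mean, max):", pool(np.array([1.0, 0, 0, 1]),
                                       np.array([[1.0, 0]])))

# points of interest from 50 reference fingerprints of length 30
reference = rng.standard_normal((50, 30))
P = select_points_of_interest(reference, k=4, seed=0)
short = pool(rng.standard_normal(30), P)    # same length as the points
long = pool(rng.standard_normal(110), P)    # a much larger molecule
print("pooled length, small molecule:", short.size)
print("pooled length, large molecule:", long.size)
# Both are 3k = 12: molecule size never changes the classifier input.
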