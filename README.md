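# molhnn

Hypergraph neural networks for classifying low vs high free-energy
peptide conformations, with **zero-shot transfer** from a small training
peptide to a larger, unseen one.

## The problem

Free-energy surfaces of even modest peptides are expensive to converge
with enhanced-sampling molecular dynamics, and the cost explodes with
system size. If a classifier can learn *which conformations are
thermodynamically favorable* on a small system — where free energies
are cheap — and apply that knowledge to a larger, chemically related
system using its **structures only**, the large system's free-energy
calculation can be skipped entirely. `molhnn` is a desk-scale,
fully testable implementation of that idea, aimed at method developers
in molecular machine learning and computational structural biology.

## The method

**Representation.** A conformation becomes a hypergraph `H(V, E, X, W)`:
vertices are atoms (features `X_v = [mass, radius]`), hyperedges are the
force-field interaction terms — bonds, Coulomb and van der Waals pairs
(`|e| = 2`), valence angles (`|e| = 3`), dihedrals (`|e| = 4`). Each
hyperedge carries a 5-slot feature vector `W_e` with exactly one slot
filled: bond indicator, Coulomb force, Lennard-Jones force, angle (rad),
or torsion (rad). All features are internal coordinates, so the
representation is invariant to rigid motion. Storage is
`3n² + 2n + 7e` floats per conformation.

**Message passing.** Per layer, with sigmoid messages and sum
aggregation over the incidence structure:

    M_v   = σ(L_fv(X_v))
    W_e'  = L_gw(W_e) + Σ_{v∈e} M_v
    M_e   = σ(L_fw([W_e ; Σ_{v∈e} M_v]))
    X_v'  = L_gv(X_v) + Σ_{e∋v} M_e

where each `L` is a learnable affine map (two layers by default).

**Pooling.** Vertex + hyperedge representations are flattened into one
vector `x` whose length depends on molecule size. `k` *points of
interest* (K-means centroids of training-set representations) give
fixed references `p_i`; a cosine sliding window of the shorter vector
over the longer one yields similarities whose (min, mean, max) per
point form a fixed 3k vector, classified by a linear + sigmoid head
into `P(low free energy)`.

**Zero-shot transfer.** Training minimizes

    BCE + λ₂ Σ‖θ‖² + λ_T ‖HMPNN₂(HMPNN₁(r_D))‖₂

where `r_D` is the sum of the right singular vectors of the matrix of
flattened *target* hypergraph features — the only target information
used, never an energy. Labels come from the source system's empirical
free energy: low iff `F − F_min ≤ 8 kJ/mol`.

**Synthetic data.** A generator emulates poly-alanine-like ensembles:
3 pseudo-atoms per residue, two dihedral basins per torsion, and
cooperative whole-chain basin patterns (helix-like, hairpin-like,
extended) with weights (0.5, 0.3, 0.2). Free energies follow
`F(s) = −(1/β) ln P̂(s)` on a wrapped grid over the central dihedrals,
so the low/high ground truth is known exactly for any chain length.

## Worked example

`examples/04_transfer_training.py` trains on a labeled 3-residue chain
and predicts an unseen 5-residue chain:

```text
   conformation  probability decision
0             0     0.556025      low
1             1     0.556027      low
2             2     0.555897      low
3             3     0.556006      low
4             4     0.555972      low
zero-shot transfer AUC on the unseen 5-residue chain: 0.997
```

The probability column is `P(low free-energy)`; the AUC is computed
against the target's own free energies, which were held back from
training — near 1 means the model ranks the target's thermodynamically
favorable conformations above the unfavorable ones without ever seeing
a target energy. The other scripts in `examples/` walk through the
hypergraph representation, message passing, pooling, and the
cluster-agreement test.

A thin CLI mirrors the library: `molhnn simulate`, `molhnn train`,
`molhnn predict`, `molhnn evaluate`, `molhnn cluster-test`
(see `molhnn --help`).

## Layout

- `src/molhnn/hypergraph.py` — topology, geometry, hypergraph assembly
- `src/molhnn/hmpnn.py` — message-passing layers and the model container
- `src/molhnn/pooling.py` — interest-point pooling and classifier head
- `src/molhnn/transfer.py` — labels, splits, losses, training, prediction
- `src/molhnn/evaluation.py` — ROC/AUC, precision/recall, cluster tests
- `src/molhnn/synthetic.py` — the synthetic peptide generator
- `src/molhnn/autodiff.py` — minimal reverse-mode autodiff over numpy
- `docs/methods.md` — modelling assumptions, parameters, limitations
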