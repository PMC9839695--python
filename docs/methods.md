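# Methods

## Model

A molecular conformation is a hypergraph `H(V, E, X, W)`. Vertices are
atoms; hyperedges are the interaction terms a classical force field
enumerates: covalent bonds, non-bonded pairs, valence angles and
torsions. A non-bonded pair contributes *two* hyperedges — one Coulomb,
one van der Waals — so that each hyperedge fills exactly one slot of
its 5-dimensional feature vector (bond indicator, Coulomb force, LJ
force, angle, dihedral). Forces are the signed radial derivatives of
the pair potentials: `F_C = k_e q_i q_j / r²` and
`F_LJ = 24ε(2σ¹²/r¹³ − σ⁶/r⁷)`, positive = repulsive. The
representation uses internal coordinates only and is therefore
invariant under rigid motion and unaffected by the absolute frame of
the input PDB.

Non-bonded pairs default to the `excl_12_13_14` exclusion rule (pairs
already covered by a bond, angle or dihedral term are excluded), the
common convention in classical force fields; it is configurable,
including no exclusion at all, and no distance cutoff is applied by
default because the chains handled here are small. Hyperedges are
stored in a fixed canonical order (bond < coulomb < vdw < angle <
dihedral, lexicographic members within a kind): the pooling stage
consumes a *flattened* feature vector, so a deterministic layout is
part of the model's definition, not an implementation detail.

Vertex features default to `[mass, radius]`; a configuration switch
substitutes `[atomic_number, partial_charge]`. Both are size-2, so the
network shape is unchanged.

### Message passing

Each layer computes, with sum aggregation and sigmoid activations,

    M_v      = σ(L_fv(X_v))
    agg_e    = Σ_{v∈e} M_v
    W_e(t+1) = L_gw(W_e(t)) + agg_e
    M_e      = σ(L_fw([W_e(t) ; agg_e]))       (pre-update W)
    X_v(t+1) = L_gv(X_v(t)) + Σ_{e∋v} M_e

The messaging functions are affine maps followed by elementwise
sigmoids applied to the concatenation of their inputs — the single form
consistent with both a "linear + sigmoid" reading and a "concatenate
then sigmoid" reading, and the only one that keeps the messages
learnable. One parameter set is shared across hyperedge kinds; the
hyperedge *features* carry the kind information. All messages and
updated representations share one hidden width `d_h` (default 16),
forced by the update form `L(x) + m`: the linear output must match the
message dimension. Two layers by default. Parameters are initialized
uniformly in `[−1/√fan_in, 1/√fan_in]` from a seeded generator, so
training runs are bit-reproducible.

Aggregation is implemented as dense incidence-matrix products
(`B @ M_v`, `Bᵀ @ M_e`), which are identical to the membership-list
double loop (tested against it) and vectorize over a batch axis — all
conformations of one topology share `B`, so a whole trajectory is one
set of matrix products.

### Pooling and classification

After message passing, vertex rows then hyperedge rows are concatenated
into a fingerprint `x` of length `(|V| + |E|)·d_h`. `k` points of
interest (default 8) are K-means centroids of the *training-system*
fingerprints — the training system is the only labeled one and K-means
needs fixed-dimension inputs, which fixes the provenance question.
Similarity between `x` and a point `p` is the cosine computed over a
sliding window of length `min(|x|, |p|)` moving with step 1 along the
longer vector (the roles swap symmetrically if `x` is shorter); a
window with zero norm contributes similarity 0, a neutral value that
keeps the min/mean/max reductions well defined. The pooled vector
`l ∈ R^{3k}` stacks (min, mean, max) per point; a single linear layer +
sigmoid maps it to `P(low free energy)`, with decision `low` iff
`p ≥ t` (boundary included).

When `|x| = |p|` (training and validation on the source system) the
window is the whole vector and min = mean = max = cos(x, p); the
training path exploits this closed form so gradients flow through a
single cosine, while prediction on larger systems uses FFT-based
correlation for the full sliding window. The two paths agree to
~1e-13 and are tested against a per-window loop oracle.

Points of interest are constants between refreshes: every 5 epochs
(configurable) the fingerprints are recomputed with the current layer
parameters and K-means is rerun with the same seed. Gradients do not
flow through the points — the refresh schedule, not joint optimization,
keeps them current.

### Transfer objective

Training minimizes `BCE + λ₂ Σ‖θ‖² + λ_T ‖layers(r_D)‖₂` (defaults
λ₂ = 1e-5, λ_T = 1e-3, Adam, lr 1e-3, batch 32). The binary cross
entropy carries the conventional leading minus sign and clamps
probabilities at 1e-12. `r_D` is computed once per run: the rows of `D`
are the flattened *raw* hypergraph features of the target
conformations; `D`'s right singular vectors (equivalently the
eigenvectors of `DᵀD`) with singular value above `1e-10 · s_max` are
sign-fixed (largest-magnitude component positive, removing the SVD
sign ambiguity) and summed. Because `r_D` is a flat vector but the
layers consume hypergraphs, it is unflattened onto the target
topology's `(X, W)` layout — the representative is treated as one
synthetic conformation of the target system — and pushed through the
message-passing layers; the Euclidean norm of the output is the
regularizer. The training loop refuses target free energies outright
(`ZeroShotViolationError`) and strips target labels: the zero-shot
contract is enforced, not assumed.

Splits: `consecutive_5` assigns every run of five consecutive frames
train/val/val/test/test (20/40/40), matching how trajectory frames are
interleaved in time; `random_20_20_60` is a seeded shuffle. The best
model is selected by validation BCE; the per-epoch history logs the
three loss terms separately.

## Synthetic study conditions

The generator emulates, at desk scale, enhanced-sampling ensembles of
short poly-alanine peptides. Each residue contributes three backbone
pseudo-atoms (masses 12/12/14 amu, radii 1.7/1.7/1.55 Å, alternating
±0.1 e charges), so an R-residue chain has 3R atoms and 3R−3 torsions
(φ/ψ analogues). Bonds sit at 1.5 ± 0.02 Å, angles at 1.9 ± 0.03 rad;
each torsion has two basins at −1.2 and +1.0 rad with wrapped-normal
width 0.25 rad, emulating the Ramachandran bimodality. Cartesian
coordinates are built by sequential internal-to-Cartesian placement,
which reproduces the drawn internal coordinates exactly (tested).

Basin occupation is **cooperative** by default: a whole-chain pattern —
helix-like (all first-basin), hairpin-like (N-half first, C-half
second), extended (all second-basin) — is drawn per sample with weights
(0.5, 0.3, 0.2). Cooperativity is the feature that makes the
free-energy structure transferable across chain lengths, exactly as
secondary-structure families do in real peptides; fully independent
per-dihedral basin choice is available (`independent_basins=True`) but
then the energetic signal does not generalize across sizes. Free
energies use the unbiased estimator `F(s) = −(1/β) ln P̂(s)` on a
wrapped grid over the two central torsions (2 bins per dimension with
the bin edge at −0.1 rad, i.e. the basin boundary), shifted so the
global minimum is 0. With β = 0.09 mol/kJ the family free energies are
0, ln(5/3)/β ≈ 5.7 and ln(2.5)/β ≈ 10.2 kJ/mol, so the 8 kJ/mol
threshold labels helix- and hairpin-like conformations low (~80%) and
extended ones high (~20%) — for *any* chain length, which is what a
transfer experiment needs. β here is a synthetic temperature scale
chosen to place the family gaps around the threshold; only the gaps
matter, not β itself.

The cluster generator builds 10 clusters in the 4 helix / 2 hairpin /
4 extended family split: each cluster representative is its family
pattern plus a small fixed per-torsion center offset (≤ 0.03 rad,
making representatives geometrically distinct), and members jitter
around it with width 0.15 rad. A classical potential
(harmonic bonds/angles, cosine-series torsions, LJ + Coulomb
non-bonded) is provided for energy-based checks and alternative
labeling.

What the generator does *not* emulate: real force-field parameters and
chemistry, excluded-volume self-avoidance, hydrogen-bond-driven
cooperativity (cooperativity is imposed, not emergent), solvent, and
metadynamics bias/reweighting. Passing tests therefore demonstrate
that the architecture and training machinery recover a known,
length-transferable free-energy structure from geometry — not that the
method's accuracy on real MD data is reproduced.

## Numerical choices

- Float64 throughout; the autodiff engine is validated against central
  finite differences (1e-5 relative) on the full objective.
- Dihedrals follow the IUPAC sign convention via the two-plane atan2
  formula, range (−π, π]; angles via arccos with clipped cosines.
  Degenerate geometry (coincident atoms, undefined planes) raises a
  named error rather than returning NaN.
- Empirical free energy of never-visited bins is +∞; labels shift the
  minimum to 0 before thresholding and the low interval is closed.
- K-means deduplicates fingerprints and weights them by multiplicity,
  which makes the centroids provably invariant under duplicated
  conformations; `k` must not exceed the number of distinct
  fingerprints.
- Wilcoxon signed rank: pairing by sample index, equal cluster sizes
  required (unequal sizes raise with an instruction to truncate), zero
  differences dropped, all-zero case returns p = 1; exact null for
  n ≤ 25, normal approximation with continuity correction above. No
  multiple-testing correction by default (the 0.01 threshold is
  per-pair); Bonferroni and an unpaired rank-sum variant sit behind
  flags.
- AUC is the trapezoidal integral of the ROC curve, equal to the
  Mann–Whitney pair-counting statistic with ties counted ½ (tested).
- RMSD uses Kabsch superposition (optimal rigid alignment) after
  centering.

## Problem sizes

The shipped experiment — also run by `scripts/acceptance.py` and the
acceptance tests — uses 5000 source conformations (3 residues, 1000
train / 2000 val / 2000 test under `consecutive_5`), 2000 target
conformations (10 residues), 30 epochs, `d_h = 16`, `k = 8`, and 10
clusters × 100 members for the agreement test. These sizes were chosen
so the full pipeline completes in about a minute on one CPU while
keeping every estimate comfortably away from its acceptance margin
(transfer AUC ≥ 0.95 across seeds against the 0.80 bar; cluster
agreement ≥ 0.91 against 0.80).

## Known limitations

- Prediction probabilities are not calibrated across system sizes: the
  sliding-window statistics shift the pooled features' scale between
  source and target, so rankings (AUC) transfer while the absolute
  `p ≥ t` decision threshold may need target-side recalibration.
- Points of interest are frozen between refreshes; a stale set early in
  training briefly mismatches the moving representations.
- The dense incidence matrix is quadratic in memory for very large
  molecules; fine up to thousands of atoms, not for proteins at atomic
  resolution.
- `independent_basins` mode deliberately breaks length transfer; it
  exists for calibration and negative-control experiments.
- Regression of absolute free energies is out of scope; the model is a
  classifier.
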