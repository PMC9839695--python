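"""Synthetic peptide-like chains with a known free-energy structure.

The generator emulates, at desk scale, the kind of data an enhanced-
sampling MD campaign on short poly-alanine peptides produces: a chain
topology, an ensemble of conformations whose backbone dihedrals occupy
a small number of basins, and free-energy labels derived from how often
each basin is visited.

Model
-----
Each residue contributes ``atoms_per_residue`` (default 3) backbone
pseudo-atoms, so a chain of R residues has ``3R`` atoms and ``3R - 3``
dihedrals (phi/psi analogues).  Every dihedral has two basins (default
centers -1.2 and +1.0 rad, emulating the Ramachandran bimodality).  By
default basin occupation is *cooperative*: a whole-chain basin pattern
(a conformational family — helix-like all-A, hairpin-like half A half
B, extended all-B) is drawn per sample, then each dihedral is sampled
from a wrapped normal around its pattern center.  Cooperative basins
are what make the free-energy structure transferable across chain
lengths; fully independent per-dihedral basin choice is available with
``independent_basins=True``.

Free energies come from the unbiased estimator F(s) = -(1/beta) ln P(s)
on a wrapped grid over a low-dimensional collective variable s (default
the two central dihedrals), shifted so the global minimum is 0 kJ/mol.
With the default pattern weights (0.5, 0.3, 0.2) and beta = 0.09
mol/kJ, the helix- and hairpin-like families sit below the 8 kJ/mol
threshold and the extended family above it, so both label classes are
populated for any chain length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .hypergraph import (
    Conformation, ExclusionRule, NonbondedParams, Topology,
    bond_distances, angle_values, dihedral_values, build_chain_topology,
)

__all__ = [
    "SyntheticConfig", "EnergyTerms", "SyntheticEnsemble", "SyntheticClusters",
    "generate_chain", "sample_conformations", "sample_ensemble",
    "toy_potential_energy", "empirical_free_energy", "free_energy_labels",
    "make_synthetic_clusters", "rmsd", "FAMILY_NAMES",
]

FAMILY_NAMES = ("helix", "hairpin", "extended")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic ensembles."""

    n_residues: int = 3
    atoms_per_residue: int = 3
    # dihedral basins (rad)
    basin_centers: tuple[float, float] = (-1.2, 1.0)
    basin_width: float = 0.25            # wrapped-normal sd within a basin
    pattern_weights: tuple[float, ...] = (0.5, 0.3, 0.2)   # helix/hairpin/extended
    independent_basins: bool = False
    basin_weights: tuple[float, float] = (0.7, 0.3)        # used when independent
    # bonded geometry
    bond_length: float = 1.5             # Å
    bond_jitter: float = 0.02            # Å
    bond_stiffness: float = 300.0        # kJ/mol/Å^2
    angle_value: float = 1.9             # rad (~109 deg)
    angle_jitter: float = 0.03           # rad
    angle_stiffness: float = 150.0       # kJ/mol/rad^2
    # dihedral cosine series: (k [kJ/mol], multiplicity, phase [rad])
    dihedral_terms: tuple[tuple[float, int, float], ...] = ((4.0, 1, 0.0),)
    # non-bonded parameters
    epsilon: float = 0.2                 # kJ/mol
    sigma: float = 1.0                   # Å
    charge_magnitude: float = 0.1        # alternating +/- partial charges
    # thermodynamics
    beta: float = 0.09                   # mol/kJ, inverse thermal energy
    energy_threshold: float = 8.0        # kJ/mol low/high boundary
    # sampling
    n_samples: int = 1000
    seed: int = 0

    @property
    def n_atoms(self) -> int:
        return self.n_residues * self.atoms_per_residue

    def __post_init__(self):
        if self.beta <= 0 or self.basin_width <= 0:
            raise ValueError("beta and basin widths must be positive")
        w = np.asarray(self.pattern_weights)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("pattern weights must sum to 1")


@dataclass(frozen=True)
class EnergyTerms:
    """Classical potential-energy decomposition (kJ/mol)."""

    e_bond: float
    e_nonbond: float
    e_angle: float
    e_dihedral: float

    @property
    def total(self) -> float:
        return self.e_bond + self.e_nonbond + self.e_angle + self.e_dihedral


def generate_chain(config: SyntheticConfig) -> Topology:
    """Backbone-like chain topology with per-atom parameters from config."""
    n = config.n_atoms
    if config.n_residues < 1:
        raise ValueError("need at least one residue")
    reps = int(np.ceil(n / 3))
    masses = ([12.0, 12.0, 14.0] * reps)[:n]
    radii = ([1.7, 1.7, 1.55] * reps)[:n]
    elements = (["C", "C", "N"] * reps)[:n]
    charges = [config.charge_magnitude * (1 if i % 2 == 0 else -1)
               for i in range(n)]
    return build_chain_topology(
        n, masses=masses, radii=radii, charges=charges, elements=elements,
        nonbonded=NonbondedParams(epsilon=config.epsilon, sigma=config.sigma),
        exclusion_rule=ExclusionRule.EXCL_12_13_14,
    )


# ----------------------------------------------------------------------
# internal-to-Cartesian chain building

def chain_coordinates(bond_lengths: np.ndarray, angles: np.ndarray,
                      dihedrals: np.ndarray) -> np.ndarray:
    """Sequential placement of a chain from internal coordinates.

    Batched: inputs (..., n-1), (..., n-2), (..., n-3) give (..., n, 3)
    coordinates whose measured internal coordinates reproduce the inputs
    (dihedrals in the IUPAC sign convention of :func:`dihedral_values`).
    """
    bond_lengths = np.atleast_2d(np.asarray(bond_lengths, dtype=float))
    batch, nb = bond_lengths.shape
    n = nb + 1
    angles = np.asarray(angles, dtype=float).reshape(batch, max(n - 2, 0))
    dihedrals = np.asarray(dihedrals, dtype=float).reshape(batch, max(n - 3, 0))
    xyz = np.zeros((batch, n, 3))
    xyz[:, 1, 0] = bond_lengths[:, 0]
    if n > 2:
        th = angles[:, 0]
        xyz[:, 2, 0] = xyz[:, 1, 0] - bond_lengths[:, 1] * np.cos(th)
        xyz[:, 2, 1] = bond_lengths[:, 1] * np.sin(th)
    for i in range(3, n):
        A, B, C = xyz[:, i - 3], xyz[:, i - 2], xyz[:, i - 1]
        l = bond_lengths[:, i - 1][:, None]
        th = angles[:, i - 2][:, None]
        phi = dihedrals[:, i - 3][:, None]
        bc = C - B
        bc /= np.linalg.norm(bc, axis=1, keepdims=True)
        ab = B - A
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        mvec = np.cross(nvec, bc)
        d_local = np.concatenate(
            [-np.cos(th), np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi)],
            axis=1,
        ) * l
        xyz[:, i] = (C + bc * d_local[:, :1]
                     + mvec * d_local[:, 1:2] + nvec * d_local[:, 2:3])
    return xyz


# ----------------------------------------------------------------------
# sampling

def family_patterns(n_dihedrals: int) -> np.ndarray:
    """Basin-index patterns of the three conformational families.

    helix = all basin 0, hairpin = N-half basin 0 / C-half basin 1,
    extended = all basin 1.
    """
    helix = np.zeros(n_dihedrals, dtype=int)
    hairpin = np.zeros(n_dihedrals, dtype=int)
    hairpin[(n_dihedrals + 1) // 2:] = 1
    extended = np.ones(n_dihedrals, dtype=int)
    return np.stack([helix, hairpin, extended])


@dataclass
class SyntheticEnsemble:
    """Sampled conformations plus the ground truth that generated them."""

    coords: np.ndarray           # (n_samples, n_atoms, 3)
    dihedrals: np.ndarray        # (n_samples, n_dihedrals) as drawn
    basin_assignment: np.ndarray  # (n_samples, n_dihedrals) basin index
    pattern_id: Optional[np.ndarray]   # (n_samples,) or None if independent

    @property
    def conformations(self) -> list[Conformation]:
        return [Conformation(c) for c in self.coords]


def _wrap(phi: np.ndarray) -> np.ndarray:
    out = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    return np.where(np.isclose(out, -np.pi), np.pi, out)


def sample_ensemble(topology: Topology, config: SyntheticConfig,
                    n_samples: Optional[int] = None,
                    seed: Optional[int] = None,
                    basin_patterns: Optional[np.ndarray] = None,
                    pattern_weights: Optional[Sequence[float]] = None,
                    center_offsets: Optional[np.ndarray] = None,
                    basin_width: Optional[float] = None) -> SyntheticEnsemble:
    """Draw conformations from the dihedral-basin model (seeded)."""
    n = topology.n_atoms
    n_dih = max(n - 3, 0)
    n_samples = config.n_samples if n_samples is None else n_samples
    rng = np.random.default_rng(config.seed if seed is None else seed)
    width = config.basin_width if basin_width is None else basin_width

    if config.independent_basins and basin_patterns is None:
        assignment = rng.choice(
            2, size=(n_samples, n_dih), p=np.asarray(config.basin_weights)
        )
        pattern_id = None
    else:
        patterns = (family_patterns(n_dih) if basin_patterns is None
                    else np.asarray(basin_patterns, dtype=int))
        weights = np.asarray(
            config.pattern_weights if pattern_weights is None else pattern_weights,
            dtype=float,
        )
        weights = weights / weights.sum()
        pattern_id = rng.choice(len(patterns), size=n_samples, p=weights)
        assignment = patterns[pattern_id]

    centers = np.asarray(config.basin_centers)[assignment]
    if center_offsets is not None:
        centers = centers + np.asarray(center_offsets)[None, :]
    dihedrals = _wrap(centers + width * rng.standard_normal((n_samples, n_dih)))
    bonds = config.bond_length + config.bond_jitter * \
        rng.standard_normal((n_samples, n - 1))
    angles = np.clip(
        config.angle_value + config.angle_jitter *
        rng.standard_normal((n_samples, n - 2)),
        0.1, np.pi - 0.1,
    )
    coords = chain_coordinates(bonds, angles, dihedrals)
    return SyntheticEnsemble(
        coords=coords, dihedrals=dihedrals,
        basin_assignment=assignment, pattern_id=pattern_id,
    )


def sample_conformations(topology: Topology, config: SyntheticConfig,
                         n_samples: Optional[int] = None,
                         seed: Optional[int] = None) -> list[Conformation]:
    """Seeded, reproducible conformations of the basin model."""
    return sample_ensemble(topology, config, n_samples, seed).conformations


# ----------------------------------------------------------------------
# energies and labels

def toy_potential_energy(topology: Topology, conf: Conformation,
                         config: SyntheticConfig) -> EnergyTerms:
    """Classical potential energy split into its four canonical terms."""
    c = conf.coords
    e_bond = e_angle = e_dihedral = e_nonbond = 0.0
    if topology.bonds:
        l = bond_distances(c, sorted(topology.bonds))
        e_bond = float(np.sum(
            config.bond_stiffness * (l - config.bond_length) ** 2
        ))
    if topology.angles:
        th = angle_values(c, topology.angles)
        e_angle = float(np.sum(
            config.angle_stiffness * (th - config.angle_value) ** 2
        ))
    if topology.dihedrals:
        phi = dihedral_values(c, topology.dihedrals)
        for k, m, phi0 in config.dihedral_terms:
            e_dihedral += float(np.sum(k * (1.0 + np.cos(m * phi - phi0))))
    if topology.nonbonded_pairs:
        pairs = np.asarray(topology.nonbonded_pairs)
        r = bond_distances(c, pairs)
        q = np.array([a.charge for a in topology.atoms])
        qq = q[pairs[:, 0]] * q[pairs[:, 1]]
        nb = topology.nonbonded
        lj = 4.0 * nb.epsilon * ((nb.sigma / r) ** 12 - (nb.sigma / r) ** 6)
        e_nonbond = float(np.sum(lj + nb.k_e * qq / r))
    return EnergyTerms(e_bond=e_bond, e_nonbond=e_nonbond,
                       e_angle=e_angle, e_dihedral=e_dihedral)


def _cv_bins(cv: np.ndarray, n_bins: int, origin: float) -> np.ndarray:
    """Wrapped uniform binning of dihedral collective variables."""
    width = 2 * np.pi / n_bins
    idx = np.floor(np.mod(cv - origin, 2 * np.pi) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def default_cv_dihedrals(n_dihedrals: int) -> tuple[int, ...]:
    """The two central dihedrals (phi/psi analogue of the middle residue)."""
    if n_dihedrals == 0:
        raise ValueError("chain has no dihedrals")
    if n_dihedrals == 1:
        return (0,)
    mid = (n_dihedrals - 1) // 2
    return (mid, mid + 1)


def empirical_free_energy(
    conformations, topology: Topology, beta: float,
    cv_dihedrals: Optional[Sequence[int]] = None,
    n_bins: int = 2, origin: float = -0.1,
):
    """Unbiased free-energy estimate F(s) = -(1/beta) ln P(s).

    ``s`` is the vector of selected dihedrals (default the two central
    ones) binned on a wrapped uniform grid with ``n_bins`` bins per
    dimension starting at ``origin`` rad; with the default two-basin
    geometry, ``n_bins=2, origin=-0.1`` separates the basins exactly.

    Returns ``(bin_F, conf_F)``: the free energy of every grid bin
    (+inf for never-visited bins) shifted so the global minimum is 0,
    and each conformation's bin free energy.
    """
    if isinstance(conformations, np.ndarray) and conformations.ndim == 3:
        coords = conformations
    else:
        conformations = list(conformations)
        if not conformations:
            raise ValueError("empty conformation set")
        coords = np.stack([c.coords for c in conformations])
    if coords.shape[0] == 0:
        raise ValueError("empty conformation set")
    quads = np.asarray(topology.dihedrals)
    phi = dihedral_values(coords, quads)          # (n, n_dihedrals)
    if cv_dihedrals is None:
        cv_dihedrals = default_cv_dihedrals(quads.shape[0])
    cv = phi[:, list(cv_dihedrals)]
    idx = _cv_bins(cv, n_bins, origin)
    flat = np.ravel_multi_index(idx.T, (n_bins,) * len(cv_dihedrals))
    counts = np.bincount(flat, minlength=n_bins ** len(cv_dihedrals))
    with np.errstate(divide="ignore"):
        F = -np.log(counts / coords.shape[0]) / beta
    F = F - F.min()
    bin_F = F.reshape((n_bins,) * len(cv_dihedrals))
    return bin_F, F[flat]


def free_energy_labels(conf_F: np.ndarray, threshold: float = 8.0) -> np.ndarray:
    """1 = low free energy (F <= threshold after min-shift), 0 = high."""
    F = np.asarray(conf_F, dtype=float)
    if F.size == 0:
        raise ValueError("no free energies given")
    return (F - F.min() <= threshold).astype(int)


# ----------------------------------------------------------------------
# synthetic cluster sets

@dataclass
class SyntheticClusters:
    coords: np.ndarray            # (n_clusters * per_cluster, n_atoms, 3)
    cluster_id: np.ndarray        # (n_total,)
    family_map: dict[int, str]    # cluster -> family name
    representatives: np.ndarray   # (n_clusters, n_atoms, 3)


def make_synthetic_clusters(topology: Topology, config: SyntheticConfig,
                            n_clusters: int = 10, per_cluster: int = 1000,
                            seed: Optional[int] = None,
                            rep_offset: float = 0.03,
                            cluster_width: float = 0.15) -> SyntheticClusters:
    """Conformational clusters grouped into secondary-structure families.

    Families follow the 4 helix / 2 hairpin / 4 extended grouping of a
    ten-cluster set (round-robin for other counts).  Clusters of one
    family share the family's basin pattern; each cluster representative
    additionally carries a small fixed per-dihedral center offset
    (<= ``rep_offset`` rad) so representatives are geometrically
    distinct, and its members jitter around it with ``cluster_width``.
    """
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_dih = topology.n_atoms - 3
    patterns = family_patterns(n_dih)
    if n_clusters == 10:
        fam_of_cluster = [0, 0, 0, 0, 1, 1, 2, 2, 2, 2]
    else:
        fam_of_cluster = [i % 3 for i in range(n_clusters)]
    coords_parts, ids = [], []
    reps = []
    family_map = {}
    for c in range(n_clusters):
        fam = fam_of_cluster[c]
        family_map[c] = FAMILY_NAMES[fam]
        offsets = rng.uniform(-rep_offset, rep_offset, size=n_dih)
        rep = sample_ensemble(
            topology, config, n_samples=1, seed=rng.integers(2**31),
            basin_patterns=patterns[fam][None, :], pattern_weights=[1.0],
            center_offsets=offsets, basin_width=1e-12,
        )
        reps.append(rep.coords[0])
        ens = sample_ensemble(
            topology, config, n_samples=per_cluster,
            seed=rng.integers(2**31),
            basin_patterns=patterns[fam][None, :], pattern_weights=[1.0],
            center_offsets=offsets, basin_width=cluster_width,
        )
        coords_parts.append(ens.coords)
        ids.append(np.full(per_cluster, c))
    return SyntheticClusters(
        coords=np.concatenate(coords_parts),
        cluster_id=np.concatenate(ids),
        family_map=family_map,
        representatives=np.stack(reps),
    )


def rmsd(conf_a, conf_b, atom_subset: Optional[Sequence[int]] = None) -> float:
    """Minimum RMSD (Å) after optimal rigid (Kabsch) superposition."""
    a = conf_a.coords if isinstance(conf_a, Conformation) else np.asarray(conf_a)
    b = conf_b.coords if isinstance(conf_b, Conformation) else np.asarray(conf_b)
    if atom_subset is not None:
        a = a[list(atom_subset)]
        b = b[list(atom_subset)]
    if a.shape != b.shape:
        raise ValueError("conformations must have the same atom count")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))
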