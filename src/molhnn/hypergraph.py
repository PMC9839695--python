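"""Hypergraph representation of molecular conformations.

A conformation of an ``n``-atom molecule is encoded as a hypergraph
``H(V, E, X, W)``: vertices are atoms, hyperedges are the interaction
terms of a classical force field — bonds and non-bonded pairs (Coulomb,
van der Waals) connect 2 vertices, valence angles connect 3, dihedrals
connect 4.  Each hyperedge carries a 5-slot feature vector with exactly
one slot filled according to its kind:

    slot 1  bond indicator (1 for a bond)
    slot 2  signed Coulomb force on the pair (kJ/mol/Å)
    slot 3  signed Lennard-Jones force on the pair (kJ/mol/Å)
    slot 4  valence angle (rad)
    slot 5  dihedral angle (rad, IUPAC sign, range (-pi, pi])

All hyperedge features are internal coordinates, so the representation
is invariant under rigid-body motion of the conformation.  Vertices
carry ``[mass, radius]`` by default (``[atomic_number, charge]`` behind
a switch).  The structure is kept both as a dense binary incidence
matrix ``B`` (|E| x |V|) and as a membership pair list ``L_adj``; the
two encodings are equivalent and tested against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AtomNode", "Topology", "Conformation", "Hyperedge", "MolecularHypergraph",
    "ExclusionRule", "HypergraphConfig", "build_chain_topology",
    "geometric_features", "pair_forces", "build_hypergraph",
    "incidence_matrix", "representation_size",
    "bond_distances", "angle_values", "dihedral_values",
]

KIND_ORDER = ("bond", "coulomb", "vdw", "angle", "dihedral")
KIND_SLOT = {k: i for i, k in enumerate(KIND_ORDER)}
KIND_SIZE = {"bond": 2, "coulomb": 2, "vdw": 2, "angle": 3, "dihedral": 4}


class InvalidTopologyError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


class ExclusionRule(str, Enum):
    """Which covalently linked pairs are excluded from non-bonded lists."""

    NONE = "none"
    EXCL_12 = "excl_12"
    EXCL_12_13 = "excl_12_13"
    EXCL_12_13_14 = "excl_12_13_14"


@dataclass(frozen=True)
class AtomNode:
    index: int
    element: str
    mass: float          # amu
    radius: float        # Angstrom
    charge: float        # elementary charge units

    def __post_init__(self):
        if self.mass <= 0 or self.radius <= 0:
            raise InvalidTopologyError(
                f"atom {self.index}: mass and radius must be positive"
            )


@dataclass(frozen=True)
class NonbondedParams:
    """Lennard-Jones well depth/size and the Coulomb prefactor."""

    epsilon: float = 0.5    # kJ/mol
    sigma: float = 3.0      # Angstrom
    k_e: float = 138.935458  # kJ mol^-1 Å e^-2, vacuum Coulomb constant


@dataclass
class Topology:
    """Conformation-independent interaction lists of one molecule."""

    atoms: list[AtomNode]
    bonds: set[tuple[int, int]]              # unordered, stored (i<j)
    angles: list[tuple[int, int, int]]
    dihedrals: list[tuple[int, int, int, int]]
    nonbonded_pairs: list[tuple[int, int]]
    nonbonded: NonbondedParams = field(default_factory=NonbondedParams)
    exclusion_rule: ExclusionRule = ExclusionRule.EXCL_12_13_14

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def validate(self) -> None:
        n = self.n_atoms
        if [a.index for a in self.atoms] != list(range(n)):
            raise InvalidTopologyError("atom indices must be consecutive from 0")
        for pair in list(self.bonds) + list(self.nonbonded_pairs):
            if not all(0 <= i < n for i in pair):
                raise InvalidTopologyError(f"index out of range in pair {pair}")
        for (i, j, k) in self.angles:
            if tuple(sorted((i, j))) not in self.bonds or \
               tuple(sorted((j, k))) not in self.bonds:
                raise InvalidTopologyError(f"angle {(i, j, k)} is not a bonded path")
        for (i, j, k, l) in self.dihedrals:
            for a, b in ((i, j), (j, k), (k, l)):
                if tuple(sorted((a, b))) not in self.bonds:
                    raise InvalidTopologyError(
                        f"dihedral {(i, j, k, l)} is not a bonded 4-chain"
                    )
        excluded = self._excluded_pairs()
        for pair in self.nonbonded_pairs:
            if tuple(sorted(pair)) in excluded:
                raise InvalidTopologyError(
                    f"nonbonded pair {pair} is excluded by {self.exclusion_rule.value}"
                )

    def _excluded_pairs(self) -> set[tuple[int, int]]:
        rule = self.exclusion_rule
        out: set[tuple[int, int]] = set()
        if rule is ExclusionRule.NONE:
            return out
        out |= {tuple(sorted(b)) for b in self.bonds}
        if rule in (ExclusionRule.EXCL_12_13, ExclusionRule.EXCL_12_13_14):
            out |= {tuple(sorted((i, k))) for (i, j, k) in self.angles}
        if rule is ExclusionRule.EXCL_12_13_14:
            out |= {tuple(sorted((i, l))) for (i, j, k, l) in self.dihedrals}
        return out


@dataclass
class Conformation:
    """Cartesian coordinates (Å) with optional free-energy label."""

    coords: np.ndarray                      # (n, 3)
    free_energy: Optional[float] = None     # kJ/mol
    label: Optional[str] = None             # "low" | "high"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class Hyperedge:
    members: tuple[int, ...]
    kind: str
    features: np.ndarray    # length-5, exactly one slot may be nonzero

    def __post_init__(self):
        if self.kind not in KIND_ORDER:
            raise ValueError(f"unknown hyperedge kind {self.kind!r}")
        if len(self.members) != KIND_SIZE[self.kind]:
            raise ValueError(
                f"{self.kind} hyperedge must have {KIND_SIZE[self.kind]} members"
            )


@dataclass(frozen=True)
class HypergraphConfig:
    node_features: str = "mass_radius"   # or "number_charge"
    exclusion_rule: Optional[ExclusionRule] = None   # override topology's rule
    nonbonded_cutoff: Optional[float] = None         # Å, None = no cutoff


@dataclass
class MolecularHypergraph:
    vertices: list[AtomNode]
    hyperedges: list[Hyperedge]
    X: np.ndarray            # |V| x d_v
    W: np.ndarray            # |E| x 5
    B: np.ndarray            # |E| x |V| binary incidence
    L_adj: np.ndarray        # (n_memberships, 2): [hyperedge idx, vertex idx]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)


# ----------------------------------------------------------------------
# geometry

def bond_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Pair distances; works on (n,3) or batched (..., n, 3) coordinates."""
    pairs = np.asarray(pairs, dtype=int)
    d = coords[..., pairs[:, 0], :] - coords[..., pairs[:, 1], :]
    return np.linalg.norm(d, axis=-1)


def angle_values(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Valence angles in [0, pi] for (i, j, k) triples, vertex at j."""
    triples = np.asarray(triples, dtype=int)
    u = coords[..., triples[:, 0], :] - coords[..., triples[:, 1], :]
    v = coords[..., triples[:, 2], :] - coords[..., triples[:, 1], :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        bad = triples[np.nonzero((nu == 0) | (nv == 0))[-1][0]]
        raise DegenerateGeometryError(f"coincident atoms in angle {tuple(bad)}")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedral_values(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Torsion angles in (-pi, pi], IUPAC sign convention (cis = 0)."""
    quads = np.asarray(quads, dtype=int)
    p0 = coords[..., quads[:, 0], :]
    p1 = coords[..., quads[:, 1], :]
    p2 = coords[..., quads[:, 2], :]
    p3 = coords[..., quads[:, 3], :]
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    denom = np.linalg.norm(n1, axis=-1) * np.linalg.norm(n2, axis=-1)
    if np.any(denom == 0) or np.any(nb2 == 0):
        bad = quads[np.nonzero((denom == 0) | (nb2 == 0))[-1][0]]
        raise DegenerateGeometryError(f"degenerate dihedral {tuple(bad)}")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / nb2[..., None]), axis=-1)
    phi = np.arctan2(y, x)
    # map -pi -> +pi so the range is (-pi, pi]
    return np.where(np.isclose(phi, -np.pi), np.pi, phi)


def geometric_features(topology: Topology, conf: Conformation) -> dict:
    """Per-interaction internal coordinates of one conformation.

    Returns a dict with ``bond_lengths`` (Å), ``nonbonded_distances`` (Å),
    ``angles`` (rad, [0, pi]) and ``dihedrals`` (rad, (-pi, pi]).
    """
    c = conf.coords
    out = {
        "bond_lengths": bond_distances(c, sorted(topology.bonds))
        if topology.bonds else np.zeros(0),
        "nonbonded_distances": bond_distances(c, topology.nonbonded_pairs)
        if topology.nonbonded_pairs else np.zeros(0),
        "angles": angle_values(c, topology.angles)
        if topology.angles else np.zeros(0),
        "dihedrals": dihedral_values(c, topology.dihedrals)
        if topology.dihedrals else np.zeros(0),
    }
    if topology.bonds and np.any(out["bond_lengths"] == 0):
        raise DegenerateGeometryError("bonded atoms coincide")
    return out


def pair_forces(q_i: float, q_j: float, r, epsilon: float, sigma: float,
                k_e: float) -> tuple:
    """Signed Coulomb and 12-6 Lennard-Jones force magnitudes at distance r.

    Both are the negative radial derivatives of the pair potentials;
    positive values push the pair apart (repulsion).
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise DegenerateGeometryError("pair distance must be positive")
    coulomb = k_e * q_i * q_j / r**2
    vdw = 24.0 * epsilon * (2.0 * sigma**12 / r**13 - sigma**6 / r**7)
    return coulomb, vdw


# ----------------------------------------------------------------------
# topology construction

def build_chain_topology(
    n_atoms: int,
    masses: Sequence[float] | float = 12.0,
    radii: Sequence[float] | float = 1.7,
    charges: Sequence[float] | float = 0.0,
    elements: Sequence[str] | str = "C",
    nonbonded: NonbondedParams | None = None,
    exclusion_rule: ExclusionRule = ExclusionRule.EXCL_12_13_14,
) -> Topology:
    """Linear-chain topology: consecutive bonds, triples and quadruples.

    Stands in for the interaction lists an MD topology file would
    provide.  Scalars broadcast to all atoms.
    """
    if n_atoms < 2:
        raise InvalidTopologyError("a chain needs at least 2 atoms")

    def _vec(x, cast=float):
        if np.isscalar(x) or isinstance(x, str):
            return [cast(x)] * n_atoms
        if len(x) != n_atoms:
            raise InvalidTopologyError("per-atom parameter length mismatch")
        return [cast(v) for v in x]

    atoms = [
        AtomNode(i, e, m, r, q)
        for i, (e, m, r, q) in enumerate(
            zip(_vec(elements, str), _vec(masses), _vec(radii), _vec(charges))
        )
    ]
    bonds = {(i, i + 1) for i in range(n_atoms - 1)}
    angles = [(i, i + 1, i + 2) for i in range(n_atoms - 2)]
    dihedrals = [(i, i + 1, i + 2, i + 3) for i in range(n_atoms - 3)]
    topo = Topology(
        atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals,
        nonbonded_pairs=[],
        nonbonded=nonbonded or NonbondedParams(),
        exclusion_rule=exclusion_rule,
    )
    excluded = topo._excluded_pairs()
    topo.nonbonded_pairs = [
        p for p in combinations(range(n_atoms), 2) if p not in excluded
    ]
    topo.validate()
    return topo


# ----------------------------------------------------------------------
# hypergraph assembly

def node_feature_matrix(topology: Topology,
                        scheme: str = "mass_radius") -> np.ndarray:
    if scheme == "mass_radius":
        return np.array([[a.mass, a.radius] for a in topology.atoms])
    if scheme == "number_charge":
        from .periodic import atomic_number
        return np.array([[atomic_number(a.element), a.charge]
                         for a in topology.atoms])
    raise ValueError(f"unknown node feature scheme {scheme!r}")


def hyperedge_index(topology: Topology,
                    config: HypergraphConfig | None = None):
    """Canonical hyperedge list (kind, members) without features.

    Order: bond < coulomb < vdw < angle < dihedral, ties broken by
    lexicographic member tuples.  The flattening order used by pooling
    depends on this being deterministic.
    """
    config = config or HypergraphConfig()
    nb = sorted(tuple(sorted(p)) for p in topology.nonbonded_pairs)
    edges = [("bond", b) for b in sorted(tuple(sorted(b)) for b in topology.bonds)]
    edges += [("coulomb", p) for p in nb]
    edges += [("vdw", p) for p in nb]
    edges += [("angle", tuple(t)) for t in sorted(map(tuple, topology.angles))]
    edges += [("dihedral", tuple(q)) for q in sorted(map(tuple, topology.dihedrals))]
    return edges


def hyperedge_features(topology: Topology, coords: np.ndarray,
                       config: HypergraphConfig | None = None) -> np.ndarray:
    """W matrix (..., |E|, 5) for coords of shape (..., n, 3).

    Batched over leading axes so whole trajectories of one topology can
    be featurized in a single call.
    """
    config = config or HypergraphConfig()
    edges = hyperedge_index(topology, config)
    batch = coords.shape[:-2]
    W = np.zeros(batch + (len(edges), 5))
    kinds = np.array([k for k, _ in edges])
    nbp = topology.nonbonded

    sel = np.nonzero(kinds == "bond")[0]
    if sel.size:
        W[..., sel, 0] = 1.0
    csel = np.nonzero(kinds == "coulomb")[0]
    vsel = np.nonzero(kinds == "vdw")[0]
    if csel.size:
        pairs = np.array([edges[i][1] for i in csel])
        r = bond_distances(coords, pairs)
        q = np.array([a.charge for a in topology.atoms])
        qprod = q[pairs[:, 0]] * q[pairs[:, 1]]
        if np.any(r <= 0):
            raise DegenerateGeometryError("non-bonded pair at zero distance")
        coulomb = nbp.k_e * qprod / r**2
        vdw = 24.0 * nbp.epsilon * (
            2.0 * nbp.sigma**12 / r**13 - nbp.sigma**6 / r**7
        )
        if config.nonbonded_cutoff is not None:
            mask = r <= config.nonbonded_cutoff
            coulomb = coulomb * mask
            vdw = vdw * mask
        W[..., csel, 1] = coulomb
        W[..., vsel, 2] = vdw
    asel = np.nonzero(kinds == "angle")[0]
    if asel.size:
        W[..., asel, 3] = angle_values(
            coords, np.array([edges[i][1] for i in asel])
        )
    dsel = np.nonzero(kinds == "dihedral")[0]
    if dsel.size:
        W[..., dsel, 4] = dihedral_values(
            coords, np.array([edges[i][1] for i in dsel])
        )
    return W


def membership(edges) -> tuple[np.ndarray, np.ndarray]:
    """Incidence matrix B and pair list L_adj for a canonical edge list."""
    n_v = 1 + max((max(m) for _, m in edges), default=-1)
    B = np.zeros((len(edges), n_v))
    pairs = []
    for e, (_, members) in enumerate(edges):
        for v in members:
            B[e, v] = 1.0
            pairs.append((e, v))
    return B, np.array(pairs, dtype=int).reshape(-1, 2)


def build_hypergraph(topology: Topology, conf: Conformation,
                     config: HypergraphConfig | None = None) -> MolecularHypergraph:
    """Assemble H(V, E, X, W) for one conformation."""
    config = config or HypergraphConfig()
    if conf.coords.shape[0] != topology.n_atoms:
        raise ValueError(
            f"conformation has {conf.coords.shape[0]} atoms, "
            f"topology has {topology.n_atoms}"
        )
    edges = hyperedge_index(topology, config)
    W = hyperedge_features(topology, conf.coords, config)
    B, L_adj = membership(edges)
    if B.shape[1] < topology.n_atoms:   # trailing isolated vertices
        B = np.hstack([B, np.zeros((B.shape[0], topology.n_atoms - B.shape[1]))])
    hyperedges = [
        Hyperedge(members=m, kind=k, features=W[i])
        for i, (k, m) in enumerate(edges)
    ]
    X = node_feature_matrix(topology, config.node_features)
    return MolecularHypergraph(
        vertices=list(topology.atoms), hyperedges=hyperedges,
        X=X, W=W, B=B, L_adj=L_adj,
    )


def incidence_matrix(H: MolecularHypergraph) -> np.ndarray:
    """Binary B with B_ij = 1 iff vertex j belongs to hyperedge i."""
    B = np.zeros((H.n_hyperedges, H.n_vertices))
    for i, e in enumerate(H.hyperedges):
        B[i, list(e.members)] = 1.0
    return B


def representation_size(H: MolecularHypergraph | None = None, *,
                        n: int | None = None, e: int | None = None) -> int:
    """Floating-point numbers needed to store one input conformation.

    ``3n^2 + 2n + 7e`` for n atoms and e hyperedges: the n x 3 coordinate
    block plus pairwise bookkeeping, the size-2 vertex features and the
    5 + 2 numbers per hyperedge (features and pair bookkeeping).
    """
    if H is not None:
        n, e = H.n_vertices, H.n_hyperedges
    if n is None or e is None:
        raise ValueError("need a hypergraph or explicit n and e")
    return 3 * n * n + 2 * n + 7 * e
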