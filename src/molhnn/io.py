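"""File formats: PDB conformations, coordinate tables, topology files,
hypergraph dumps and free-energy/prediction tables.

Internally everything is 0-based and in Å / kJ/mol; PDB serial numbers
are 1-based on disk.  The topology file is a small YAML document with
explicit sections, not a force-field dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .hypergraph import (
    AtomNode, ExclusionRule, MolecularHypergraph, NonbondedParams, Topology,
)

__all__ = [
    "write_pdb", "read_pdb", "write_coord_table", "read_coord_table",
    "save_topology", "load_topology", "dump_hypergraph",
    "write_free_energy_table", "read_free_energy_table",
]


def _atom_array(coords: np.ndarray, elements: Sequence[str]):
    n = coords.shape[-2]
    arr = struc.AtomArray(n) if coords.ndim == 2 else \
        struc.AtomArrayStack(coords.shape[0], n)
    arr.coord = coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "UNK")
    arr.atom_name = np.array([f"{e}{i + 1}" for i, e in enumerate(elements)])
    arr.element = np.array([e.upper() for e in elements])
    arr.hetero = np.full(n, True)
    return arr


def write_pdb(path, coords: np.ndarray, topology: Topology | None = None,
              elements: Sequence[str] | None = None) -> None:
    """Write one conformation (n, 3) or a stack (m, n, 3) as PDB models."""
    coords = np.asarray(coords, dtype=np.float64)
    if elements is None:
        elements = [a.element for a in topology.atoms] if topology \
            else ["C"] * coords.shape[-2]
    pdb = PDBFile()
    pdb.set_structure(_atom_array(coords, elements))
    pdb.write(str(path))


def read_pdb(path) -> np.ndarray:
    """Coordinates from a PDB file: (n, 3) or (models, n, 3)."""
    pdb = PDBFile.read(str(path))
    coords = pdb.get_coord()   # (models, n, 3)
    return coords[0] if coords.shape[0] == 1 else coords


def write_coord_table(path, coords: np.ndarray) -> None:
    """Plain 3-column x/y/z text table (Å) for one conformation."""
    np.savetxt(path, np.asarray(coords, dtype=np.float64),
               header="x y z", fmt="%.8f")


def read_coord_table(path) -> np.ndarray:
    coords = np.loadtxt(path)
    return coords.reshape(-1, 3)


# ----------------------------------------------------------------------
# topology

def save_topology(path, topo: Topology) -> None:
    doc = {
        "atoms": [
            {"index": a.index, "element": a.element, "mass": a.mass,
             "radius": a.radius, "charge": a.charge}
            for a in topo.atoms
        ],
        "bonds": sorted([list(b) for b in topo.bonds]),
        "angles": [list(t) for t in topo.angles],
        "dihedrals": [list(q) for q in topo.dihedrals],
        "nonbonded_pairs": [list(p) for p in topo.nonbonded_pairs],
        "nonbonded": {"epsilon": topo.nonbonded.epsilon,
                      "sigma": topo.nonbonded.sigma,
                      "k_e": topo.nonbonded.k_e},
        "exclusion_rule": topo.exclusion_rule.value,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_topology(path) -> Topology:
    doc = yaml.safe_load(Path(path).read_text())
    topo = Topology(
        atoms=[AtomNode(**a) for a in doc["atoms"]],
        bonds={tuple(sorted(b)) for b in doc["bonds"]},
        angles=[tuple(t) for t in doc["angles"]],
        dihedrals=[tuple(q) for q in doc["dihedrals"]],
        nonbonded_pairs=[tuple(p) for p in doc["nonbonded_pairs"]],
        nonbonded=NonbondedParams(**doc["nonbonded"]),
        exclusion_rule=ExclusionRule(doc["exclusion_rule"]),
    )
    topo.validate()
    return topo


# ----------------------------------------------------------------------
# hypergraph dump and tables

def dump_hypergraph(path, H: MolecularHypergraph) -> None:
    """One row per hyperedge: kind, members, the 5 feature slots."""
    rows = [
        {"kind": e.kind, "members": "-".join(map(str, e.members)),
         **{f"w{i + 1}": e.features[i] for i in range(5)}}
        for e in H.hyperedges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def write_free_energy_table(path, free_energies: np.ndarray) -> None:
    pd.DataFrame({
        "conformation": np.arange(len(free_energies)),
        "free_energy_kJ_mol": np.asarray(free_energies, dtype=float),
    }).to_csv(path, sep="\t", index=False)


def read_free_energy_table(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["free_energy_kJ_mol"].to_numpy()
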