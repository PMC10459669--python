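"""Molecular graph construction: adjacency, atom/bond features, coordinates.

Each molecule becomes a graph over its heavy atoms.  Node features are
74-dimensional (element vocabulary of 43 symbols, degree 0-10, implicit H
count 0-6, formal charge, radical electrons, hybridization, aromaticity,
total H count 0-4); bond features are 12-dimensional (bond type, conjugation,
ring membership, stereo configuration); 3D information enters as the
horizontal concatenation of the M aligned conformer coordinate sets, giving
an n x 3M coordinate block (30 columns for the default ten conformers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from rdkit import Chem

from .chemprep import ConformerEnsemble, StandardizedMolecule
from .errors import ConsistencyError

NODE_FEATURE_DIM = 74
EDGE_FEATURE_DIM = 12

# 43-symbol element vocabulary; out-of-vocabulary elements encode as an
# all-zero element block (plus a warning) rather than a dedicated slot.
ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_ELEMENT_INDEX = {s: i for i, s in enumerate(ELEMENTS)}

_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]

_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

_BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]


@dataclass
class MolecularGraph:
    """Graph tensors for one molecule and its conformer ensemble.

    Edge features are stored per *directed* edge (both orientations carry the
    bond's 12-dim feature) to serve message passing; `A` stays undirected.
    """

    molecule_id: str
    A: np.ndarray            # n x n binary adjacency, zero diagonal
    HV: np.ndarray           # n x 74 node features
    edge_index: np.ndarray   # 2 x E directed edges (source row, target row)
    HE: np.ndarray           # E x 12 edge features
    HC: np.ndarray           # n x 3M concatenated conformer coordinates (A)
    M: int
    label_y: float | None = None
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.A.shape[0]

    def conformer_coords(self, m: int) -> np.ndarray:
        """Slice conformer m's n x 3 coordinates out of HC."""
        return self.HC[:, 3 * m : 3 * m + 3]


def _as_mol(mol_or_std) -> Chem.Mol:
    if isinstance(mol_or_std, StandardizedMolecule):
        return mol_or_std.to_mol()
    return mol_or_std


def build_adjacency(mol_or_std) -> np.ndarray:
    """Binary heavy-atom adjacency (symmetric, zero diagonal)."""
    mol = _as_mol(mol_or_std)
    return np.asarray(Chem.GetAdjacencyMatrix(mol), dtype=np.int8)


def _atom_row(atom: Chem.Atom) -> np.ndarray:
    row = np.zeros(NODE_FEATURE_DIM, dtype=np.float32)
    symbol = atom.GetSymbol()
    idx = _ELEMENT_INDEX.get(symbol)
    if idx is None:
        warnings.warn(f"element {symbol!r} outside the 43-symbol vocabulary")
    else:
        row[idx] = 1.0
    off = len(ELEMENTS)
    degree = min(atom.GetDegree(), 10)
    row[off + degree] = 1.0
    off += 11
    implicit_h = min(atom.GetNumImplicitHs(), 6)
    row[off + implicit_h] = 1.0
    off += 7
    row[off] = float(atom.GetFormalCharge())
    row[off + 1] = float(atom.GetNumRadicalElectrons())
    off += 2
    hyb = atom.GetHybridization()
    if hyb in _HYBRIDIZATIONS:
        row[off + _HYBRIDIZATIONS.index(hyb)] = 1.0
    off += 5
    row[off] = float(atom.GetIsAromatic())
    off += 1
    total_h = min(atom.GetTotalNumHs(), 4)
    row[off + total_h] = 1.0
    return row


def featurize_atoms(mol_or_std) -> np.ndarray:
    """n x 74 node feature matrix in RDKit atom order."""
    mol = _as_mol(mol_or_std)
    return np.stack([_atom_row(a) for a in mol.GetAtoms()])


def _bond_row(bond: Chem.Bond) -> np.ndarray:
    row = np.zeros(EDGE_FEATURE_DIM, dtype=np.float32)
    if bond.GetBondType() in _BOND_TYPES:
        row[_BOND_TYPES.index(bond.GetBondType())] = 1.0
    row[4] = float(bond.GetIsConjugated())
    row[5] = float(bond.IsInRing())
    stereo = bond.GetStereo()
    if stereo in _BOND_STEREO:
        row[6 + _BOND_STEREO.index(stereo)] = 1.0
    return row


def featurize_bonds(mol_or_std) -> np.ndarray:
    """b x 12 bond feature matrix (one row per undirected bond)."""
    mol = _as_mol(mol_or_std)
    rows = [_bond_row(b) for b in mol.GetBonds()]
    if not rows:
        return np.zeros((0, EDGE_FEATURE_DIM), dtype=np.float32)
    return np.stack(rows)


def directed_edges(mol_or_std) -> tuple[np.ndarray, np.ndarray]:
    """(2 x E edge index, E x 12 features) with both bond orientations."""
    mol = _as_mol(mol_or_std)
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        row = _bond_row(bond)
        src += [i, j]
        dst += [j, i]
        feats += [row, row]
    if not src:
        return (
            np.zeros((2, 0), dtype=np.int64),
            np.zeros((0, EDGE_FEATURE_DIM), dtype=np.float32),
        )
    return np.array([src, dst], dtype=np.int64), np.stack(feats)


def assemble_graph(
    ens: ConformerEnsemble, label_y: float | None = None
) -> MolecularGraph:
    """Build the full graph for an aligned, hydrogen-stripped ensemble."""
    mol = ens.mol
    if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        raise ConsistencyError("ensemble still contains explicit hydrogens")
    n = mol.GetNumAtoms()
    coords = ens.coords
    for xyz in coords:
        if xyz.shape != (n, 3):
            raise ConsistencyError(
                f"conformer coordinates {xyz.shape} do not match {n} atoms"
            )
    HC = np.concatenate(coords, axis=1).astype(np.float32)
    edge_index, HE = directed_edges(mol)
    if label_y is None:
        label_y = ens.label
    return MolecularGraph(
        molecule_id=ens.molecule_id or ens.molecule.smiles_canonical,
        A=build_adjacency(mol),
        HV=featurize_atoms(mol),
        edge_index=edge_index,
        HE=HE,
        HC=HC,
        M=ens.M,
        label_y=None if label_y is None else float(label_y),
        smiles=ens.molecule.smiles_canonical,
    )


# ---------------------------------------------------------------------------
# HDF5 container for featurized datasets
# ---------------------------------------------------------------------------

def save_graphs(path, graphs: list[MolecularGraph]) -> None:
    with h5py.File(str(path), "w") as f:
        for k, g in enumerate(graphs):
            grp = f.create_group(f"mol_{k:06d}")
            grp.attrs["molecule_id"] = g.molecule_id
            grp.attrs["smiles"] = g.smiles
            grp.attrs["M"] = g.M
            if g.label_y is not None:
                grp.attrs["label_y"] = g.label_y
            grp.create_dataset("A", data=g.A)
            grp.create_dataset("HV", data=g.HV)
            grp.create_dataset("edge_index", data=g.edge_index)
            grp.create_dataset("HE", data=g.HE)
            grp.create_dataset("HC", data=g.HC)


def load_graphs(path) -> list[MolecularGraph]:
    graphs = []
    with h5py.File(str(path), "r") as f:
        for key in sorted(f.keys()):
            grp = f[key]
            graphs.append(
                MolecularGraph(
                    molecule_id=str(grp.attrs["molecule_id"]),
                    A=grp["A"][...],
                    HV=grp["HV"][...],
                    edge_index=grp["edge_index"][...],
                    HE=grp["HE"][...],
                    HC=grp["HC"][...],
                    M=int(grp.attrs["M"]),
                    label_y=(
                        float(grp.attrs["label_y"]) if "label_y" in grp.attrs else None
                    ),
                    smiles=str(grp.attrs["smiles"]),
                )
            )
    return graphs
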