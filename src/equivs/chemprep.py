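"""Structure standardization and multi-conformer ensemble preparation.

Molecules enter as SMILES, are standardized (functional-group normalization,
charge recombination and neutralization, metal-bond disconnection,
reionization, canonical tautomer, salt/solvent stripping), then converted to
ensembles of 3D conformers: hydrogens added, ETKDG distance-geometry
embedding with per-conformer random seeds, MMFF94 relaxation, rigid-body
alignment of every conformer onto the first, and finally hydrogen removal so
that downstream graphs carry heavy atoms only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import (
    EmbeddingError,
    EmptyMoleculeError,
    ForceFieldError,
    FormatError,
    ParseError,
)

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_CONFORMERS = 10  # ensemble size used throughout the pipeline

_STANDARDIZE_STEPS = (
    "cleanup",          # normalize groups, reionize, disconnect metals
    "fragment_parent",  # drop salt / solvent fragments
    "uncharge",         # neutralize residual charges
    "tautomer_canonicalize",
)


@dataclass(frozen=True)
class StandardizedMolecule:
    """A curated structure: canonical SMILES plus provenance of the steps."""

    smiles_canonical: str
    n_heavy_atoms: int
    provenance_flags: frozenset = frozenset(_STANDARDIZE_STEPS)

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise ParseError(self.smiles_canonical)
        return mol


@dataclass
class ConformerEnsemble:
    """A molecule with M conformers sharing one atom ordering.

    `mol` is an RDKit molecule holding all conformers; `stripped` records
    whether hydrogens have been removed and `aligned` whether conformers have
    been superposed onto the first one.
    """

    molecule: StandardizedMolecule
    mol: Chem.Mol
    seed: int
    energies: list[float] | None = None
    converged: list[bool] | None = None
    aligned: bool = False
    stripped: bool = False
    molecule_id: str = ""
    label: float | None = None

    @property
    def M(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def coords(self) -> list[np.ndarray]:
        """Per-conformer coordinate matrices (atoms x 3, Angstrom)."""
        return [
            np.asarray(conf.GetPositions(), dtype=np.float64)
            for conf in self.mol.GetConformers()
        ]

    def copy(self) -> "ConformerEnsemble":
        new = copy.copy(self)
        new.mol = Chem.Mol(self.mol)
        if self.energies is not None:
            new.energies = list(self.energies)
        if self.converged is not None:
            new.converged = list(self.converged)
        return new


def standardize(smiles: str) -> StandardizedMolecule:
    """Standardize a SMILES string into a parent structure.

    Raises ParseError for unparseable input and EmptyMoleculeError when no
    heavy atoms survive fragment removal.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise EmptyMoleculeError(f"no heavy atoms left after standardization: {smiles!r}")
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    mol = rdMolStandardize.TautomerEnumerator().Canonicalize(mol)
    canonical = Chem.MolToSmiles(mol)
    check = Chem.MolFromSmiles(canonical)
    if check is None:
        raise ParseError(f"standardization produced invalid structure: {smiles!r}")
    return StandardizedMolecule(canonical, check.GetNumHeavyAtoms())


def generate_conformers(
    molecule: StandardizedMolecule,
    n_conformers: int = DEFAULT_N_CONFORMERS,
    seed: int = 0,
    max_retries: int = 5,
) -> ConformerEnsemble:
    """Embed `n_conformers` 3D conformers with ETKDG.

    Hydrogens are added before embedding.  Conformer m uses random seed
    seed + m so the "different random initializations" are reproducible.  On
    embedding failure the seed is bumped up to `max_retries` times, then a
    single random-coordinate fallback is attempted before EmbeddingError.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    mol = Chem.AddHs(molecule.to_mol())
    for m in range(n_conformers):
        conf_id = -1
        for attempt in range(max_retries + 1):
            params = AllChem.ETKDGv3()
            params.randomSeed = int(seed + m + 100003 * attempt)
            params.clearConfs = False
            conf_id = AllChem.EmbedMolecule(mol, params)
            if conf_id >= 0:
                break
        if conf_id < 0:
            params = AllChem.ETKDGv3()
            params.randomSeed = int(seed + m)
            params.clearConfs = False
            params.useRandomCoords = True
            conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id < 0:
            raise EmbeddingError(
                f"embedding failed for {molecule.smiles_canonical!r} (conformer {m})"
            )
    return ConformerEnsemble(molecule=molecule, mol=mol, seed=int(seed))


def _mmff_energies(mol: Chem.Mol) -> list[float]:
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        raise ForceFieldError("MMFF94 has no parameters for this molecule")
    energies = []
    for conf in mol.GetConformers():
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf.GetId())
        if ff is None:
            raise ForceFieldError("MMFF94 force-field setup failed")
        energies.append(ff.CalcEnergy())
    return energies


def optimize_conformers(
    ens: ConformerEnsemble, max_iters: int = 200
) -> ConformerEnsemble:
    """Relax every conformer with the MMFF94 force field.

    max_iters=0 leaves coordinates untouched but still records energies.
    """
    out = ens.copy()
    if max_iters == 0:
        out.energies = _mmff_energies(out.mol)
        out.converged = [False] * out.M
        return out
    if AllChem.MMFFGetMoleculeProperties(out.mol) is None:
        raise ForceFieldError("MMFF94 has no parameters for this molecule")
    results = AllChem.MMFFOptimizeMoleculeConfs(out.mol, maxIters=int(max_iters))
    out.converged = [flag == 0 for flag, _ in results]
    out.energies = [energy for _, energy in results]
    return out


def align_and_strip(ens: ConformerEnsemble) -> ConformerEnsemble:
    """Superpose every conformer onto the first (heavy atoms) and remove H.

    Heavy-atom ordering is preserved; RDKit appends hydrogens after heavy
    atoms at AddHs time, so stripping keeps the original indexing.
    """
    out = ens.copy()
    heavy_ids = [a.GetIdx() for a in out.mol.GetAtoms() if a.GetAtomicNum() > 1]
    if out.M > 1 and len(heavy_ids) > 1:
        AllChem.AlignMolConformers(out.mol, atomIds=heavy_ids)
    if not out.stripped:
        out.mol = Chem.RemoveHs(out.mol)
        out.stripped = True
    out.aligned = True
    return out


def prepare_ensemble(
    smiles: str,
    n_conformers: int = DEFAULT_N_CONFORMERS,
    seed: int = 0,
    max_iters: int = 200,
    molecule_id: str = "",
    label: float | None = None,
) -> ConformerEnsemble:
    """Full pipeline: standardize -> embed -> MMFF94 -> align -> strip H."""
    molecule = standardize(smiles)
    ens = generate_conformers(molecule, n_conformers=n_conformers, seed=seed)
    ens = optimize_conformers(ens, max_iters=max_iters)
    ens = align_and_strip(ens)
    ens.molecule_id = molecule_id or molecule.smiles_canonical
    ens.label = label
    return ens


# ---------------------------------------------------------------------------
# SDF round-trip: one V2000 record per conformer, grouped by molecule title.
# ---------------------------------------------------------------------------

def write_sdf(ensembles: ConformerEnsemble | list[ConformerEnsemble], path) -> None:
    """Write ensembles to an SDF file, one record per conformer."""
    if isinstance(ensembles, ConformerEnsemble):
        ensembles = [ensembles]
    writer = Chem.SDWriter(str(path))
    try:
        for ens in ensembles:
            for m, conf in enumerate(ens.mol.GetConformers()):
                mol = Chem.Mol(ens.mol)
                mol.SetProp("_Name", ens.molecule_id or ens.molecule.smiles_canonical)
                mol.SetProp("conformer_index", str(m))
                mol.SetProp("seed", str(ens.seed))
                if ens.label is not None:
                    mol.SetProp("label_logM", repr(float(ens.label)))
                if ens.energies is not None:
                    mol.SetProp("mmff94_energy", repr(float(ens.energies[m])))
                writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()


def load_sdf_library(path) -> list[ConformerEnsemble]:
    """Read an SDF written by `write_sdf`, regrouping records into ensembles."""
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise FormatError(f"unreadable SDF file: {path}") from exc
    groups: dict[str, list[Chem.Mol]] = {}
    order: list[str] = []
    n_records = 0
    for mol in supplier:
        if mol is None:
            raise FormatError(f"malformed SDF record in {path}")
        n_records += 1
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
        if name not in groups:
            groups[name] = []
            order.append(name)
        groups[name].append(mol)
    if n_records == 0:
        raise FormatError(f"empty or unreadable SDF file: {path}")
    ensembles = []
    for name in order:
        mols = groups[name]
        base = Chem.Mol(mols[0])
        base.RemoveAllConformers()
        energies = []
        for rec in mols:
            if rec.GetNumAtoms() != base.GetNumAtoms():
                raise FormatError(f"inconsistent atom counts for molecule {name!r}")
            base.AddConformer(rec.GetConformer(), assignId=True)
            if rec.HasProp("mmff94_energy"):
                energies.append(float(rec.GetProp("mmff94_energy")))
        first = mols[0]
        seed = int(first.GetProp("seed")) if first.HasProp("seed") else 0
        label = (
            float(first.GetProp("label_logM")) if first.HasProp("label_logM") else None
        )
        no_h = Chem.RemoveHs(Chem.Mol(base))
        stripped = no_h.GetNumAtoms() == base.GetNumAtoms()
        molecule = StandardizedMolecule(
            Chem.MolToSmiles(Chem.RemoveHs(mols[0])), no_h.GetNumHeavyAtoms()
        )
        ensembles.append(
            ConformerEnsemble(
                molecule=molecule,
                mol=base,
                seed=seed,
                energies=energies or None,
                aligned=True,
                stripped=stripped,
                molecule_id=name,
                label=label,
            )
        )
    return ensembles


def read_sdf(path) -> ConformerEnsemble:
    """Read a single-molecule multi-conformer SDF file."""
    ensembles = load_sdf_library(path)
    if len(ensembles) != 1:
        raise FormatError(
            f"expected one molecule in {path}, found {len(ensembles)}"
        )
    return ensembles[0]
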