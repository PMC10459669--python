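"""Self-contained synthetic tasks for exercising the full pipeline.

Two task families:

* a plain regression task over small drug-like molecules enumerated from a
  built-in scaffold x substituent library, with labels an affine function of
  invariant molecular statistics (heavy-atom and ring counts) plus Gaussian
  noise, clipped to the plausible potency range observed in public
  bioactivity collections (0.1 - 21.8 -logM);
* a noisy-conformer MIL task in which exactly one conformer per molecule
  keeps its force-field-optimized geometry while the others are scrambled by
  large random atomic displacements, and the label depends on a
  distance-derived statistic of the informative conformer only — so a model
  must identify that conformer to predict well.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemprep import ConformerEnsemble, prepare_ensemble
from .errors import GenerationError
from .molgraph import MolecularGraph, assemble_graph

LABEL_RANGE = (0.1, 21.8)   # plausible -logM potency window

# Case fixture: a CDK2-active sulfonamide, measured at 9.0 -logM.
CASE_MOLECULE_SMILES = "Nc1ccc(-c2cc(Nc3ccc(S(N)(=O)=O)cc3)[nH]n2)cc1"
CASE_MOLECULE_LABEL = 9.0

_SCAFFOLDS = [
    "c1ccc({})cc1",               # benzene
    "c1ccc2cc({})ccc2c1",         # naphthalene
    "c1cc({})ccn1",               # pyridine
    "c1cc({})cnc1",               # pyridine (meta)
    "c1cnc({})cn1",               # pyrazine
    "c1ccc(-c2ccc({})cc2)cc1",    # biphenyl
    "c1cc({})oc1",                # furan
    "c1cc({})sc1",                # thiophene
    "c1cc({})[nH]c1",             # pyrrole
    "c1ccc2[nH]c({})cc2c1",       # indole
    "c1ccc2nc({})ccc2c1",         # quinoline
    "c1ccc2c(c1)ncc({})n2",       # quinoxaline-like
    "C1CCC({})CC1",               # cyclohexane
    "C1CCN({})CC1",               # piperidine (N-substituted)
    "C1COCCN1{}",                 # morpholine (N-substituted)
    "c1ccc(C({})=O)cc1",          # phenyl ketone
    "c1ccc(N{})cc1",              # aniline-linked
    "c1ccc(O{})cc1",              # phenol ether-linked
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)N", "C(=O)C",
    "S(N)(=O)=O", "CO",
]


def _enumerate_library() -> list[str]:
    """Deterministic canonical SMILES library from scaffold x substituent."""
    seen: set[str] = set()
    library: list[str] = []
    for scaffold in _SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            smiles = scaffold.format(sub)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None or mol.GetNumHeavyAtoms() < 4:
                continue
            if AllChem.MMFFGetMoleculeProperties(Chem.AddHs(mol)) is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            library.append(canonical)
    return library


_LIBRARY: list[str] | None = None


def molecule_library() -> list[str]:
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = _enumerate_library()
    return list(_LIBRARY)


@dataclass
class SyntheticTask:
    """A labeled molecule set with a known generating process."""

    molecules: list[str]                 # SMILES
    labels: np.ndarray                   # -logM floats
    seed: int
    noise_sigma: float
    generator: str                       # human-readable generating rule
    informative_conformer_index: list[int] | None = None
    ensembles: list[ConformerEnsemble] | None = None
    molecule_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.molecule_ids:
            self.molecule_ids = [f"mol_{i:04d}" for i in range(len(self.molecules))]


def _regression_label(smiles: str) -> float:
    """Noise-free regression target: affine in heavy-atom and ring counts."""
    mol = Chem.MolFromSmiles(smiles)
    n_heavy = mol.GetNumHeavyAtoms()
    n_rings = mol.GetRingInfo().NumRings()
    return 1.5 + 0.35 * n_heavy + 0.6 * n_rings


def make_regression_task(
    n: int, noise_sigma: float = 0.1, seed: int = 0
) -> SyntheticTask:
    """Sample n molecules from the built-in library with affine labels."""
    if n < 10:
        raise ValueError("n must be >= 10")
    library = molecule_library()
    if n > len(library):
        raise GenerationError(
            f"requested {n} molecules but the library enumerates {len(library)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [library[i] for i in rng.choice(len(library), size=n, replace=False)]
    clean = np.array([_regression_label(s) for s in chosen])
    labels = clean + rng.normal(0.0, noise_sigma, size=n)
    labels = np.clip(labels, *LABEL_RANGE)
    return SyntheticTask(
        molecules=chosen,
        labels=labels,
        seed=seed,
        noise_sigma=noise_sigma,
        generator="1.5 + 0.35*n_heavy + 0.6*n_rings + N(0, sigma)",
    )


def _mean_pairwise_distance(coords: np.ndarray) -> float:
    n = coords.shape[0]
    if n < 2:
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return float(d[np.triu_indices(n, 1)].mean())


def make_noisy_conformer_task(
    n: int,
    M: int = 10,
    seed: int = 0,
    perturb_sigma: float = 2.0,
    noise_sigma: float = 0.1,
    conformer_seed: int | None = None,
) -> SyntheticTask:
    """MIL task: one informative conformer per molecule, the rest scrambled.

    Per molecule, a designated conformer keeps its aligned MMFF94-optimized
    coordinates; every other conformer's atomic positions receive iid
    Gaussian displacements of scale `perturb_sigma` (Angstrom), destroying
    chemically plausible geometry.  The label is an affine function of the
    informative conformer's mean pairwise heavy-atom distance plus small
    noise, so only that conformer carries the signal.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    library = molecule_library()
    if n > len(library):
        raise GenerationError(
            f"requested {n} molecules but the library enumerates {len(library)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [library[i] for i in rng.choice(len(library), size=n, replace=False)]
    cseed = seed if conformer_seed is None else conformer_seed
    ensembles: list[ConformerEnsemble] = []
    informative: list[int] = []
    labels = np.empty(n)
    for i, smiles in enumerate(chosen):
        ens = prepare_ensemble(
            smiles,
            n_conformers=M,
            seed=cseed + 1000 * i,
            molecule_id=f"mol_{i:04d}",
        )
        info = int(rng.integers(M))
        if perturb_sigma > 0:
            for m, conf in enumerate(ens.mol.GetConformers()):
                if m == info:
                    continue
                coords = np.asarray(conf.GetPositions())
                coords = coords + rng.normal(0.0, perturb_sigma, size=coords.shape)
                for a in range(coords.shape[0]):
                    conf.SetAtomPosition(a, coords[a].tolist())
        stat = _mean_pairwise_distance(ens.coords[info])
        labels[i] = 2.0 + 0.8 * stat + rng.normal(0.0, noise_sigma)
        ens.label = float(np.clip(labels[i], *LABEL_RANGE))
        labels[i] = ens.label
        ensembles.append(ens)
        informative.append(info)
    return SyntheticTask(
        molecules=chosen,
        labels=labels,
        seed=seed,
        noise_sigma=noise_sigma,
        generator="2.0 + 0.8*mean_pairwise_distance(informative conformer) + N(0, sigma)",
        informative_conformer_index=informative,
        ensembles=ensembles,
        molecule_ids=[e.molecule_id for e in ensembles],
    )


def case_molecule_fixture(seed: int = 0, n_conformers: int = 10) -> SyntheticTask:
    """The CDK2 case molecule (9.0 -logM) with a generated conformer ensemble."""
    ens = prepare_ensemble(
        CASE_MOLECULE_SMILES,
        n_conformers=n_conformers,
        seed=seed,
        molecule_id="case_cdk2",
        label=CASE_MOLECULE_LABEL,
    )
    return SyntheticTask(
        molecules=[CASE_MOLECULE_SMILES],
        labels=np.array([CASE_MOLECULE_LABEL]),
        seed=seed,
        noise_sigma=0.0,
        generator="measured case endpoint",
        ensembles=[ens],
        molecule_ids=["case_cdk2"],
    )


def task_graphs(
    task: SyntheticTask, n_conformers: int = 10, conformer_seed: int = 0
) -> list[MolecularGraph]:
    """Featurize a task into molecular graphs (generating conformers when
    the task does not already carry ensembles)."""
    graphs = []
    if task.ensembles is not None:
        for ens, label in zip(task.ensembles, task.labels):
            graphs.append(assemble_graph(ens, label_y=float(label)))
        return graphs
    for i, (smiles, label) in enumerate(zip(task.molecules, task.labels)):
        ens = prepare_ensemble(
            smiles,
            n_conformers=n_conformers,
            seed=conformer_seed + 1000 * i,
            molecule_id=task.molecule_ids[i],
        )
        graphs.append(assemble_graph(ens, label_y=float(label)))
    return graphs
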