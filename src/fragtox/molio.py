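"""Molecule parsing, featurization, 3D embedding and dataset loading.

Molecules are handled as heavy-atom graphs (hydrogens implicit) in canonical
SMILES atom order: every SMILES is canonicalized and re-parsed so that atom
indices are reproducible from the stored string alone.  3D conformers come
from ETKDG embedding followed by MMFF94 force-field optimization, both seeded
for determinism; molecules for which no conformer can be generated are
dropped and counted in a recovery log, mirroring the per-dataset "recovered"
accounting used when benchmarking on public toxicity sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import (
    AllMoleculesDropped,
    EmbedFailure,
    EmptyDataset,
    MissingColumn,
    ParseFailure,
    SanitizeFailure,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FeaturizerConfig",
    "Molecule",
    "RecoveryLog",
    "LabeledDataset",
    "SplitIndices",
    "featurize_molecule",
    "embed_3d",
    "compute_ecfp",
    "scaffold_split",
    "load_dataset",
    "murcko_scaffold_smiles",
]

# one-hot vocabularies for the atom descriptor vector
_ELEMENTS = (6, 7, 8, 16, 9, 17, 35, 53, 15)  # C N O S F Cl Br I P (+other)
_HYBRID = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)
_CHIRAL = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_MAX_DEGREE = 5
_MAX_NUM_H = 4


@dataclass(frozen=True)
class FeaturizerConfig:
    """Atom-descriptor layout; ``n_features`` is derived from the vocabularies."""

    ecfp_radius: int = 2
    ecfp_bits: int = 1024

    @property
    def n_features(self) -> int:
        return (
            len(_ELEMENTS) + 1  # element one-hot + other
            + _MAX_DEGREE + 2  # degree one-hot (+ unused overflow slot)
            + 1  # formal charge
            + len(_HYBRID) + 1  # hybridization one-hot + other
            + 1  # aromatic flag
            + _MAX_NUM_H + 2  # total H one-hot (+ unused overflow slot)
            + 1  # ring membership
            + len(_CHIRAL) + 1  # chirality one-hot + other
        )


@dataclass(frozen=True)
class Molecule:
    """A heavy-atom molecular graph with 2D/3D geometry and an ECFP.

    ``coords3d`` is all-NaN until :func:`embed_3d` succeeds.
    """

    smiles: str
    n_atoms: int
    atom_features: np.ndarray  # (N, nf)
    coords2d: np.ndarray  # (N, 2)
    coords3d: np.ndarray  # (N, 3), Angstrom
    bond_adjacency: np.ndarray  # (N, N) binary, zero diagonal
    atom_masses: np.ndarray  # (N,), amu
    ecfp: np.ndarray  # (n_bits,) in {0,1}

    @property
    def has_conformer(self) -> bool:
        return bool(np.isfinite(self.coords3d).all())

    def rdkit_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class RecoveryLog:
    """Per-stage molecule accounting: parsed = embedded + dropped."""

    total: int = 0
    parsed: int = 0
    embedded: int = 0
    dropped: int = 0
    dropped_smiles: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "parsed": self.parsed,
            "embedded": self.embedded,
            "dropped": self.dropped,
            "dropped_smiles": list(self.dropped_smiles),
        }


@dataclass
class LabeledDataset:
    molecules: list
    labels: np.ndarray  # (M, T) float
    observed: np.ndarray  # (M, T) in {0,1}
    task_names: list
    recovery_log: RecoveryLog = field(default_factory=RecoveryLog)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def _onehot(value, vocab) -> list:
    v = [0.0] * (len(vocab) + 1)
    try:
        v[vocab.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def _atom_vector(atom: Chem.Atom) -> list:
    return (
        _onehot(atom.GetAtomicNum(), list(_ELEMENTS))
        + _onehot(min(atom.GetDegree(), _MAX_DEGREE), list(range(_MAX_DEGREE + 1)))
        + [float(atom.GetFormalCharge())]
        + _onehot(atom.GetHybridization(), list(_HYBRID))
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _onehot(min(atom.GetTotalNumHs(), _MAX_NUM_H), list(range(_MAX_NUM_H + 1)))
        + [1.0 if atom.IsInRing() else 0.0]
        + _onehot(atom.GetChiralTag(), list(_CHIRAL))
    )


def featurize_molecule(smiles: str, config: FeaturizerConfig | None = None) -> Molecule:
    """Parse a SMILES into a featurized heavy-atom graph.

    Atom order follows the canonical SMILES; 2D coordinates come from the
    standard depiction layout; 3D coordinates are NaN placeholders until
    :func:`embed_3d`.

    Raises
    ------
    ParseFailure, SanitizeFailure
    """
    config = config or FeaturizerConfig()
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseFailure(f"empty SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ParseFailure(f"unparsable SMILES: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitize error types
        raise SanitizeFailure(f"sanitization failed for {smiles!r}: {exc}") from exc
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)  # canonical atom order
    n = mol.GetNumAtoms()

    feats = np.array([_atom_vector(a) for a in mol.GetAtoms()], dtype=np.float64)
    feats = feats.reshape(n, config.n_features)

    adj = np.zeros((n, n), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0

    AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords2d = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y] for i in range(n)])

    masses = np.array([a.GetMass() for a in mol.GetAtoms()], dtype=np.float64)
    ecfp = compute_ecfp(mol, config.ecfp_radius, config.ecfp_bits)
    return Molecule(
        smiles=canonical,
        n_atoms=n,
        atom_features=feats,
        coords2d=coords2d,
        coords3d=np.full((n, 3), np.nan),
        bond_adjacency=adj,
        atom_masses=masses,
        ecfp=ecfp,
    )


def embed_3d(mol: Molecule, seed: int = 0) -> Molecule:
    """Attach an MMFF-optimized 3D conformer (heavy atoms only).

    Deterministic for a fixed ``seed``.  Raises :class:`EmbedFailure` when no
    conformer can be generated.
    """
    rd = Chem.MolFromSmiles(mol.smiles)
    rdh = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    cid = AllChem.EmbedMolecule(rdh, params)
    if cid < 0:
        raise EmbedFailure(f"no conformer for {mol.smiles!r}")
    try:
        AllChem.MMFFOptimizeMolecule(rdh)
    except Exception:
        pass  # keep the unoptimized ETKDG geometry
    rdh = Chem.RemoveHs(rdh)
    coords = np.asarray(rdh.GetConformer().GetPositions(), dtype=np.float64)
    if coords.shape != (mol.n_atoms, 3) or not np.isfinite(coords).all():
        raise EmbedFailure(f"degenerate conformer for {mol.smiles!r}")
    return replace(mol, coords3d=coords)


def compute_ecfp(mol, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Extended-connectivity fingerprint as a {0,1} vector of length ``n_bits``."""
    rd = mol.rdkit_mol() if isinstance(mol, Molecule) else mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(rd)
    arr = np.zeros(n_bits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def murcko_scaffold_smiles(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES ('' for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


def scaffold_split(
    dataset: LabeledDataset,
    fractions: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitIndices:
    """Deterministic scaffold split: whole scaffold groups per subset.

    Groups are sorted by (size descending, scaffold string) and filled
    greedily train -> val -> test toward the target counts, so the test set
    holds scaffolds never seen in training.  ``fractions`` must be
    non-negative with a positive train share and sum to 1; a zero fraction
    yields an empty subset.  ``seed`` is accepted for interface stability but
    the fill is fully deterministic.
    """
    if dataset.n_molecules == 0:
        raise EmptyDataset("cannot split an empty dataset")
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr < 0).any() or fr[0] <= 0 or abs(fr.sum() - 1.0) > 1e-8:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")

    groups: dict[str, list] = {}
    for i, m in enumerate(dataset.molecules):
        groups.setdefault(murcko_scaffold_smiles(m.smiles), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    m_total = dataset.n_molecules
    targets = [fr[0] * m_total, fr[1] * m_total, fr[2] * m_total]
    sets: list[list] = [[], [], []]
    for _, idxs in ordered:
        # place the group in the earliest subset still short of its target
        placed = False
        for s in range(3):
            if len(sets[s]) + len(idxs) <= targets[s] + 1e-9:
                sets[s].extend(idxs)
                placed = True
                break
        if not placed:
            deficits = [targets[s] - len(sets[s]) for s in range(3)]
            sets[int(np.argmax(deficits))].extend(idxs)
    return SplitIndices(
        train=np.array(sorted(sets[0]), dtype=int),
        val=np.array(sorted(sets[1]), dtype=int),
        test=np.array(sorted(sets[2]), dtype=int),
    )


def load_dataset(
    path,
    smiles_column: str,
    task_columns,
    seed: int = 0,
    config: FeaturizerConfig | None = None,
    embed: bool = True,
) -> LabeledDataset:
    """Load a CSV of SMILES + binary labels into a featurized dataset.

    Rows whose molecule fails parsing or 3D embedding are dropped and logged;
    empty label cells become unobserved entries (mask 0).
    """
    df = pd.read_csv(path)
    task_columns = list(task_columns)
    missing = [c for c in [smiles_column, *task_columns] if c not in df.columns]
    if missing:
        raise MissingColumn(f"columns {missing} not in {list(df.columns)}")

    molecules, labels, observed = [], [], []
    log = RecoveryLog(total=len(df))
    for _, row in df.iterrows():
        smi = row[smiles_column]
        try:
            mol = featurize_molecule(smi, config)
        except (ParseFailure, SanitizeFailure):
            log.dropped += 1
            log.dropped_smiles.append(str(smi))
            continue
        log.parsed += 1
        if embed:
            try:
                mol = embed_3d(mol, seed=seed)
            except EmbedFailure:
                log.dropped += 1
                log.dropped_smiles.append(mol.smiles)
                continue
        log.embedded += 1
        lab, obs = [], []
        for col in task_columns:
            v = row[col]
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                lab.append(0.0)
                obs.append(0.0)
            else:
                lab.append(float(v))
                obs.append(1.0)
        molecules.append(mol)
        labels.append(lab)
        observed.append(obs)
    if not molecules:
        raise AllMoleculesDropped(f"no usable molecules in {path}")
    labels_arr = np.asarray(labels, dtype=np.float64)
    observed_arr = np.asarray(observed, dtype=np.float64)
    bad = (observed_arr == 1) & ~np.isin(labels_arr, (0.0, 1.0))
    if bad.any():
        warnings.warn("non-binary observed labels found; kept as-is", stacklevel=2)
    return LabeledDataset(molecules, labels_arr, observed_arr, task_columns, log)
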