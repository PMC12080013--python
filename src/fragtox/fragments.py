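"""Atom partitions under three fragmentation schemes, lifted to fragment graphs.

Each scheme yields a :class:`FragmentAssignment` — a partition of the heavy
atoms into connected, disjoint, covering fragments:

* **BRICS** severs the retrosynthetic cleavage bonds and takes the connected
  components (attachment dummies are never materialized; membership is on
  the original atom indices).
* **Murcko** separates the Bemis-Murcko scaffold (ring systems + linkers)
  from its side chains; each connected side-chain component is a fragment,
  and an acyclic molecule is a single whole-molecule fragment.
* **Functional groups** collects all matches of the RDKit functional-group
  SMARTS catalog (attachment points excluded), merges overlapping matches,
  and groups the unmatched atoms into connected backbone fragments.

:func:`build_fragment_graph` pools a molecule onto a partition: sum-pooled
features, mass-weighted center-of-mass coordinates (3D and 2D), and a
fragment adjacency inherited from any inter-fragment bond.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS, FragmentCatalog, RDConfig
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import PartitionError
from .molio import Molecule

__all__ = [
    "FragmentationMethod",
    "FragmentAssignment",
    "FragmentGraph",
    "fragment_brics",
    "fragment_murcko",
    "fragment_functional_groups",
    "fragment_all_views",
    "build_fragment_graph",
]


class FragmentationMethod(str, Enum):
    BRICS = "brics"
    MURCKO = "murcko"
    FUNCTIONAL_GROUP = "fg"


@dataclass(frozen=True)
class FragmentAssignment:
    method: FragmentationMethod
    fragments: tuple  # tuple of frozensets of atom indices

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def validate(self, n_atoms: int, adjacency: np.ndarray) -> None:
        """Raise :class:`PartitionError` unless this is a valid partition
        into connected fragments."""
        seen: set[int] = set()
        for frag in self.fragments:
            if not frag:
                raise PartitionError("empty fragment")
            if seen & frag:
                raise PartitionError("overlapping fragments")
            seen |= frag
            if not _connected(frag, adjacency):
                raise PartitionError(f"fragment {sorted(frag)} not connected")
        if seen != set(range(n_atoms)):
            raise PartitionError("fragments do not cover all atoms")


@dataclass(frozen=True)
class FragmentGraph:
    """A molecule lifted to fragment resolution."""

    n_frags: int
    frag_features: np.ndarray  # (K, nf) sum-pooled atom features
    frag_coords3d: np.ndarray  # (K, 3) centers of mass
    frag_coords2d: np.ndarray  # (K, 2)
    frag_adjacency: np.ndarray  # (K, K) binary
    frag_distances2d: np.ndarray  # (K, K)
    frag_masses: np.ndarray  # (K,) total fragment mass
    assignment: FragmentAssignment


def _connected(atoms: frozenset, adjacency: np.ndarray) -> bool:
    atoms = set(atoms)
    start = next(iter(atoms))
    seen = {start}
    frontier = [start]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(adjacency[i])[0]:
            j = int(j)
            if j in atoms and j not in seen:
                seen.add(j)
                frontier.append(j)
    return seen == atoms


def _components(atoms, adjacency: np.ndarray):
    """Connected components of the subgraph induced by ``atoms``."""
    remaining = set(atoms)
    comps = []
    while remaining:
        start = remaining.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(adjacency[i])[0]:
                j = int(j)
                if j in remaining:
                    remaining.discard(j)
                    comp.add(j)
                    frontier.append(j)
        comps.append(frozenset(comp))
    return comps


def _sorted_fragments(frags) -> tuple:
    return tuple(sorted(frags, key=lambda f: min(f)))


def fragment_brics(mol: Molecule) -> FragmentAssignment:
    """Partition by severing BRICS retrosynthetic cleavage bonds.

    A molecule with no cleavable bond is one whole-molecule fragment.
    """
    rd = mol.rdkit_mol()
    cut = {tuple(sorted(bond)) for bond, _labels in BRICS.FindBRICSBonds(rd)}
    adj = mol.bond_adjacency.copy()
    for i, j in cut:
        adj[i, j] = adj[j, i] = 0.0
    frags = _components(range(mol.n_atoms), adj)
    return FragmentAssignment(FragmentationMethod.BRICS, _sorted_fragments(frags))


def _scaffold_atoms(rd: Chem.Mol) -> set:
    """Atom indices of the Bemis-Murcko scaffold (empty set if acyclic)."""
    if rd.GetRingInfo().NumRings() == 0:
        return set()
    scaffold = MurckoScaffold.GetScaffoldForMol(rd)
    if scaffold is not None and scaffold.GetNumAtoms() > 0:
        match = rd.GetSubstructMatch(scaffold)
        if match:
            return set(match)
    # fallback: iteratively prune non-ring leaves (plain pruning drops
    # exocyclic double-bonded atoms, acceptable for degenerate inputs)
    keep = set(range(rd.GetNumAtoms()))
    ring = {a.GetIdx() for a in rd.GetAtoms() if a.IsInRing()}
    changed = True
    while changed:
        changed = False
        for i in sorted(keep - ring):
            deg = sum(1 for j in _neighbors(rd, i) if j in keep)
            if deg <= 1:
                keep.discard(i)
                changed = True
    return keep


def _neighbors(rd: Chem.Mol, i: int):
    return [n.GetIdx() for n in rd.GetAtomWithIdx(i).GetNeighbors()]


def fragment_murcko(mol: Molecule) -> FragmentAssignment:
    """Scaffold fragment plus one fragment per connected side-chain component."""
    rd = mol.rdkit_mol()
    scaffold = _scaffold_atoms(rd)
    if not scaffold:
        frags = [frozenset(range(mol.n_atoms))]
    else:
        frags = [frozenset(scaffold)]
        rest = set(range(mol.n_atoms)) - scaffold
        if rest:
            frags.extend(_components(rest, mol.bond_adjacency))
    return FragmentAssignment(FragmentationMethod.MURCKO, _sorted_fragments(frags))


_FG_PATTERNS: list | None = None


def _functional_group_patterns() -> list:
    """RDKit functional-group SMARTS catalog with the attachment dummy marked."""
    global _FG_PATTERNS
    if _FG_PATTERNS is None:
        path = os.path.join(RDConfig.RDDataDir, "FunctionalGroups.txt")
        params = FragmentCatalog.FragCatParams(1, 6, path)
        patterns = []
        for i in range(params.GetNumFuncGroups()):
            # copy: the group Mol is owned by `params` and must outlive it
            query = Chem.Mol(params.GetFuncGroup(i))
            dummy_pos = [a.GetIdx() for a in query.GetAtoms() if a.GetAtomicNum() == 0]
            patterns.append((query, dummy_pos))
        _FG_PATTERNS = patterns
    return _FG_PATTERNS


def fragment_functional_groups(mol: Molecule) -> FragmentAssignment:
    """Functional-group matches (merged when overlapping) + backbone components."""
    rd = mol.rdkit_mol()
    matched_sets = []
    for query, dummy_pos in _functional_group_patterns():
        for match in rd.GetSubstructMatches(query):
            atoms = frozenset(a for pos, a in enumerate(match) if pos not in dummy_pos)
            if atoms:
                matched_sets.append(set(atoms))
    # merge overlapping matches (union-find over shared atoms)
    merged: list[set] = []
    for s in matched_sets:
        group = set(s)
        keep = []
        for existing in merged:
            if existing & group:
                group |= existing
            else:
                keep.append(existing)
        keep.append(group)
        merged = keep
    frags = [frozenset(f) for f in merged]
    covered = set().union(*merged) if merged else set()
    rest = set(range(mol.n_atoms)) - covered
    if rest:
        frags.extend(_components(rest, mol.bond_adjacency))
    # a merged FG group can straddle a severed backbone and come out
    # disconnected; split it into its connected pieces to keep the invariant
    final = []
    for f in frags:
        final.extend(_components(f, mol.bond_adjacency))
    return FragmentAssignment(FragmentationMethod.FUNCTIONAL_GROUP, _sorted_fragments(final))


def fragment_all_views(mol: Molecule) -> dict:
    """All three fragment views keyed by :class:`FragmentationMethod`."""
    return {
        FragmentationMethod.BRICS: fragment_brics(mol),
        FragmentationMethod.MURCKO: fragment_murcko(mol),
        FragmentationMethod.FUNCTIONAL_GROUP: fragment_functional_groups(mol),
    }


def build_fragment_graph(mol: Molecule, assignment: FragmentAssignment) -> FragmentGraph:
    """Lift a molecule onto a fragment partition.

    Fragment features are sum-pooled atom features; fragment coordinates are
    the mass-weighted centers of the member atoms (heavy-atom masses); two
    fragments are adjacent iff any bond crosses between them.
    """
    assignment.validate(mol.n_atoms, mol.bond_adjacency)
    k = assignment.n_fragments
    nf = mol.atom_features.shape[1]
    feats = np.zeros((k, nf))
    c3d = np.zeros((k, 3))
    c2d = np.zeros((k, 2))
    masses = np.zeros(k)
    frag_of = np.empty(mol.n_atoms, dtype=int)
    for idx, frag in enumerate(assignment.fragments):
        members = sorted(frag)
        frag_of[members] = idx
        w = mol.atom_masses[members]
        masses[idx] = w.sum()
        feats[idx] = mol.atom_features[members].sum(axis=0)
        c3d[idx] = (w[:, None] * mol.coords3d[members]).sum(axis=0) / w.sum()
        c2d[idx] = (w[:, None] * mol.coords2d[members]).sum(axis=0) / w.sum()
    adj = np.zeros((k, k))
    for i, j in zip(*np.nonzero(np.triu(mol.bond_adjacency))):
        a, b = frag_of[i], frag_of[j]
        if a != b:
            adj[a, b] = adj[b, a] = 1.0
    dist2d = np.linalg.norm(c2d[:, None, :] - c2d[None, :, :], axis=-1)
    return FragmentGraph(k, feats, c3d, c2d, adj, dist2d, masses, assignment)
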