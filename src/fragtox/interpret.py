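"""Attention-based toxicophore highlighting.

Per-atom scores are read off the combined attention matrices of a chosen
transformer layer (the last by default): heads are averaged and the score of
an atom is the column mean of the averaged matrix — the attention the atom
*receives*, averaged over source atoms (a row-mean variant is available).
Atoms scoring strictly above the molecule-mean score are highlighted, and a
bond is highlighted when both endpoints are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LayerOutOfRange, ShapeMismatch
from .model import AttentionRecord
from .molio import Molecule

__all__ = ["AtomScores", "extract_atom_attention", "highlight", "render_svg"]


@dataclass(frozen=True)
class AtomScores:
    scores: np.ndarray  # (N,) non-negative
    layer: int


def extract_atom_attention(record: AttentionRecord, layer: int = -1, mode: str = "column") -> AtomScores:
    """Per-atom attention scores from one layer's head-averaged matrix.

    ``mode='column'`` scores attention received (column mean); ``mode='row'``
    scores attention emitted.  Scores of a layer whose head matrices are
    row-stochastic sum to 1 in column mode.
    """
    if record.n_layers == 0:
        raise LayerOutOfRange("empty attention record")
    if layer < -record.n_layers or layer >= record.n_layers:
        raise LayerOutOfRange(f"layer {layer} outside [0, {record.n_layers})")
    resolved = layer % record.n_layers
    head_avg = record.matrices[resolved].mean(axis=0)  # (N, N)
    if mode == "column":
        scores = head_avg.mean(axis=0)
    elif mode == "row":
        scores = head_avg.mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AtomScores(scores=np.asarray(scores, dtype=np.float64), layer=resolved)


def highlight(mol: Molecule, scores: AtomScores) -> dict:
    """Atoms above the molecule-mean score; bonds with both ends highlighted.

    Returns ``{highlighted_atoms, highlighted_bonds, intensities}`` where
    intensities are the min-max normalized scores (all zeros when flat).
    """
    s = scores.scores
    if s.shape != (mol.n_atoms,):
        raise ShapeMismatch(f"expected {mol.n_atoms} scores, got {s.shape}")
    span = s.max() - s.min()
    intensities = (s - s.min()) / span if span > 0 else np.zeros_like(s)
    atoms = sorted(int(i) for i in np.nonzero(s > s.mean())[0])
    atom_set = set(atoms)
    bonds = [
        [int(i), int(j)]
        for i, j in zip(*np.nonzero(np.triu(mol.bond_adjacency)))
        if int(i) in atom_set and int(j) in atom_set
    ]
    return {
        "highlighted_atoms": atoms,
        "highlighted_bonds": bonds,
        "intensities": intensities,
    }


def render_svg(mol: Molecule, scores: AtomScores, size: tuple = (400, 400)) -> str:
    """Draw the molecule with red atom intensities; returns SVG text."""
    from rdkit.Chem.Draw import rdMolDraw2D

    annotation = highlight(mol, scores)
    rd = mol.rdkit_mol()
    colors = {
        int(i): (1.0, 1.0 - 0.8 * float(v), 1.0 - 0.8 * float(v))
        for i, v in enumerate(annotation["intensities"])
    }
    bond_ids, bond_colors = [], {}
    for i, j in annotation["highlighted_bonds"]:
        b = rd.GetBondBetweenAtoms(i, j)
        if b is not None:
            bond_ids.append(b.GetIdx())
            bond_colors[b.GetIdx()] = (0.6, 0.6, 0.6)
    drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        rd,
        highlightAtoms=list(colors),
        highlightAtomColors=colors,
        highlightBonds=bond_ids,
        highlightBondColors=bond_colors,
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()
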