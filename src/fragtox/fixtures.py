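"""Deterministic synthetic SMILES datasets with rule-based labels.

Molecules are assembled from a curated set of drug-like ring/chain templates
and substituent building blocks, so every generated structure is guaranteed
to parse, sanitize and 3D-embed.  Labels are substructure indicators checked
by SMARTS on the assembled molecule (a nitro group, a carboxylic acid, a
halogen, or an aromatic scaffold class), which makes them exactly learnable
from atom descriptors and fingerprints — a wiring check for the model, not
an emulation of real toxicity label noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import InfeasibleSpec
from .molio import FeaturizerConfig, LabeledDataset, RecoveryLog, embed_3d, featurize_molecule

__all__ = ["LabelRule", "FixtureSpec", "generate_fixture_dataset", "fixture_molecule_panel"]


class LabelRule(str, Enum):
    HAS_NITRO = "has_nitro"
    HAS_CARBOXYL = "has_carboxyl"
    HAS_HALOGEN = "has_halogen"
    SCAFFOLD_CLASS = "scaffold_class"  # aromatic ring present


_RULE_SMARTS = {
    LabelRule.HAS_NITRO: "[N+](=O)[O-]",
    LabelRule.HAS_CARBOXYL: "[CX3](=O)[OX2H1]",
    LabelRule.HAS_HALOGEN: "[F,Cl,Br,I]",
    LabelRule.SCAFFOLD_CLASS: "a",
}

# templates with two substitution slots; all embed cleanly at small size
_TEMPLATES = (
    "c1cc({a})ccc1{b}",          # benzene
    "c1cc({a})cnc1{b}",          # pyridine
    "c1nc({a})ncc1{b}",          # pyrimidine
    "c1oc({a})cc1{b}",           # furan
    "c1sc({a})cc1{b}",           # thiophene
    "C1CCC({a})CC1{b}",          # cyclohexane
    "C1CCC({a})C1{b}",           # cyclopentane
    "C1CCN({a})CC1{b}",          # piperidine (N-substituted)
    "C1COCCN1{a}",               # morpholine, single slot
    "c1ccc2cc({a})ccc2c1",       # naphthalene, single slot
    "C({a})CC{b}",               # propane chain
    "C({a})CCCC{b}",             # pentane chain
    "OC({a})CC{b}",              # alcohol chain
    "C1CC1C({a})C{b}",           # cyclopropane chain
)

# substituents written as branch fragments; keyed by which rules they trigger
_RULE_SUBSTITUENT = {
    LabelRule.HAS_NITRO: ("[N+](=O)[O-]",),
    LabelRule.HAS_CARBOXYL: ("C(=O)O",),
    LabelRule.HAS_HALOGEN: ("F", "Cl", "Br"),
}
_NEUTRAL = ("C", "CC", "O", "OC", "N", "CO", "C(C)C", "CN", "")


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 32
    label_rules: tuple = (LabelRule.HAS_NITRO,)
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 4:
            raise InfeasibleSpec("need at least 4 molecules")
        if not 0 < self.positive_fraction < 1:
            raise InfeasibleSpec("positive_fraction must be in (0, 1)")
        if len(self.label_rules) not in (1, 2):
            raise InfeasibleSpec("1 or 2 label rules supported")


def _rule_labels(smiles: str, rules) -> list:
    mol = Chem.MolFromSmiles(smiles)
    return [
        1.0 if mol.HasSubstructMatch(Chem.MolFromSmarts(_RULE_SMARTS[r])) else 0.0
        for r in rules
    ]


def _assemble(rng: np.random.Generator, want_positive: bool, rule: LabelRule) -> str:
    # decoy substituents: neutral groups plus the marks of the *other* rules,
    # giving harder negatives and label variation for a second task
    decoys = _NEUTRAL + tuple(
        s for r, subs in _RULE_SUBSTITUENT.items() if r != rule for s in subs
    )
    template = _TEMPLATES[rng.integers(len(_TEMPLATES))]
    if rule == LabelRule.SCAFFOLD_CLASS:
        # class membership is the template's aromaticity
        pool = [t for t in _TEMPLATES if t.startswith("c") == want_positive]
        template = pool[rng.integers(len(pool))]
        sub_a = _NEUTRAL[rng.integers(len(_NEUTRAL))]
        sub_b = _NEUTRAL[rng.integers(len(_NEUTRAL))]
    elif want_positive:
        marks = _RULE_SUBSTITUENT[rule]
        sub_a = marks[rng.integers(len(marks))]
        sub_b = decoys[rng.integers(len(decoys))]
        if rng.random() < 0.5:
            sub_a, sub_b = sub_b, sub_a
    else:
        sub_a = decoys[rng.integers(len(decoys))]
        sub_b = decoys[rng.integers(len(decoys))]
    smiles = template.replace("{a}", sub_a).replace("{b}", sub_b)
    smiles = smiles.replace("()", "")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ""
    return Chem.MolToSmiles(mol)


def generate_fixture_dataset(
    spec: FixtureSpec,
    csv_path=None,
    embed: bool = True,
    config: FeaturizerConfig | None = None,
) -> LabeledDataset:
    """Generate a rule-labeled dataset (optionally writing the CSV).

    The first rule drives the positive/negative balance
    (``positive_fraction``); labels for every rule are re-derived by SMARTS
    on the assembled molecule, so label/structure consistency holds by
    construction.  Byte-identical CSVs for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    rule = spec.label_rules[0]
    n_pos = int(round(spec.positive_fraction * spec.n_molecules))
    n_neg = spec.n_molecules - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InfeasibleSpec("positive_fraction infeasible for n_molecules")
    chosen: list[str] = []
    seen: set[str] = set()
    counts = {True: 0, False: 0}
    budget = {True: n_pos, False: n_neg}
    attempts = 0
    while counts[True] < n_pos or counts[False] < n_neg:
        attempts += 1
        if attempts > 200 * spec.n_molecules:
            raise InfeasibleSpec("could not assemble the requested class balance")
        want_positive = counts[True] < n_pos
        smiles = _assemble(rng, want_positive, rule)
        if not smiles:
            continue
        is_pos = _rule_labels(smiles, [rule])[0] == 1.0
        if counts[is_pos] >= budget[is_pos]:
            continue
        if smiles in seen and attempts < 50 * spec.n_molecules:
            continue  # prefer unique structures, allow repeats as last resort
        seen.add(smiles)
        chosen.append(smiles)
        counts[is_pos] += 1
    order = rng.permutation(len(chosen))
    chosen = [chosen[i] for i in order]

    rows = []
    task_names = [r.value for r in spec.label_rules]
    for smi in chosen:
        rows.append([smi] + [int(v) for v in _rule_labels(smi, spec.label_rules)])
    frame = pd.DataFrame(rows, columns=["smiles"] + task_names)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)

    molecules, labels = [], []
    log = RecoveryLog(total=len(frame))
    for smi, *labs in rows:
        mol = featurize_molecule(smi, config)
        log.parsed += 1
        if embed:
            mol = embed_3d(mol, seed=spec.seed)
        log.embedded += 1
        molecules.append(mol)
        labels.append([float(v) for v in labs])
    labels_arr = np.asarray(labels)
    return LabeledDataset(molecules, labels_arr, np.ones_like(labels_arr), task_names, log)


_PANEL = {
    # simple probes
    "ethane": "CC",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "ethanol": "CCO",
    "hexane": "CCCCCC",
    "nitrobenzene": "O=[N+]([O-])c1ccccc1",
    "benzoic_acid": "OC(=O)c1ccccc1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    # case-study drugs: BBB-permeant/impermeant antihistamines and
    # beta-blockers, an azo-dye carcinogen, and a dopamine agonist
    "diphenhydramine": "CN(C)CCOC(c1ccccc1)c1ccccc1",
    "cetirizine": "OC(=O)COCCN1CCN(CC1)C(c1ccccc1)c1ccc(Cl)cc1",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "sudan_i": "Oc1ccc2ccccc2c1/N=N/c1ccccc1",
    "pramipexole": "CCCN[C@H]1CCc2nc(N)sc2C1",
}


def fixture_molecule_panel() -> dict:
    """Named canonical SMILES used across the test-suite (immutable copy)."""
    return dict(_PANEL)
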