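import numpy as np
import pytest

from fragtox import DualBranchModel, embed_3d, featurize_molecule
from fragtox.fixtures import fixture_molecule_panel


def random_rigid_transform(rng):
    """Random rotation-or-reflection matrix + translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rng.random() < 0.5:
        q = -q  # include reflections
    t = rng.normal(size=3) * 5.0
    return q, t


@pytest.fixture(scope="session")
def panel_molecules():
    """All panel molecules, featurized and 3D-embedded (session cache)."""
    return {
        name: embed_3d(featurize_molecule(smi), seed=1)
        for name, smi in fixture_molecule_panel().items()
    }


@pytest.fixture(scope="session")
def small_model(panel_molecules):
    mol = next(iter(panel_molecules.values()))
    return DualBranchModel(mol.atom_features.shape[1], n_tasks=1, seed=3)
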