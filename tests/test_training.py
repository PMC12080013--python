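"""Losses, PCGrad, dataset merging, the optimization loop, AUROC."""

import numpy as np
import pytest

from fragtox import DualBranchModel, masked_bce_loss, merge_datasets, pcgrad
from fragtox.autodiff import Tensor
from fragtox.errors import ConfigError, EmptyDataset, LengthMismatch, NoDefinedTask, ShapeMismatch
from fragtox.fixtures import FixtureSpec, LabelRule, generate_fixture_dataset
from fragtox.molio import SplitIndices
from fragtox.training import Adam, TrainConfig, evaluate_auroc, train


# -- masked BCE --------------------------------------------------------------

def test_bce_analytic_value():
    total, per_task = masked_bce_loss(
        Tensor(np.array([[0.5]])), np.array([[1.0]]), np.array([[1.0]])
    )
    assert np.isclose(float(total.data), -np.log(0.5))


def test_bce_fully_masked_task_contributes_nothing():
    p = Tensor(np.array([[0.7, 0.2], [0.4, 0.9]]), requires_grad=True)
    labels = np.array([[1.0, 0.0], [0.0, 1.0]])
    observed = np.array([[1.0, 0.0], [1.0, 0.0]])  # task 2 fully masked
    total, per_task = masked_bce_loss(p, labels, observed)
    assert per_task.data[1] == 0.0
    total.backward()
    assert np.all(p.grad[:, 1] == 0.0)


def test_bce_perfect_fit_limit():
    p = Tensor(np.array([[1.0 - 1e-9, 1e-9]]))
    total, _ = masked_bce_loss(p, np.array([[1.0, 0.0]]), np.ones((1, 2)))
    assert float(total.data) < 1e-6


def test_bce_shape_mismatch():
    with pytest.raises(ShapeMismatch):
        masked_bce_loss(Tensor(np.zeros((2, 2))), np.zeros((2, 1)), np.zeros((2, 2)))


def test_masked_loss_isolation_gradients(panel_molecules):
    """An extra fully-masked task leaves the original task's gradients unchanged."""
    mol = panel_molecules["ethanol"]
    nfeat = mol.atom_features.shape[1]
    base = DualBranchModel(nfeat, n_tasks=1, seed=4)
    extended = DualBranchModel(nfeat, n_tasks=2, seed=4)
    # branch parameters coincide (same seed, drawn before the head); copy the
    # head column of the original task so adding the masked task changes
    # nothing about the task-0 function
    extended.params["head.W"].data[:, 0] = base.params["head.W"].data[:, 0]
    extended.params["head.b"].data[0] = base.params["head.b"].data[0]
    grads = {}
    for model, n_tasks in ((base, 1), (extended, 2)):
        probs, _ = model.forward(mol)
        labels = np.zeros((1, n_tasks))
        labels[0, 0] = 1.0
        observed = np.zeros((1, n_tasks))
        observed[0, 0] = 1.0
        total, _ = masked_bce_loss(probs.reshape(1, n_tasks), labels, observed)
        model.zero_grad()
        total.backward()
        grads[n_tasks] = {
            k: v.grad.copy()
            for k, v in model.params.items()
            if not k.startswith("head.") and v.grad is not None
        }
    for k in grads[1]:
        assert np.abs(grads[1][k] - grads[2][k]).max() < 1e-9


# -- PCGrad ------------------------------------------------------------------

def test_pcgrad_no_conflict_passthrough():
    rng = np.random.default_rng(0)
    out = pcgrad([np.array([1.0, 0.0]), np.array([0.0, 1.0])], rng)
    assert np.allclose(out, [1.0, 1.0])


def test_pcgrad_toy_projection():
    # g1=(1,0) conflicts with g2=(-1,1): g1 - (g1.g2/|g2|^2) g2 = (0.5, 0.5)
    g1, g2 = np.array([1.0, 0.0]), np.array([-1.0, 1.0])
    proj = g1 - (g1 @ g2) / (g2 @ g2) * g2
    assert np.allclose(proj, [0.5, 0.5])
    # g2 does not conflict back after checking: g2.g1 = -1 < 0, so g2 is
    # also projected; the combined update is the sum of both projections
    rng = np.random.default_rng(1)
    out = pcgrad([g1, g2], rng)
    proj2 = g2 - (g2 @ g1) / (g1 @ g1) * g1
    assert np.allclose(out, proj + proj2)


def test_pcgrad_single_task_and_zero_norm():
    rng = np.random.default_rng(2)
    g = np.array([3.0, -1.0, 2.0])
    assert np.allclose(pcgrad([g], rng), g)
    assert np.allclose(pcgrad([g, np.zeros(3)], rng), g)  # zero-norm skipped


def test_pcgrad_postcondition_random_conflicts():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n_tasks = int(rng.integers(2, 5))
        dim = int(rng.integers(2, 20))
        grads = [rng.normal(size=dim) for _ in range(n_tasks)]
        # replicate the algorithm to check the pairwise postcondition
        check_rng = np.random.default_rng(rng.integers(2**31))
        for i in check_rng.permutation(n_tasks):
            g_pc = grads[i].copy()
            for j in check_rng.permutation(n_tasks):
                if j == i:
                    continue
                dot = g_pc @ grads[j]
                if dot < 0:
                    g_pc = g_pc - dot / (grads[j] @ grads[j]) * grads[j]
                assert g_pc @ grads[j] >= -1e-9


def test_pcgrad_length_mismatch():
    with pytest.raises(LengthMismatch):
        pcgrad([np.zeros(3), np.zeros(4)], np.random.default_rng(0))


# -- merging -----------------------------------------------------------------

def _mini_dataset(seed, rule, n=6):
    return generate_fixture_dataset(
        FixtureSpec(n_molecules=n, label_rules=(rule,), seed=seed), embed=False
    )


def test_merge_disjoint_block_structure():
    a = _mini_dataset(1, LabelRule.HAS_NITRO)
    b = _mini_dataset(2, LabelRule.HAS_CARBOXYL)
    shared = len({m.smiles for m in a.molecules} & {m.smiles for m in b.molecules})
    merged = merge_datasets([a, b])
    assert merged.n_tasks == 2
    assert merged.n_molecules == 12 - shared
    if shared == 0:
        assert np.isclose(merged.observed.mean(), 0.5)


def test_merge_shared_molecule_row():
    a = _mini_dataset(1, LabelRule.HAS_NITRO)
    b = _mini_dataset(1, LabelRule.HAS_NITRO)  # identical molecules
    merged = merge_datasets([a, b])
    assert merged.n_molecules == a.n_molecules
    assert np.all(merged.observed == 1.0)
    assert np.array_equal(merged.labels[:, 0], merged.labels[:, 1])


def test_merge_preserves_heldout_membership():
    a = _mini_dataset(1, LabelRule.HAS_NITRO, n=8)
    b = _mini_dataset(1, LabelRule.HAS_NITRO, n=8)
    sp_a = SplitIndices(np.arange(6), np.array([], dtype=int), np.array([6, 7]))
    sp_b = SplitIndices(np.array([6, 7]), np.array([], dtype=int), np.arange(6))
    merged, sp = merge_datasets([a, b], splits=[sp_a, sp_b])
    # every molecule conflicts train-vs-test; all go to test
    assert len(sp.train) == 0 and len(sp.test) == merged.n_molecules


# -- training loop -----------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training_setup():
    ds = generate_fixture_dataset(FixtureSpec(n_molecules=12, seed=5))
    model = DualBranchModel(ds.molecules[0].atom_features.shape[1], 1, seed=0)
    prepared = [model.prepare_molecule(m) for m in ds.molecules]
    splits = SplitIndices(np.arange(12), np.array([], dtype=int), np.array([], dtype=int))
    return ds, splits, prepared


def test_training_seeded_determinism(tiny_training_setup):
    ds, splits, prepared = tiny_training_setup
    histories = []
    for _ in range(2):
        model = DualBranchModel(ds.molecules[0].atom_features.shape[1], 1, seed=0)
        _, hist = train(model, ds, splits, TrainConfig(max_epochs=5, seed=9), prepared=prepared)
        histories.append(hist.train_loss)
    assert np.allclose(histories[0], histories[1], rtol=0, atol=0)


def test_pcgrad_single_task_matches_plain_adam(tiny_training_setup):
    ds, splits, prepared = tiny_training_setup
    states = []
    for use_pcgrad in (False, True):
        model = DualBranchModel(ds.molecules[0].atom_features.shape[1], 1, seed=0)
        cfg = TrainConfig(max_epochs=2, seed=9, use_pcgrad=use_pcgrad)
        train(model, ds, splits, cfg, prepared=prepared)
        states.append(model.state_dict())
    for k in states[0]:
        assert np.allclose(states[0][k], states[1][k])


def test_multitask_pcgrad_training_runs():
    spec = FixtureSpec(n_molecules=10, label_rules=(LabelRule.HAS_NITRO, LabelRule.HAS_CARBOXYL), seed=3)
    ds = generate_fixture_dataset(spec)
    model = DualBranchModel(ds.molecules[0].atom_features.shape[1], 2, seed=0)
    splits = SplitIndices(np.arange(10), np.array([], dtype=int), np.array([], dtype=int))
    cfg = TrainConfig(max_epochs=2, seed=1, mode="MTL", use_pcgrad=True)
    _, hist = train(model, ds, splits, cfg)
    assert len(hist.train_loss) == 2 and np.isfinite(hist.train_loss).all()


def test_train_rejects_empty_split(tiny_training_setup):
    ds, _, prepared = tiny_training_setup
    model = DualBranchModel(ds.molecules[0].atom_features.shape[1], 1, seed=0)
    empty = SplitIndices(np.array([], dtype=int), np.array([], dtype=int), np.array([], dtype=int))
    with pytest.raises(EmptyDataset):
        train(model, ds, empty, TrainConfig(max_epochs=1), prepared=prepared)


def test_mtl_mode_requires_two_tasks(tiny_training_setup):
    ds, splits, prepared = tiny_training_setup
    model = DualBranchModel(ds.molecules[0].atom_features.shape[1], 1, seed=0)
    with pytest.raises(ConfigError):
        train(model, ds, splits, TrainConfig(max_epochs=1, mode="MTL"), prepared=prepared)


# -- AUROC -------------------------------------------------------------------

def _brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_perfect_and_reversed_rankings():
    from fragtox.training import _auroc_from_probs

    scores = np.array([[0.9], [0.8], [0.2], [0.1]])
    labels = np.array([[1.0], [1.0], [0.0], [0.0]])
    per, mean = _auroc_from_probs(scores, labels, np.ones_like(labels), ["t"])
    assert mean == 1.0
    per, mean = _auroc_from_probs(scores, 1 - labels, np.ones_like(labels), ["t"])
    assert mean == 0.0
    two = np.array([[0.6], [0.4]])
    assert _auroc_from_probs(two, np.array([[0.0], [1.0]]), np.ones((2, 1)), ["t"])[1] == 0.0
    assert _auroc_from_probs(two, np.array([[1.0], [0.0]]), np.ones((2, 1)), ["t"])[1] == 1.0


def test_auroc_matches_rank_pair_oracle():
    from fragtox.training import _auroc_from_probs

    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2)  # ties included
        labels = rng.integers(0, 2, size=n).astype(float)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, mean = _auroc_from_probs(scores[:, None], labels[:, None], np.ones((n, 1)), ["t"])
        assert np.isclose(mean, _brute_force_auroc(scores, labels))


def test_auroc_single_class_task_excluded():
    from fragtox.training import _auroc_from_probs

    scores = np.array([[0.5, 0.9], [0.6, 0.1]])
    labels = np.array([[1.0, 1.0], [1.0, 0.0]])
    with pytest.warns(UserWarning):
        per, mean = _auroc_from_probs(scores, labels, np.ones_like(labels), ["a", "b"])
    assert per["a"] is None and per["b"] == 1.0 and mean == 1.0
    with pytest.raises(NoDefinedTask):
        _auroc_from_probs(scores[:, :1], labels[:, :1], np.ones((2, 1)), ["a"])
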