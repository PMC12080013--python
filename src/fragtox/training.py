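"""Multi-task training: masked BCE loss, PCGrad gradient surgery, Adam loop.

Multi-organ datasets are merged by canonical SMILES into one molecule table
with a labels matrix and an observed mask; a task contributes to the loss
only through its observed cells.  With gradient surgery enabled, per-task
gradients of the shared parameters are computed separately each step and
conflicting pairs (negative dot product) are resolved by projecting one
gradient onto the normal plane of the other before summation — the PCGrad
scheme — after which Adam applies the combined update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor, stack
from .errors import (
    ConfigError,
    EmptyDataset,
    LengthMismatch,
    NoDefinedTask,
    NonFiniteLoss,
    ShapeMismatch,
)
from .model import DualBranchModel
from .molio import LabeledDataset, RecoveryLog, SplitIndices

__all__ = [
    "GradientSet",
    "TrainConfig",
    "TrainingHistory",
    "Adam",
    "masked_bce_loss",
    "masked_mse_loss",
    "pcgrad",
    "merge_datasets",
    "train",
    "evaluate_auroc",
    "predict_dataset",
]


@dataclass
class GradientSet:
    """Per-task flattened gradients over the shared parameters."""

    task_names: list
    vectors: list  # list of 1-D arrays, equal length

    def __post_init__(self):
        lengths = {v.shape[0] for v in self.vectors}
        if len(lengths) > 1:
            raise LengthMismatch(f"gradient lengths differ: {sorted(lengths)}")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    seed: int = 0
    mode: str = "STL"  # or "MTL"
    use_pcgrad: bool = False
    loss: str = "bce"  # or "mse"
    patience: int | None = None  # early stop on val mean AUROC
    pcgrad_reduce: str = "sum"  # or "mean"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("learning_rate, batch_size, max_epochs must be positive")
        if self.mode not in ("STL", "MTL"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.loss not in ("bce", "mse"):
            raise ConfigError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingHistory:
    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_auroc: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "epoch": list(self.epoch),
            "train_loss": list(self.train_loss),
            "val_loss": list(self.val_loss),
            "val_auroc": list(self.val_auroc),
        }


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _check_loss_shapes(probabilities, labels, observed):
    if probabilities.shape != labels.shape or labels.shape != observed.shape:
        raise ShapeMismatch(
            f"probabilities {probabilities.shape}, labels {labels.shape}, "
            f"observed {observed.shape} must agree"
        )


def masked_bce_loss(probabilities: Tensor, labels: np.ndarray, observed: np.ndarray):
    """Binary cross entropy over observed cells only.

    Per-task loss is the mean over that task's observed cells (0 when a task
    has none); the total is the sum of per-task losses.  Returns
    ``(total, per_task)`` where ``per_task`` is a (T,) Tensor.
    """
    probabilities = probabilities if isinstance(probabilities, Tensor) else Tensor(probabilities)
    labels = np.asarray(labels, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    _check_loss_shapes(probabilities, labels, observed)
    p = probabilities.clip(1e-12, 1.0 - 1e-12)
    cell = -(Tensor(labels) * p.log() + Tensor(1.0 - labels) * (1.0 - p).log())
    cell = cell * Tensor(observed)
    counts = np.maximum(observed.sum(axis=0), 1.0)
    per_task = cell.sum(axis=0) * Tensor(1.0 / counts)
    return per_task.sum(), per_task


def masked_mse_loss(predictions: Tensor, targets: np.ndarray, observed: np.ndarray):
    """Mean squared error over observed cells (same contract as the BCE loss)."""
    predictions = predictions if isinstance(predictions, Tensor) else Tensor(predictions)
    targets = np.asarray(targets, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    _check_loss_shapes(predictions, targets, observed)
    diff = (predictions - Tensor(targets)) * Tensor(observed)
    counts = np.maximum(observed.sum(axis=0), 1.0)
    per_task = (diff * diff).sum(axis=0) * Tensor(1.0 / counts)
    return per_task.sum(), per_task


# ---------------------------------------------------------------------------
# gradient surgery
# ---------------------------------------------------------------------------

def pcgrad(grads, rng: np.random.Generator, reduce: str = "sum") -> np.ndarray:
    """Projecting-conflicting-gradients combination of per-task gradients.

    Tasks are visited in a random order; for each task the other tasks are
    also visited in a random order, and whenever the running gradient
    conflicts with another task's raw gradient (negative dot product) its
    component along that gradient is removed.  The projected gradients are
    summed (or averaged with ``reduce='mean'``).
    """
    if isinstance(grads, GradientSet):
        vectors = [np.asarray(v, dtype=np.float64) for v in grads.vectors]
    else:
        vectors = [np.asarray(v, dtype=np.float64) for v in grads]
    if not vectors:
        raise LengthMismatch("need at least one gradient")
    length = vectors[0].shape[0]
    if any(v.shape != (length,) for v in vectors):
        raise LengthMismatch("gradient vectors must share one length")
    n_tasks = len(vectors)
    combined = np.zeros(length)
    for i in rng.permutation(n_tasks):
        g_pc = vectors[i].copy()
        for j in rng.permutation(n_tasks):
            if j == i:
                continue
            g_j = vectors[j]
            denom = g_j @ g_j
            if denom <= 0.0:
                continue
            dot = g_pc @ g_j
            if dot < 0.0:
                g_pc = g_pc - (dot / denom) * g_j
        combined += g_pc
    if reduce == "mean":
        combined /= n_tasks
    return combined


# ---------------------------------------------------------------------------
# dataset merging
# ---------------------------------------------------------------------------

def merge_datasets(datasets, splits=None):
    """Union datasets by canonical SMILES into one multi-task dataset.

    Task columns are concatenated (names uniquified when they collide);
    labels are carried where defined and masked elsewhere.  When per-source
    ``splits`` are given, a merged :class:`SplitIndices` is returned as well;
    a molecule appearing in different subsets across sources is assigned to
    the most held-out one (test > val > train), which also resolves
    train/test conflicts.
    """
    if not datasets:
        raise EmptyDataset("no datasets to merge")
    task_names: list = []
    for ds in datasets:
        for t in ds.task_names:
            name = t
            k = 1
            while name in task_names:
                k += 1
                name = f"{t}_{k}"
            task_names.append(name)

    index: dict[str, int] = {}
    molecules: list = []
    for ds in datasets:
        for mol in ds.molecules:
            if mol.smiles not in index:
                index[mol.smiles] = len(molecules)
                molecules.append(mol)
    m_total, t_total = len(molecules), len(task_names)
    labels = np.zeros((m_total, t_total))
    observed = np.zeros((m_total, t_total))
    membership = np.full(m_total, -1)  # 0 train, 1 val, 2 test (max wins)
    col = 0
    log = RecoveryLog()
    for src, ds in enumerate(datasets):
        rows = [index[m.smiles] for m in ds.molecules]
        t = ds.n_tasks
        labels[rows, col : col + t] = np.where(ds.observed > 0, ds.labels, labels[rows, col : col + t])
        observed[rows, col : col + t] = np.maximum(observed[rows, col : col + t], ds.observed)
        col += t
        log.total += ds.recovery_log.total
        log.parsed += ds.recovery_log.parsed
        log.embedded += ds.recovery_log.embedded
        log.dropped += ds.recovery_log.dropped
        log.dropped_smiles.extend(ds.recovery_log.dropped_smiles)
        if splits is not None:
            sp = splits[src]
            for rank, idxs in enumerate((sp.train, sp.val, sp.test)):
                for i in idxs:
                    row = index[ds.molecules[int(i)].smiles]
                    membership[row] = max(membership[row], rank)
    merged = LabeledDataset(molecules, labels, observed, task_names, log)
    if splits is None:
        return merged
    merged_splits = SplitIndices(
        train=np.nonzero(membership == 0)[0],
        val=np.nonzero(membership == 1)[0],
        test=np.nonzero(membership == 2)[0],
    )
    return merged, merged_splits


# ---------------------------------------------------------------------------
# optimizer and loop
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def predict_dataset(model: DualBranchModel, prepared: list, indices) -> np.ndarray:
    """Probability matrix for the given molecule indices (no gradients kept)."""
    rows = []
    for i in indices:
        probs, _ = model.forward_prepared(prepared[int(i)])
        rows.append(probs.data.copy())
    return np.asarray(rows)


def _loss_fn(config: TrainConfig):
    return masked_bce_loss if config.loss == "bce" else masked_mse_loss


def train(
    model: DualBranchModel,
    dataset: LabeledDataset,
    splits: SplitIndices,
    config: TrainConfig,
    prepared: list | None = None,
):
    """Fit the model; returns ``(params, history)``.

    Each step runs the forward pass on one mixed batch, computes per-task
    masked losses, and either backpropagates their sum or — with
    ``use_pcgrad`` and at least two tasks — computes per-task gradients,
    applies gradient surgery, and hands the combined gradient to Adam.
    The best-validation-AUROC parameters are restored at the end when a
    validation split is available.
    """
    if len(splits.train) == 0:
        raise EmptyDataset("empty training split")
    if config.mode == "MTL" and dataset.n_tasks < 2:
        raise ConfigError("MTL mode requires at least two tasks")
    rng = np.random.default_rng(config.seed)
    if prepared is None:
        prepared = [model.prepare_molecule(m) for m in dataset.molecules]
    loss_fn = _loss_fn(config)
    optimizer = Adam(model.params, lr=config.learning_rate)
    history = TrainingHistory()
    best_val, best_state, since_best = -np.inf, None, 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(splits.train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = splits.train[order[start : start + config.batch_size]]
            probs = stack([model.forward_prepared(prepared[int(i)])[0] for i in batch], axis=0)
            total, per_task = loss_fn(probs, dataset.labels[batch], dataset.observed[batch])
            if not np.isfinite(total.data):
                raise NonFiniteLoss(f"loss {total.data} at epoch {epoch}")
            if config.use_pcgrad and dataset.n_tasks >= 2:
                vectors = []
                for t in range(dataset.n_tasks):
                    model.zero_grad()
                    onehot = np.zeros(dataset.n_tasks)
                    onehot[t] = 1.0
                    (per_task * Tensor(onehot)).sum().backward()
                    vectors.append(model.flat_grad())
                combined = pcgrad(vectors, rng, reduce=config.pcgrad_reduce)
                model.set_flat_grad(combined)
            else:
                model.zero_grad()
                total.backward()
            optimizer.step()
            epoch_loss += float(total.data)
            n_batches += 1
        history.epoch.append(epoch)
        history.train_loss.append(epoch_loss / max(n_batches, 1))

        if len(splits.val) > 0:
            val_probs = predict_dataset(model, prepared, splits.val)
            val_total, _ = loss_fn(
                Tensor(val_probs), dataset.labels[splits.val], dataset.observed[splits.val]
            )
            history.val_loss.append(float(val_total.data))
            try:
                _, mean_auroc = _auroc_from_probs(
                    val_probs, dataset.labels[splits.val], dataset.observed[splits.val], dataset.task_names
                )
            except NoDefinedTask:
                mean_auroc = np.nan
            history.val_auroc.append(mean_auroc)
            if np.isfinite(mean_auroc) and mean_auroc > best_val:
                best_val, best_state, since_best = mean_auroc, model.state_dict(), 0
            else:
                since_best += 1
                if config.patience is not None and since_best > config.patience:
                    break
        else:
            history.val_loss.append(np.nan)
            history.val_auroc.append(np.nan)

    if best_state is not None:
        model.load_state_dict(best_state)
    return model.params, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _auroc_from_probs(probs: np.ndarray, labels: np.ndarray, observed: np.ndarray, task_names):
    per_task = {}
    defined = []
    for t, name in enumerate(task_names):
        mask = observed[:, t] > 0
        y, s = labels[mask, t], probs[mask, t]
        if mask.sum() == 0 or len(np.unique(y)) < 2:
            warnings.warn(f"AUROC undefined for task {name!r} (single class)", stacklevel=2)
            per_task[name] = None
            continue
        auc = float(roc_auc_score(y, s))
        per_task[name] = auc
        defined.append(auc)
    if not defined:
        raise NoDefinedTask("AUROC undefined for every task")
    return per_task, float(np.mean(defined))


def evaluate_auroc(model: DualBranchModel, dataset: LabeledDataset, indices, prepared: list | None = None):
    """Per-task AUROC over observed cells + mean over defined tasks."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise EmptyDataset("empty evaluation split")
    if prepared is None:
        prepared = {int(i): model.prepare_molecule(dataset.molecules[int(i)]) for i in indices}
        probs = np.asarray([model.forward_prepared(prepared[int(i)])[0].data for i in indices])
    else:
        probs = predict_dataset(model, prepared, indices)
    return _auroc_from_probs(
        probs, dataset.labels[indices], dataset.observed[indices], dataset.task_names
    )
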