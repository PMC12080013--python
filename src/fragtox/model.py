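"""Dual-branch molecular network: graph-augmented transformer + E(3)-equivariant GNN.

The atom branch reads the heavy-atom graph (descriptor features, bond
adjacency, pairwise 2D depiction distances, 3D conformer coordinates); the
fragment branch reads each of the three fragment views through one shared
set of parameters.  Each branch runs

1. a transformer stack whose per-head attention is a convex combination of
   scaled dot-product attention, a row-softmaxed negative 2D distance
   matrix, and the row-normalized adjacency matrix
   (``P = lam_attn*P_attn + lam_dist*D' + lam_adj*A'``), then
2. an equivariant graph convolution (EGCL) stack over a k-nearest-neighbor
   graph of the 3D coordinates: messages are functions of endpoint features
   and squared distances, and coordinates are updated along weighted
   difference vectors, then
3. a permutation-invariant readout (mean over nodes).

The three fragment-view embeddings are fused by a convex combination and
the head applies a linear map + sigmoid over
``concat(atom embedding, fused fragment embedding, ECFP)``.  Because 3D
coordinates enter only through pairwise distances and the updated
coordinates never reach the readout, predictions are invariant under
rotations, translations and reflections of the conformer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, layer_norm, silu, softmax
from .errors import ConfigError, ShapeMismatch
from .fragments import FragmentationMethod, FragmentGraph, build_fragment_graph, fragment_all_views
from .molio import Molecule

__all__ = [
    "TransformerConfig",
    "EgnnConfig",
    "FusionConfig",
    "BranchInput",
    "AttentionRecord",
    "knn_graph",
    "attention_layer",
    "egcl_layer",
    "encode_branch",
    "fuse_fragment_embeddings",
    "predict",
    "DualBranchModel",
]


def _check_simplex(*lams, what: str) -> None:
    if any(l < 0 for l in lams) or abs(sum(lams) - 1.0) > 1e-8:
        raise ConfigError(f"{what} weights must be non-negative and sum to 1, got {lams}")


@dataclass(frozen=True)
class TransformerConfig:
    """Attention stack: ``nf`` must be divisible by ``n_head`` (d_k = nf/n_head)."""

    n_head: int = 4
    nf: int = 32
    n_layers: int = 1
    lambda_attn: float = 1.0 / 3.0
    lambda_dist: float = 1.0 / 3.0
    lambda_adj: float = 1.0 / 3.0

    def __post_init__(self):
        if self.nf % self.n_head != 0:
            raise ConfigError(f"nf={self.nf} not divisible by n_head={self.n_head}")
        _check_simplex(self.lambda_attn, self.lambda_dist, self.lambda_adj, what="attention")


@dataclass(frozen=True)
class EgnnConfig:
    """EGCL stack; ``coord_scale`` is the constant scaling positional updates."""

    n_layers: int = 2
    k_neighbors: int = 5
    hidden_dim: int = 32
    coord_scale: float = 0.1

    def __post_init__(self):
        if self.k_neighbors < 1 or self.n_layers < 1 or self.hidden_dim < 1:
            raise ConfigError("EGNN config fields must be positive")


@dataclass(frozen=True)
class FusionConfig:
    """Convex weights for the BRICS / Murcko / functional-group views."""

    lambda_b: float = 1.0 / 3.0
    lambda_m: float = 1.0 / 3.0
    lambda_f: float = 1.0 / 3.0

    def __post_init__(self):
        _check_simplex(self.lambda_b, self.lambda_m, self.lambda_f, what="fusion")


@dataclass(frozen=True)
class BranchInput:
    """Raw per-graph arrays consumed by one branch."""

    node_features: np.ndarray  # (N, n_in)
    adjacency: np.ndarray  # (N, N)
    distances2d: np.ndarray  # (N, N)
    coords3d: np.ndarray  # (N, 3)

    def __post_init__(self):
        n = self.node_features.shape[0]
        if self.adjacency.shape != (n, n) or self.distances2d.shape != (n, n):
            raise ShapeMismatch("adjacency/distance matrices must be N x N")
        if self.coords3d.shape != (n, 3):
            raise ShapeMismatch("coords3d must be N x 3")


@dataclass
class AttentionRecord:
    """Per-layer combined attention matrices, each of shape (n_head, N, N)."""

    matrices: list = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.matrices)


# ---------------------------------------------------------------------------
# constant (parameter-free) preprocessing
# ---------------------------------------------------------------------------

def row_normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Rows divided by their sums; isolated nodes fall back to self-weight 1."""
    a = np.asarray(adjacency, dtype=np.float64).copy()
    sums = a.sum(axis=1)
    out = np.zeros_like(a)
    for i, s in enumerate(sums):
        if s > 0:
            out[i] = a[i] / s
        else:
            out[i, i] = 1.0
    return out


def distance_softmax(distances: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the negative distance matrix."""
    d = -np.asarray(distances, dtype=np.float64)
    d = d - d.max(axis=1, keepdims=True)
    e = np.exp(d)
    return e / e.sum(axis=1, keepdims=True)


def knn_graph(coords3d: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized k-nearest-neighbor adjacency (ties broken by index)."""
    c = np.asarray(coords3d, dtype=np.float64)
    n = c.shape[0]
    adj = np.zeros((n, n))
    if n <= 1:
        return adj
    dist = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    kk = min(int(k), n - 1)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        adj[i, order[:kk]] = 1.0
    return np.maximum(adj, adj.T)


@dataclass
class PreparedBranch:
    """Parameter-independent tensors for one graph, computed once."""

    n: int
    features: Tensor  # (N, n_in)
    a_norm: Tensor  # (N, N) row-normalized adjacency
    d_soft: Tensor  # (N, N) softmax(-D) rows
    a_knn: np.ndarray  # (N, N) binary
    coords3d: Tensor  # (N, 3)


def prepare_branch(inp: BranchInput, e_config: EgnnConfig) -> PreparedBranch:
    return PreparedBranch(
        n=inp.node_features.shape[0],
        features=Tensor(inp.node_features),
        a_norm=Tensor(row_normalized_adjacency(inp.adjacency)),
        d_soft=Tensor(distance_softmax(inp.distances2d)),
        a_knn=knn_graph(inp.coords3d, e_config.k_neighbors),
        coords3d=Tensor(inp.coords3d),
    )


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in: int, fan_out: int, scale: float = 1.0) -> Tensor:
    std = scale * np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, std, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


def init_branch_params(rng, prefix: str, n_in: int, t_cfg: TransformerConfig, e_cfg: EgnnConfig) -> dict:
    nf, hid = t_cfg.nf, e_cfg.hidden_dim
    p = {
        f"{prefix}.embed.W": _glorot(rng, n_in, nf),
        f"{prefix}.embed.b": _zeros(nf),
    }
    for l in range(t_cfg.n_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{prefix}.t{l}.{name}"] = _glorot(rng, nf, nf)
        for name in ("bq", "bk", "bv", "bo"):
            p[f"{prefix}.t{l}.{name}"] = _zeros(nf)
        p[f"{prefix}.t{l}.ln1.g"] = _ones(nf)
        p[f"{prefix}.t{l}.ln1.b"] = _zeros(nf)
        p[f"{prefix}.t{l}.ffn.W1"] = _glorot(rng, nf, 2 * nf)
        p[f"{prefix}.t{l}.ffn.b1"] = _zeros(2 * nf)
        p[f"{prefix}.t{l}.ffn.W2"] = _glorot(rng, 2 * nf, nf)
        p[f"{prefix}.t{l}.ffn.b2"] = _zeros(nf)
        p[f"{prefix}.t{l}.ln2.g"] = _ones(nf)
        p[f"{prefix}.t{l}.ln2.b"] = _zeros(nf)
    for l in range(e_cfg.n_layers):
        p[f"{prefix}.e{l}.We1"] = _glorot(rng, 2 * nf + 2, hid)
        p[f"{prefix}.e{l}.be1"] = _zeros(hid)
        p[f"{prefix}.e{l}.We2"] = _glorot(rng, hid, hid)
        p[f"{prefix}.e{l}.be2"] = _zeros(hid)
        p[f"{prefix}.e{l}.Wh1"] = _glorot(rng, nf + hid, hid)
        p[f"{prefix}.e{l}.bh1"] = _zeros(hid)
        p[f"{prefix}.e{l}.Wh2"] = _glorot(rng, hid, nf)
        p[f"{prefix}.e{l}.bh2"] = _zeros(nf)
        if l < e_cfg.n_layers - 1:
            # the last layer's updated coordinates would never be read, so it
            # performs a feature-only update and carries no coordinate weights
            p[f"{prefix}.e{l}.Wx"] = _glorot(rng, hid, 1, scale=1e-2)
    return p


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def attention_layer(
    h: Tensor,
    a_norm: Tensor,
    d_soft: Tensor,
    params: dict,
    prefix: str,
    layer: int,
    config: TransformerConfig,
):
    """One transformer block with graph-augmented attention.

    Returns the updated node features and the combined per-head attention
    matrix ``P_weighted`` (detached, for interpretation).
    """
    n = h.shape[0]
    nh, nf = config.n_head, config.nf
    dk = nf // nh
    g = lambda name: params[f"{prefix}.t{layer}.{name}"]

    def heads(x: Tensor) -> Tensor:
        return x.reshape(n, nh, dk).transpose((1, 0, 2))  # (nh, N, dk)

    q = heads(h @ g("Wq") + g("bq"))
    k = heads(h @ g("Wk") + g("bk"))
    v = heads(h @ g("Wv") + g("bv"))
    p_attn = softmax(q @ k.transpose((0, 2, 1)) * (1.0 / np.sqrt(dk)), axis=-1)
    p_weighted = (
        config.lambda_attn * p_attn
        + config.lambda_dist * d_soft
        + config.lambda_adj * a_norm
    )
    out = (p_weighted @ v).transpose((1, 0, 2)).reshape(n, nf) @ g("Wo") + g("bo")
    h = layer_norm(h + out, g("ln1.g"), g("ln1.b"))
    ffn = silu(h @ g("ffn.W1") + g("ffn.b1")) @ g("ffn.W2") + g("ffn.b2")
    h = layer_norm(h + ffn, g("ln2.g"), g("ln2.b"))
    return h, p_weighted.data.copy()


def egcl_layer(
    h: Tensor,
    c: Tensor,
    a_knn: np.ndarray,
    params: dict,
    prefix: str,
    layer: int,
    config: EgnnConfig,
    update_coords: bool = True,
):
    """One equivariant graph convolution: invariant features, covariant coords.

    With ``update_coords=False`` the coordinates pass through unchanged (used
    for the final stacked layer, whose updated coordinates nothing reads).
    """
    n = h.shape[0]
    nf = h.shape[1]
    g = lambda name: params[f"{prefix}.e{layer}.{name}"]
    mask = Tensor(a_knn[:, :, None])
    expand = Tensor(np.ones((n, n, 1)))

    ci = c.reshape(n, 1, 3)
    cj = c.reshape(1, n, 3)
    diff = ci - cj  # (N, N, 3) by broadcasting
    d2 = (diff * diff).sum(axis=-1, keepdims=True)  # (N, N, 1)
    hi = h.reshape(n, 1, nf) * expand
    hj = h.reshape(1, n, nf) * expand
    edge_in = concat([hi, hj, d2, mask], axis=-1)
    m = silu(silu(edge_in @ g("We1") + g("be1")) @ g("We2") + g("be2"))  # (N, N, hid)
    m_i = (m * mask).sum(axis=1)  # (N, hid)
    h_out = silu(concat([h, m_i], axis=-1) @ g("Wh1") + g("bh1")) @ g("Wh2") + g("bh2")
    if not update_coords:
        return h_out, c
    w_x = m @ g("Wx")  # (N, N, 1)
    c_out = c + config.coord_scale * (diff * w_x * mask).sum(axis=1)
    return h_out, c_out


def encode_branch(
    prep: PreparedBranch,
    params: dict,
    prefix: str,
    t_config: TransformerConfig,
    e_config: EgnnConfig,
    readout: str = "mean",
):
    """Transformer stack -> EGCL stack -> node readout; returns (embedding, record)."""
    record = AttentionRecord()
    h = prep.features @ params[f"{prefix}.embed.W"] + params[f"{prefix}.embed.b"]
    for l in range(t_config.n_layers):
        h, p_w = attention_layer(h, prep.a_norm, prep.d_soft, params, prefix, l, t_config)
        record.matrices.append(p_w)
    c = prep.coords3d
    for l in range(e_config.n_layers):
        h, c = egcl_layer(
            h, c, prep.a_knn, params, prefix, l, e_config,
            update_coords=l < e_config.n_layers - 1,
        )
    if readout == "mean":
        emb = h.mean(axis=0)
    elif readout == "sum":
        emb = h.sum(axis=0)
    else:
        raise ConfigError(f"unknown readout {readout!r}")
    return emb, record


def fuse_fragment_embeddings(e_brics: Tensor, e_murcko: Tensor, e_fg: Tensor, config: FusionConfig) -> Tensor:
    """Convex combination of the three fragment-view embeddings."""
    if not (e_brics.shape == e_murcko.shape == e_fg.shape):
        raise ShapeMismatch("fragment-view embeddings must share a width")
    return config.lambda_b * e_brics + config.lambda_m * e_murcko + config.lambda_f * e_fg


def predict(e_atom: Tensor, e_frag: Tensor, ecfp: np.ndarray, params: dict, n_tasks: int) -> Tensor:
    """Linear head + sigmoid over concat(atom, fragment, ECFP); (T,) probabilities."""
    x = concat([e_atom, e_frag, Tensor(np.asarray(ecfp, dtype=np.float64))], axis=0)
    w = params["head.W"]
    if x.shape[0] != w.shape[0]:
        raise ShapeMismatch(f"head expects width {w.shape[0]}, got {x.shape[0]}")
    logits = x.reshape(1, -1) @ w + params["head.b"]
    return logits.sigmoid().reshape(n_tasks)


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

_VIEWS = (
    FragmentationMethod.BRICS,
    FragmentationMethod.MURCKO,
    FragmentationMethod.FUNCTIONAL_GROUP,
)


@dataclass
class PreparedMolecule:
    """Constant tensors for one molecule across the atom and fragment branches."""

    atom: PreparedBranch
    views: dict  # FragmentationMethod -> PreparedBranch
    ecfp: np.ndarray


class DualBranchModel:
    """Atom-level + fragment-level toxicity predictor.

    Parameters are a flat name -> Tensor dict; the fragment branch shares one
    parameter set across the three fragmentation views, the atom branch has
    its own, and a linear head maps the concatenated embeddings + ECFP to
    per-task probabilities.
    """

    def __init__(
        self,
        n_atom_features: int,
        n_tasks: int,
        t_config: TransformerConfig | None = None,
        e_config: EgnnConfig | None = None,
        fusion: FusionConfig | None = None,
        ecfp_bits: int = 1024,
        readout: str = "mean",
        seed: int = 0,
    ):
        self.n_atom_features = int(n_atom_features)
        self.n_tasks = int(n_tasks)
        self.t_config = t_config or TransformerConfig()
        self.e_config = e_config or EgnnConfig()
        self.fusion = fusion or FusionConfig()
        self.ecfp_bits = int(ecfp_bits)
        self.readout = readout
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.params = {}
        self.params.update(init_branch_params(rng, "atom", n_atom_features, self.t_config, self.e_config))
        self.params.update(init_branch_params(rng, "frag", n_atom_features, self.t_config, self.e_config))
        head_in = 2 * self.t_config.nf + self.ecfp_bits
        self.params["head.W"] = _glorot(rng, head_in, n_tasks)
        self.params["head.b"] = _zeros(n_tasks)

    # -- data preparation ---------------------------------------------------
    def prepare_molecule(self, mol: Molecule, frag_graphs: dict | None = None) -> PreparedMolecule:
        if frag_graphs is None:
            frag_graphs = {
                method: build_fragment_graph(mol, assignment)
                for method, assignment in fragment_all_views(mol).items()
            }
        atom_inp = BranchInput(
            node_features=mol.atom_features,
            adjacency=mol.bond_adjacency,
            distances2d=np.linalg.norm(
                mol.coords2d[:, None, :] - mol.coords2d[None, :, :], axis=-1
            ),
            coords3d=mol.coords3d,
        )
        views = {}
        for method in _VIEWS:
            fg: FragmentGraph = frag_graphs[method]
            views[method] = prepare_branch(
                BranchInput(fg.frag_features, fg.frag_adjacency, fg.frag_distances2d, fg.frag_coords3d),
                self.e_config,
            )
        ecfp = mol.ecfp
        if ecfp.shape[0] != self.ecfp_bits:
            raise ShapeMismatch(f"model expects {self.ecfp_bits}-bit ECFP, got {ecfp.shape[0]}")
        return PreparedMolecule(prepare_branch(atom_inp, self.e_config), views, ecfp)

    # -- forward ------------------------------------------------------------
    def forward_prepared(self, pm: PreparedMolecule):
        e_atom, rec_atom = encode_branch(
            pm.atom, self.params, "atom", self.t_config, self.e_config, self.readout
        )
        frag_embs, records = {}, {"atom": rec_atom}
        for method in _VIEWS:
            emb, rec = encode_branch(
                pm.views[method], self.params, "frag", self.t_config, self.e_config, self.readout
            )
            frag_embs[method] = emb
            records[method.value] = rec
        e_frag = fuse_fragment_embeddings(
            frag_embs[FragmentationMethod.BRICS],
            frag_embs[FragmentationMethod.MURCKO],
            frag_embs[FragmentationMethod.FUNCTIONAL_GROUP],
            self.fusion,
        )
        probs = predict(e_atom, e_frag, pm.ecfp, self.params, self.n_tasks)
        return probs, records

    def forward(self, mol: Molecule, frag_graphs: dict | None = None):
        """Per-task probability Tensor + attention records for one molecule."""
        return self.forward_prepared(self.prepare_molecule(mol, frag_graphs))

    def predict_proba(self, mol: Molecule) -> np.ndarray:
        probs, _ = self.forward(mol)
        return probs.data.copy()

    # -- parameter utilities ------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def param_names(self) -> list:
        return sorted(self.params)

    def flat_grad(self) -> np.ndarray:
        """Current gradients flattened in sorted-name order (zeros if unset)."""
        parts = []
        for name in self.param_names():
            p = self.params[name]
            parts.append((p.grad if p.grad is not None else np.zeros_like(p.data)).ravel())
        return np.concatenate(parts)

    def set_flat_grad(self, vec: np.ndarray) -> None:
        offset = 0
        for name in self.param_names():
            p = self.params[name]
            size = p.data.size
            p.grad = vec[offset : offset + size].reshape(p.data.shape).copy()
            offset += size
        if offset != vec.size:
            raise ShapeMismatch("flat gradient length mismatch")

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- persistence --------------------------------------------------------
    def save(self, path: str) -> None:
        """Write parameters (`.npz`) and a JSON config sidecar (`.json`)."""
        np.savez(path, **self.state_dict())
        config = {
            "n_atom_features": self.n_atom_features,
            "n_tasks": self.n_tasks,
            "t_config": asdict(self.t_config),
            "e_config": asdict(self.e_config),
            "fusion": asdict(self.fusion),
            "ecfp_bits": self.ecfp_bits,
            "readout": self.readout,
            "seed": self.seed,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(config, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "DualBranchModel":
        with open(str(path) + ".json") as fh:
            config = json.load(fh)
        model = cls(
            n_atom_features=config["n_atom_features"],
            n_tasks=config["n_tasks"],
            t_config=TransformerConfig(**config["t_config"]),
            e_config=EgnnConfig(**config["e_config"]),
            fusion=FusionConfig(**config["fusion"]),
            ecfp_bits=config["ecfp_bits"],
            readout=config["readout"],
            seed=config["seed"],
        )
        archive = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        model.load_state_dict({k: archive[k] for k in archive.files})
        return model


def forward(mol: Molecule, frag_graphs: dict, model: DualBranchModel):
    """Functional alias for :meth:`DualBranchModel.forward`."""
    return model.forward(mol, frag_graphs)
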