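"""Directed message-passing network over condensed reaction graphs.

Messages live on directed edges.  Initial states are a linear map of
e_vw = cat(x_v, bond_vw); the update for edge v->w aggregates incoming
states of v excluding the reverse edge,

    h^{t+1}_vw = tau(h^0_vw + W_h * sum_{k in N(v) \\ {w}} h^t_kv),

after T steps atom embeddings are h_v = tau(W_0 cat(x_v, sum_k h^T_kv)),
pooled (mean by default) into a molecule vector that a feed-forward head
maps to the barrier height.

Auxiliary atom features (ml-QM columns, positional descriptors) can be
concatenated raw (route2_plain) or first embedded by a linear layer with
ReLU (route1_linear_relu), optionally followed by a single-head scaled
dot-product self-attention pass over the reaction's atoms with a residual
connection (route1_linear_relu_attention); the resulting block joins the
atom features either before message passing or after it, just ahead of
pooling.  Molecule-level extras are appended to the pooled vector.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gather, relu, segment_sum, softmax
from .reaction_graph import CondensedGraph, directed_edge_features

__all__ = [
    "ModelConfig",
    "FeatureWidths",
    "ModelState",
    "EmptyGraphError",
    "ConfigError",
    "init_params",
    "init_edge_states",
    "message_pass",
    "atom_embeddings",
    "pool",
    "embed_extra",
    "forward",
    "forward_batch",
    "save_state",
    "load_state",
]

ROUTES = ("none", "route2_plain", "route1_linear_relu", "route1_linear_relu_attention")
PLACEMENTS = ("before_mpnn", "after_mpnn")


class EmptyGraphError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    hidden_dim: int = 64
    depth: int = 3
    activation: str = "relu"
    dropout_mpnn: float = 0.0
    dropout_ffn: float = 0.0
    pooling: str = "mean"
    ffn_layers: int = 2
    ffn_hidden_dim: int = 64
    extra_route: str = "none"
    extra_placement: str = "before_mpnn"
    extra_embed_dim: int = 64

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.depth < 0 or self.ffn_layers < 1:
            raise ConfigError("hidden_dim > 0, depth >= 0, ffn_layers >= 1 required")
        if self.extra_route not in ROUTES:
            raise ConfigError(f"unknown extra_route {self.extra_route!r}")
        if self.extra_placement not in PLACEMENTS:
            raise ConfigError(f"unknown extra_placement {self.extra_placement!r}")
        if self.pooling not in ("mean", "sum"):
            raise ConfigError(f"unknown pooling {self.pooling!r}")


@dataclass
class FeatureWidths:
    atom: int
    bond: int
    atom_extra: int = 0
    mol_extra: int = 0


@dataclass
class ModelState:
    """Learnable arrays plus the shape/scaling metadata to rebuild them."""

    config: ModelConfig
    widths: FeatureWidths
    params: dict[str, np.ndarray]
    target_mean: float = 0.0
    target_std: float = 1.0

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            widths=self.widths,
            params={k: v.copy() for k, v in self.params.items()},
            target_mean=self.target_mean,
            target_std=self.target_std,
        )


def _processed_extra_width(config: ModelConfig, widths: FeatureWidths) -> int:
    if config.extra_route == "none" or widths.atom_extra == 0:
        return 0
    if config.extra_route == "route2_plain":
        return widths.atom_extra
    return config.extra_embed_dim


def _layer_sizes(config: ModelConfig, widths: FeatureWidths) -> dict[str, tuple[int, int]]:
    h = config.hidden_dim
    pe = _processed_extra_width(config, widths)
    atom_in = widths.atom + (pe if config.extra_placement == "before_mpnn" else 0)
    sizes = {
        "W_i": (atom_in + widths.bond, h),
        "W_h": (h, h),
        "W_o": (atom_in + h, h),
    }
    if config.extra_route in ("route1_linear_relu", "route1_linear_relu_attention") and widths.atom_extra:
        sizes["W_e"] = (widths.atom_extra, config.extra_embed_dim)
        if config.extra_route == "route1_linear_relu_attention":
            d = config.extra_embed_dim
            sizes.update({"W_q": (d, d), "W_k": (d, d), "W_v": (d, d)})
    ffn_in = h + (pe if config.extra_placement == "after_mpnn" else 0) + widths.mol_extra
    dims = [ffn_in] + [config.ffn_hidden_dim] * (config.ffn_layers - 1) + [1]
    for i in range(config.ffn_layers):
        sizes[f"W_f{i}"] = (dims[i], dims[i + 1])
    return sizes


def init_params(config: ModelConfig, widths: FeatureWidths, seed: int = 0) -> ModelState:
    """Seeded uniform fan-in initialisation of every linear map (with bias)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, (fan_in, fan_out) in _layer_sizes(config, widths).items():
        bound = 1.0 / np.sqrt(max(fan_in, 1))
        params[name] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        params["b" + name[1:]] = rng.uniform(-bound, bound, size=fan_out)
    return ModelState(config=config, widths=widths, params=params)


# ---------------------------------------------------------------------------
# batched autodiff forward pass
# ---------------------------------------------------------------------------


@dataclass
class GraphBatch:
    """Block-diagonal concatenation of reaction graphs.

    Atom rows are grouped per molecule (contiguous); directed edge ``e``
    and ``e ^ 1`` are mutual reverses.
    """

    x: np.ndarray  # (N, d_atom)
    bond: np.ndarray  # (E_dir, d_bond)
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    mol_index: np.ndarray  # (N,)
    mol_slices: list[tuple[int, int]]
    atom_extras: np.ndarray  # (N, k)
    mol_extras: np.ndarray  # (n_mols, km)
    targets: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.x.shape[0]

    @property
    def n_mols(self) -> int:
        return len(self.mol_slices)


def make_batch(records) -> GraphBatch:
    """Assemble a GraphBatch from EncodedReaction-like records (each with
    ``cgr``, ``atom_extras``, ``mol_extras`` and optional ``target``)."""
    xs, bonds, srcs, dsts, revs, mol_idx, slices = [], [], [], [], [], [], []
    aex, mex, targets = [], [], []
    a_off = e_off = 0
    for mi, rec in enumerate(records):
        cgr = rec.cgr
        src, dst, rev, _ = directed_edge_features(cgr)
        xs.append(cgr.atom_features)
        bonds.append(np.repeat(cgr.bond_features, 2, axis=0))
        srcs.append(src + a_off)
        dsts.append(dst + a_off)
        revs.append(rev + e_off)
        mol_idx.append(np.full(cgr.n_atoms, mi))
        slices.append((a_off, a_off + cgr.n_atoms))
        aex.append(rec.atom_extras)
        mex.append(rec.mol_extras)
        targets.append(np.nan if rec.target is None else rec.target)
        a_off += cgr.n_atoms
        e_off += 2 * cgr.n_edges
    return GraphBatch(
        x=np.concatenate(xs, axis=0),
        bond=np.concatenate(bonds, axis=0) if e_off else np.zeros((0, records[0].cgr.bond_features.shape[1])),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        rev=np.concatenate(revs),
        mol_index=np.concatenate(mol_idx),
        mol_slices=slices,
        atom_extras=np.concatenate(aex, axis=0),
        mol_extras=np.stack(mex),
        targets=np.asarray(targets, dtype=np.float64),
    )


def _dropout(t: Tensor, p: float, training: bool, rng) -> Tensor:
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


def _linear(x: Tensor, params: dict[str, Tensor], name: str) -> Tensor:
    return x @ params[name] + params["b" + name[1:]]


def _embed_extras_t(
    extras: Tensor, params: dict[str, Tensor], config: ModelConfig, mol_slices
) -> Tensor:
    if config.extra_route == "route2_plain":
        return extras
    e = relu(_linear(extras, params, "W_e"))
    if config.extra_route == "route1_linear_relu_attention":
        d = config.extra_embed_dim
        scale = 1.0 / np.sqrt(d)
        outs = []
        for a, b in mol_slices:
            idx = np.arange(a, b)
            em = gather(e, idx)
            q = _linear(em, params, "W_q")
            k = _linear(em, params, "W_k")
            v = _linear(em, params, "W_v")
            att = softmax((q @ k.T) * scale, axis=-1)
            outs.append(em + att @ v)
        e = concat(outs, axis=0)
    return e


def forward_batch(
    state: ModelState,
    batch: GraphBatch,
    training: bool = False,
    rng: np.random.Generator | None = None,
    params: dict[str, Tensor] | None = None,
) -> Tensor:
    """Scaled-target predictions for a batch, differentiable w.r.t. params."""
    config, widths = state.config, state.widths
    if batch.n_atoms == 0:
        raise EmptyGraphError("batch contains no atoms")
    if params is None:
        params = {k: Tensor(v, requires_grad=True) for k, v in state.params.items()}
    rng = rng or np.random.default_rng(0)

    x = Tensor(batch.x)
    use_extra = config.extra_route != "none" and widths.atom_extra > 0
    if use_extra and batch.atom_extras.shape[1] != widths.atom_extra:
        raise ConfigError(
            f"atom extras width {batch.atom_extras.shape[1]} != configured {widths.atom_extra}"
        )
    proc = None
    if use_extra:
        proc = _embed_extras_t(Tensor(batch.atom_extras), params, config, batch.mol_slices)
        if config.extra_placement == "before_mpnn":
            x = concat([x, proc], axis=1)

    n = batch.n_atoms
    if len(batch.src):
        e_vw = concat([gather(x, batch.src), Tensor(batch.bond)], axis=1)
        h0 = _linear(e_vw, params, "W_i")  # no activation at init
        h = h0
        for _ in range(config.depth):
            incoming = segment_sum(h, batch.dst, n)
            msg = gather(incoming, batch.src) - gather(h, batch.rev)
            h = relu(h0 + _linear(msg, params, "W_h"))
            h = _dropout(h, config.dropout_mpnn, training, rng)
        atom_sum = segment_sum(h, batch.dst, n)
    else:
        atom_sum = Tensor(np.zeros((n, config.hidden_dim)))

    q = concat([x, atom_sum], axis=1)
    hv = relu(_linear(q, params, "W_o"))
    hv = _dropout(hv, config.dropout_mpnn, training, rng)

    if use_extra and config.extra_placement == "after_mpnn":
        hv = concat([hv, proc], axis=1)

    hm = segment_sum(hv, batch.mol_index, batch.n_mols)
    if config.pooling == "mean":
        counts = np.array([b - a for a, b in batch.mol_slices], dtype=np.float64)
        hm = hm * Tensor((1.0 / counts)[:, None])

    if widths.mol_extra:
        if batch.mol_extras.shape[1] != widths.mol_extra:
            raise ConfigError("molecule extras width mismatch")
        hm = concat([hm, Tensor(batch.mol_extras)], axis=1)

    out = hm
    for i in range(config.ffn_layers):
        out = _linear(out, params, f"W_f{i}")
        if i < config.ffn_layers - 1:
            out = relu(out)
            out = _dropout(out, config.dropout_ffn, training, rng)
    return out.reshape(-1)


def predict(state: ModelState, records) -> np.ndarray:
    """Barrier predictions in kcal/mol (targets un-scaled)."""
    batch = make_batch(records)
    scaled = forward_batch(state, batch).data
    return scaled * state.target_std + state.target_mean


# ---------------------------------------------------------------------------
# operation-level surface (plain NumPy, batch of one)
# ---------------------------------------------------------------------------


def init_edge_states(cgr: CondensedGraph, state: ModelState) -> np.ndarray:
    """h^0_vw: linear map of the directed edge features, no activation."""
    _, _, _, feats = directed_edge_features(cgr)
    W, b = state.params["W_i"], state.params["b_i"]
    if feats.shape[1] != W.shape[0]:
        raise ConfigError(f"edge feature width {feats.shape[1]} != {W.shape[0]}")
    return feats @ W + b


def message_pass(cgr: CondensedGraph, states: np.ndarray, state: ModelState, T: int) -> np.ndarray:
    """Run T update steps from initial states; T=0 returns them unchanged."""
    src, dst, rev, _ = directed_edge_features(cgr)
    W, b = state.params["W_h"], state.params["b_h"]
    h0 = states
    h = states
    for _ in range(T):
        incoming = np.zeros((cgr.n_atoms, h.shape[1]))
        np.add.at(incoming, dst, h)
        msg = incoming[src] - h[rev]
        h = np.maximum(h0 + msg @ W + b, 0.0)
    return h


def atom_embeddings(cgr: CondensedGraph, final_states: np.ndarray, state: ModelState) -> np.ndarray:
    """h_v = tau(W_0 cat(x_v, sum of incoming final edge states))."""
    src, dst, rev, _ = directed_edge_features(cgr)
    h = state.config.hidden_dim
    incoming = np.zeros((cgr.n_atoms, h))
    if len(dst):
        np.add.at(incoming, dst, final_states)
    q = np.concatenate([cgr.atom_features, incoming], axis=1)
    W, b = state.params["W_o"], state.params["b_o"]
    if q.shape[1] != W.shape[0]:
        raise ConfigError(f"atom embedding input width {q.shape[1]} != {W.shape[0]}")
    return np.maximum(q @ W + b, 0.0)


def pool(atom_embedding: np.ndarray, mode: str = "mean") -> np.ndarray:
    if atom_embedding.shape[0] == 0:
        raise EmptyGraphError("cannot pool an empty graph")
    if mode == "mean":
        return atom_embedding.mean(axis=0)
    if mode == "sum":
        return atom_embedding.sum(axis=0)
    raise ConfigError(f"unknown pooling mode {mode!r}")


def embed_extra(extra_vectors: np.ndarray, config: ModelConfig, state: ModelState) -> np.ndarray:
    """Process one reaction's raw extra atom features per the configured route."""
    if config.extra_route == "none":
        raise ConfigError("embed_extra requires extra_route != none")
    n = extra_vectors.shape[0]
    t = _embed_extras_t(
        Tensor(extra_vectors),
        {k: Tensor(v) for k, v in state.params.items()},
        config,
        [(0, n)],
    )
    return t.data


@dataclass
class _Single:
    cgr: CondensedGraph
    atom_extras: np.ndarray
    mol_extras: np.ndarray
    target: float | None = None


def forward(
    cgr: CondensedGraph,
    extra: np.ndarray | None,
    positional: np.ndarray | None,
    config: ModelConfig,
    state: ModelState,
) -> float:
    """Predicted barrier (kcal/mol) for one reaction.

    ``extra`` and ``positional`` are per-atom matrices in CGR atom order;
    they are concatenated (extra first) into the model's auxiliary block.
    """
    blocks = [b for b in (extra, positional) if b is not None and b.size]
    atom_extras = (
        np.concatenate(blocks, axis=1) if blocks else np.zeros((cgr.n_atoms, 0))
    )
    if config.extra_route == "none" and atom_extras.shape[1]:
        raise ConfigError("extra features supplied but extra_route is 'none'")
    rec = _Single(cgr=cgr, atom_extras=atom_extras, mol_extras=cgr.mol_extra)
    return float(predict(state, [rec])[0])


# ---------------------------------------------------------------------------
# checkpoint archive: JSON config + named weight arrays
# ---------------------------------------------------------------------------


def save_state(state: ModelState, path) -> None:
    meta = {
        "config": asdict(state.config),
        "widths": asdict(state.widths),
        "target_mean": state.target_mean,
        "target_std": state.target_std,
        "param_names": sorted(state.params),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        for name, arr in state.params.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_state(path) -> ModelState:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        params = {
            name: np.load(io.BytesIO(zf.read(f"weights/{name}.npy")))
            for name in meta["param_names"]
        }
    return ModelState(
        config=ModelConfig(**meta["config"]),
        widths=FeatureWidths(**meta["widths"]),
        params=params,
        target_mean=meta["target_mean"],
        target_std=meta["target_std"],
    )
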