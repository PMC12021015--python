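"""The shared-weight dual-graph stability network.

Wild-type and mutant residue graphs are encoded by the *same* stack of
edge-weighted SAGE-style graph convolutions (a siamese arrangement), each
graph is mean-pooled to a fixed-length vector, the two vectors are combined
(concatenation by default, difference as an option), and a small fully
connected head regresses ddG in kcal/mol.  Because the two encoders share
parameters and pooling is length-independent, the same model handles
substitutions, multi-point mutations and indels of arbitrary size.

Each convolution computes ``h'_v = act(W_self h_v + W_neigh agg(v) + b)``
where ``agg`` is the weighted mean of neighbour states (contact
probabilities as weights) — the self term doubles as a skip connection —
optionally followed by L2 normalisation of the node state.

With ``combiner="diff"`` the head is applied antisymmetrically,
``y = (head(z) - head(-z))/2 + head(0)``, so swapping wild and mutant flips
the prediction around ``head(0)`` exactly (and exactly negates it once the
head biases are zero).  The default ``concat`` model has no such built-in
constraint; antisymmetry is then a property to be *learned* from
antisymmetrically augmented data.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .graphs import GraphSample, ProteinGraph

CONV_TYPES = ("sage_weighted", "graphconv_plain")
COMBINERS = ("concat", "diff")
HEAD_ACTIVATIONS = {"relu": ad.relu, "tanh": ad.tanh, "identity": lambda t: t}


@dataclass
class ModelConfig:
    """Architecture axes of the stability network."""

    conv_type: str = "sage_weighted"
    n_conv_layers: int = 2
    hidden_dim: int = 64
    use_edge_weights: bool = True
    share_weights: bool = True
    combiner: str = "concat"
    pooling: str = "mean"
    head_blocks: int = 2
    dropout: float = 0.0
    l2_normalize_nodes: bool = False
    head_activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_type not in CONV_TYPES:
            raise ValueError(f"conv_type must be one of {CONV_TYPES}")
        if self.combiner not in COMBINERS:
            raise ValueError(f"combiner must be one of {COMBINERS}")
        if self.pooling != "mean":
            raise ValueError("only mean pooling is supported")
        if self.hidden_dim <= 0 or self.n_conv_layers < 1 or self.head_blocks < 1:
            raise ValueError("hidden_dim, n_conv_layers and head_blocks must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.head_activation not in HEAD_ACTIVATIONS:
            raise ValueError(f"head_activation must be one of {sorted(HEAD_ACTIVATIONS)}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


ModelParams = dict[str, Tensor]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def encoder_prefixes(cfg: ModelConfig) -> tuple[str, str]:
    """Parameter prefixes for the wild and mutant encoder paths."""
    return ("enc", "enc") if cfg.share_weights else ("enc_w", "enc_m")


def init_params(cfg: ModelConfig, in_dim: int) -> ModelParams:
    """Initialise all parameters (Glorot weights, zero biases, unit gains)."""
    rng = np.random.default_rng(cfg.seed)
    params: ModelParams = {}

    def add_encoder(prefix: str) -> None:
        d_in = in_dim
        for layer in range(cfg.n_conv_layers):
            d_out = cfg.hidden_dim
            params[f"{prefix}.layer{layer}.W_self"] = Tensor(
                _glorot(rng, d_in, d_out), requires_grad=True
            )
            params[f"{prefix}.layer{layer}.W_neigh"] = Tensor(
                _glorot(rng, d_in, d_out), requires_grad=True
            )
            params[f"{prefix}.layer{layer}.b"] = Tensor(np.zeros(d_out), requires_grad=True)
            d_in = d_out

    for prefix in dict.fromkeys(encoder_prefixes(cfg)):
        add_encoder(prefix)

    d = 2 * cfg.hidden_dim if cfg.combiner == "concat" else cfg.hidden_dim
    for k in range(cfg.head_blocks):
        params[f"head.block{k}.W"] = Tensor(_glorot(rng, d, cfg.hidden_dim), requires_grad=True)
        params[f"head.block{k}.b"] = Tensor(np.zeros(cfg.hidden_dim), requires_grad=True)
        params[f"head.block{k}.ln_gain"] = Tensor(np.ones(cfg.hidden_dim), requires_grad=True)
        params[f"head.block{k}.ln_bias"] = Tensor(np.zeros(cfg.hidden_dim), requires_grad=True)
        d = cfg.hidden_dim
    params["head.out.W"] = Tensor(_glorot(rng, d, 1), requires_grad=True)
    params["head.out.b"] = Tensor(np.zeros(1), requires_grad=True)
    return params


def count_parameters(params: ModelParams, prefix: str = "") -> int:
    return sum(p.value.size for name, p in params.items() if name.startswith(prefix))


def zero_head_biases(params: ModelParams) -> None:
    """Zero every additive head parameter (biases and layer-norm shifts)."""
    for name, p in params.items():
        if name.startswith("head.") and (name.endswith(".b") or name.endswith(".ln_bias")):
            p.value[...] = 0.0


# ---------------------------------------------------------------------------
# aggregation operators and batching
# ---------------------------------------------------------------------------


def aggregation_matrix(g: ProteinGraph, cfg: ModelConfig) -> sp.csr_matrix:
    """Sparse operator A with (A h)_v = the layer's neighbour aggregate of v.

    ``sage_weighted``: weighted (or plain) mean over neighbours — rows of
    isolated nodes are empty, so their aggregate is the zero vector.
    ``graphconv_plain``: unweighted neighbour sum.
    """
    n = g.n_nodes
    if g.edges.size == 0:
        return sp.csr_matrix((n, n))
    rows = np.concatenate([g.edges[:, 0], g.edges[:, 1]])
    cols = np.concatenate([g.edges[:, 1], g.edges[:, 0]])
    if cfg.conv_type == "graphconv_plain":
        data = np.ones(rows.shape[0])
    elif cfg.use_edge_weights:
        data = np.concatenate([g.edge_weights, g.edge_weights]).astype(np.float64)
    else:
        data = np.ones(rows.shape[0])
    if cfg.conv_type == "sage_weighted":
        denom = np.bincount(rows, weights=data, minlength=n)
        data = data / denom[rows]
    mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    return mat.tocsr()


@dataclass
class PackedGraph:
    """One graph pre-packed for batching: features + aggregation operator."""

    x: np.ndarray
    agg: sp.csr_matrix
    n: int


def pack_graph(g: ProteinGraph, cfg: ModelConfig) -> PackedGraph:
    if g.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    return PackedGraph(x=g.node_features, agg=aggregation_matrix(g, cfg), n=g.n_nodes)


def _block_diag_csr(mats: Sequence[sp.csr_matrix]) -> sp.csr_matrix:
    data = np.concatenate([m.data for m in mats])
    indices_parts = []
    indptr_parts = [np.zeros(1, dtype=np.int64)]
    col_off = 0
    nnz_off = 0
    for m in mats:
        indices_parts.append(m.indices.astype(np.int64) + col_off)
        indptr_parts.append(m.indptr[1:].astype(np.int64) + nnz_off)
        col_off += m.shape[1]
        nnz_off += m.nnz
    n = col_off
    return sp.csr_matrix(
        (data, np.concatenate(indices_parts), np.concatenate(indptr_parts)), shape=(n, n)
    )


@dataclass
class GraphBatch:
    """Disjoint union of graphs with a segment mean-pooling operator."""

    x: np.ndarray  # (total_nodes, F)
    agg: sp.csr_matrix  # (total_nodes, total_nodes)
    pool: sp.csr_matrix  # (n_graphs, total_nodes)
    sizes: np.ndarray


def make_batch(packed: Sequence[PackedGraph]) -> GraphBatch:
    sizes = np.array([p.n for p in packed], dtype=np.int64)
    x = np.vstack([p.x for p in packed])
    agg = _block_diag_csr([p.agg for p in packed])
    total = int(sizes.sum())
    indptr = np.concatenate([[0], np.cumsum(sizes)])
    pool = sp.csr_matrix(
        (np.repeat(1.0 / sizes, sizes), np.arange(total), indptr),
        shape=(len(packed), total),
    )
    return GraphBatch(x=x, agg=agg, pool=pool, sizes=sizes)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def encode_batch(batch: GraphBatch, params: ModelParams, cfg: ModelConfig, prefix: str) -> Tensor:
    """Run the convolution stack and mean-pool each graph to one vector."""
    h = Tensor(batch.x)
    for layer in range(cfg.n_conv_layers):
        w_self = params[f"{prefix}.layer{layer}.W_self"]
        w_neigh = params[f"{prefix}.layer{layer}.W_neigh"]
        b = params[f"{prefix}.layer{layer}.b"]
        m = ad.spmm(batch.agg, h)
        h = ad.relu((h @ w_self) + (m @ w_neigh) + b)
        if cfg.l2_normalize_nodes:
            h = ad.l2_normalize_rows(h)
    return ad.spmm(batch.pool, h)


def _head(
    z: Tensor,
    params: ModelParams,
    cfg: ModelConfig,
    masks: list[np.ndarray] | None,
) -> Tensor:
    act = HEAD_ACTIVATIONS[cfg.head_activation]
    for k in range(cfg.head_blocks):
        z = (z @ params[f"head.block{k}.W"]) + params[f"head.block{k}.b"]
        z = ad.layer_norm_rows(z, params[f"head.block{k}.ln_gain"], params[f"head.block{k}.ln_bias"])
        z = act(z)
        if masks is not None:
            z = ad.mul(z, Tensor(masks[k]))
    return (z @ params["head.out.W"]) + params["head.out.b"]


def dropout_masks(
    cfg: ModelConfig, n_rows: int, rng: np.random.Generator
) -> list[np.ndarray] | None:
    """Inverted-dropout masks for the head blocks (training mode only)."""
    if cfg.dropout == 0.0:
        return None
    keep = 1.0 - cfg.dropout
    return [
        (rng.random((n_rows, cfg.hidden_dim)) < keep) / keep for _ in range(cfg.head_blocks)
    ]


def forward_pairs(
    wild: GraphBatch,
    mut: GraphBatch,
    params: ModelParams,
    cfg: ModelConfig,
    masks: list[np.ndarray] | None = None,
) -> Tensor:
    """Predicted ddG column vector for a batch of (wild, mutant) pairs."""
    pw, pm = encoder_prefixes(cfg)
    ew = encode_batch(wild, params, cfg, pw)
    em = encode_batch(mut, params, cfg, pm)
    if cfg.combiner == "concat":
        z = ad.concat_cols(ew, em)
        return _head(z, params, cfg, masks)
    # diff combiner: antisymmetrised head, y(z) = (h(z) - h(-z))/2 + h(0)
    z = ew - em
    h_pos = _head(z, params, cfg, masks)
    h_neg = _head(ad.scale(z, -1.0), params, cfg, masks)
    h_zero = _head(Tensor(np.zeros_like(z.value)), params, cfg, masks)
    return ad.scale(h_pos - h_neg, 0.5) + h_zero


def predict_ddg(
    wild: ProteinGraph, mut: ProteinGraph, params: ModelParams, cfg: ModelConfig
) -> float:
    """Inference-mode ddG prediction for a single wild/mutant graph pair."""
    if wild.feature_dim != mut.feature_dim:
        raise ValueError("wild and mutant graphs carry different feature dimensions")
    bw = make_batch([pack_graph(wild, cfg)])
    bm = make_batch([pack_graph(mut, cfg)])
    return float(forward_pairs(bw, bm, params, cfg, masks=None).value[0, 0])


def predict_many(
    samples: Sequence[GraphSample],
    params: ModelParams,
    cfg: ModelConfig,
    batch_size: int = 256,
) -> np.ndarray:
    """Vectorised inference over a list of :class:`GraphSample`."""
    preds = np.empty(len(samples))
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        bw = make_batch([pack_graph(s.wild, cfg) for s in chunk])
        bm = make_batch([pack_graph(s.mut, cfg) for s in chunk])
        preds[start : start + len(chunk)] = forward_pairs(bw, bm, params, cfg).value[:, 0]
    return preds


# ---------------------------------------------------------------------------
# single-graph reference operations (also used as test oracles elsewhere)
# ---------------------------------------------------------------------------


def weighted_mean_aggregate(
    node: int, g: ProteinGraph, h: np.ndarray, use_edge_weights: bool = True
) -> np.ndarray:
    """Weighted mean of neighbour feature rows; zero vector if isolated."""
    if h.shape[0] != g.n_nodes:
        raise ValueError("feature row count != node count")
    acc = np.zeros(h.shape[1])
    total = 0.0
    for (i, j), w in zip(g.edges, g.edge_weights):
        w = float(w) if use_edge_weights else 1.0
        if i == node:
            acc += w * h[j]
            total += w
        elif j == node:
            acc += w * h[i]
            total += w
    return acc / total if total > 0 else acc


def sage_layer(
    g: ProteinGraph,
    h: np.ndarray,
    w_self: np.ndarray,
    w_neigh: np.ndarray,
    b: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] = lambda x: x,
    use_edge_weights: bool = True,
    l2_normalize: bool = False,
) -> np.ndarray:
    """One SAGE-style convolution on a single graph (plain numpy)."""
    out = np.empty((g.n_nodes, np.atleast_2d(w_self).shape[-1]))
    ws = np.atleast_2d(w_self)
    wn = np.atleast_2d(w_neigh)
    for v in range(g.n_nodes):
        agg = weighted_mean_aggregate(v, g, h, use_edge_weights)
        out[v] = activation(h[v] @ ws + agg @ wn + b)
    if l2_normalize:
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        out = out / np.where(norms > 0, norms, 1.0)
    return out


def encode_graph(g: ProteinGraph, params: ModelParams, cfg: ModelConfig, prefix: str | None = None) -> np.ndarray:
    """Inference-mode graph embedding (mean-pooled final node states)."""
    if g.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    if prefix is None:
        prefix = encoder_prefixes(cfg)[0]
    batch = make_batch([pack_graph(g, cfg)])
    return encode_batch(batch, params, cfg, prefix).value[0]


# ---------------------------------------------------------------------------
# checkpoint IO (deterministic zip container: byte-identical for equal state)
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, params: ModelParams, cfg: ModelConfig, in_dim: int) -> None:
    meta = {"config": asdict(cfg), "in_dim": in_dim, "names": sorted(params)}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("meta.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, json.dumps(meta, sort_keys=True))
        for name in sorted(params):
            buf = io.BytesIO()
            np.save(buf, params[name].value)
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig, int]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        params = {
            name: Tensor(np.load(io.BytesIO(zf.read(name + ".npy"))), requires_grad=True)
            for name in meta["names"]
        }
    return params, ModelConfig(**meta["config"]), int(meta["in_dim"])
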