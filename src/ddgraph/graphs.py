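"""Residue graphs: contact-probability thresholding and node features.

A protein is represented as a weighted undirected graph whose nodes are
residues.  Node features come from a pluggable per-residue embedding
provider (a protein language model in production; one-hot encoding as the
built-in fallback), and edges from a symmetric residue contact-probability
matrix: pairs whose probability reaches the cutoff (default 0.1) become
edges, with the probability itself reused as the edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from .records import AMINO_ACIDS

DEFAULT_CUTOFF = 0.1

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class ContactMap:
    """Symmetric N x N matrix of residue-residue contact probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"contact map must be square, got {p.shape}")
        if not np.allclose(p, p.T, atol=1e-8):
            raise ValueError("contact map must be symmetric")
        if np.any(np.diag(p) != 0.0):
            raise ValueError("contact map must have a zero diagonal")
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("contact probabilities must lie in [0, 1]")
        self.probs = p

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class ProteinGraph:
    """Node features plus a weighted undirected edge set (i < j pairs)."""

    node_features: np.ndarray
    edges: np.ndarray  # (M, 2) int array, each row i < j
    edge_weights: np.ndarray  # (M,) floats in (0, 1]

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64).reshape(-1)
        if self.edges.shape[0] != self.edge_weights.shape[0]:
            raise ValueError("edges and edge_weights length mismatch")
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= self.n_nodes
        ):
            raise ValueError("edge index out of range")
        if np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must be stored as i < j pairs")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]

    def neighbor_lists(self) -> list[list[tuple[int, float]]]:
        """Adjacency as neighbor (index, weight) lists."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_nodes)]
        for (i, j), w in zip(self.edges, self.edge_weights):
            adj[i].append((int(j), float(w)))
            adj[j].append((int(i), float(w)))
        return adj


class EmbeddingProvider(Protocol):
    """Contract for per-residue feature sources: |seq| rows, fixed width."""

    dim: int

    def embed(self, seq: str) -> np.ndarray: ...


def one_hot_embed(seq: str) -> np.ndarray:
    """One-hot node features over the 20 standard residues (alphabetical order)."""
    idx = np.empty(len(seq), dtype=np.int64)
    for k, a in enumerate(seq):
        if a not in _AA_INDEX:
            raise ValueError(f"non-standard residue {a!r} at position {k}")
        idx[k] = _AA_INDEX[a]
    out = np.zeros((len(seq), 20), dtype=np.float64)
    out[np.arange(len(seq)), idx] = 1.0
    return out


class OneHotProvider:
    dim = 20

    def embed(self, seq: str) -> np.ndarray:
        return one_hot_embed(seq)


def load_embeddings(path: str | Path, seq: str) -> np.ndarray:
    """Load a precomputed N x F per-residue embedding matrix for ``seq``.

    Accepts a ``.npy``/``.npz`` array container (first array in an npz) or a
    plain TSV of floats.  The row count must equal the sequence length.
    """
    path = Path(path)
    if path.suffix == ".npy":
        mat = np.load(path)
    elif path.suffix == ".npz":
        with np.load(path) as z:
            mat = z[list(z.files)[0]]
    else:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError(f"embedding file {path.name} is not a 2-D matrix")
    if mat.shape[0] != len(seq):
        raise ValueError(
            f"embedding rows ({mat.shape[0]}) != sequence length ({len(seq)}) in {path.name}"
        )
    return mat


class FileProvider:
    """Embedding provider backed by per-sequence matrix files."""

    def __init__(self, paths: dict[str, str | Path]):
        self.paths = dict(paths)
        self.dim = -1  # set on first load

    def embed(self, seq: str) -> np.ndarray:
        mat = load_embeddings(self.paths[seq], seq)
        if self.dim == -1:
            self.dim = mat.shape[1]
        elif mat.shape[1] != self.dim:
            raise ValueError("inconsistent embedding width across sequences")
        return mat


def threshold_contacts(cm: ContactMap, cutoff: float = DEFAULT_CUTOFF) -> tuple[np.ndarray, np.ndarray]:
    """Edges (i < j) whose contact probability reaches the cutoff (inclusive).

    The probability itself becomes the edge weight; the diagonal never
    contributes.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    p = cm.probs
    iu, ju = np.triu_indices(cm.n, k=1)
    keep = p[iu, ju] >= cutoff
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    return edges, p[edges[:, 0], edges[:, 1]]


def assemble_graph(
    seq: str,
    provider: EmbeddingProvider,
    cm: ContactMap,
    cutoff: float = DEFAULT_CUTOFF,
    backbone_edges: bool = False,
) -> ProteinGraph:
    """Build the residue graph for one sequence.

    ``backbone_edges=True`` additionally connects sequence neighbours
    (i, i+1) with weight 1.0 (a robustness option for very sparse maps);
    by default only thresholded contacts form edges.
    """
    if cm.n != len(seq):
        raise ValueError(f"contact map size {cm.n} != sequence length {len(seq)}")
    feats = provider.embed(seq)
    if feats.shape[0] != len(seq):
        raise ValueError("embedding provider returned wrong row count")
    edges, weights = threshold_contacts(cm, cutoff)
    if backbone_edges and len(seq) > 1:
        present = {tuple(e) for e in edges.tolist()}
        extra = [(i, i + 1) for i in range(len(seq) - 1) if (i, i + 1) not in present]
        if extra:
            edges = np.vstack([edges, np.asarray(extra, dtype=np.int64)])
            weights = np.concatenate([weights, np.ones(len(extra))])
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges, weights = edges[order], weights[order]
        # existing backbone contacts are promoted to full weight
        bb = edges[:, 1] - edges[:, 0] == 1
        weights = np.where(bb, 1.0, weights)
    return ProteinGraph(node_features=feats, edges=edges, edge_weights=weights)


@dataclass
class GraphSample:
    """A (wild graph, mutant graph, ddG) training/evaluation example."""

    wild: ProteinGraph
    mut: ProteinGraph
    ddg: float
    protein_id: str = ""
    direction: str = "direct"
    pair_id: int | None = None


def save_contact_map(cm: ContactMap, path: str | Path) -> None:
    np.savetxt(path, cm.probs, delimiter="\t", fmt="%.10g")


def load_contact_map(path: str | Path) -> ContactMap:
    path = Path(path)
    if path.suffix == ".npy":
        return ContactMap(np.load(path))
    return ContactMap(np.loadtxt(path, delimiter="\t", ndmin=2))
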