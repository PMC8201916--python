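"""Single-level graph baselines: modularity, participation, global metrics.

These are the classical weighted-network comparators for the hierarchical
components: Newman modularity of a given labelling,

    Q = (1/l) Σ_ij [w_ij − k_i k_j / l] δ(m_i, m_j),   l = Σ_ij w_ij,

the participation coefficient PC_i = 1 − Σ_m (k_im/k_i)², and weighted
global metrics (characteristic path length and efficiency on 1/w distances,
Onnela geometric-mean clustering).  Module labels are an input here — no
community detection is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "LabeledNetwork",
    "GlobalMetrics",
    "modularity",
    "participation",
    "global_metrics",
]


@dataclass
class LabeledNetwork:
    """Weighted undirected network with a module label per node."""

    weights: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if w.min() < 0:
            raise ValueError("weights must be non-negative")
        if not np.allclose(np.diag(w), 0.0):
            raise ValueError("weight matrix diagonal must be zero")
        self.weights = 0.5 * (w + w.T)
        self.labels = np.asarray(self.labels)
        if self.labels.size != w.shape[0]:
            raise ValueError("one module label per node required")

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths k_i = Σ_j w_ij."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """l = Σ_ij w_ij over ordered pairs (twice the edge-weight sum)."""
        return float(self.weights.sum())

    def membership(self) -> np.ndarray:
        """Node × module one-hot matrix in label-sorted module order."""
        _, idx = np.unique(self.labels, return_inverse=True)
        m = idx.max() + 1
        onehot = np.zeros((self.labels.size, m))
        onehot[np.arange(self.labels.size), idx] = 1.0
        return onehot


def modularity(net: LabeledNetwork) -> float:
    """Newman modularity of the given labelling (ordered-pair double sum,
    i = j pairs included, exactly as the printed formula)."""
    ell = net.total_weight
    if ell <= 0:
        raise ValueError("modularity undefined: total weight is zero")
    s = net.membership()
    k = net.strengths
    within = float(np.sum((s.T @ net.weights @ s).diagonal()))
    null = float(np.sum((s.T @ np.outer(k, k) @ s).diagonal())) / ell
    return (within - null) / ell


def participation(net: LabeledNetwork) -> tuple[np.ndarray, float]:
    """Participation coefficient per node and its network mean.

    PC_i = 1 − Σ_m (k_im/k_i)²; a node whose strength concentrates in one
    module scores 0, one spread equally over M modules scores 1 − 1/M.
    Isolated nodes (k_i = 0) get PC = 0 with a warning.
    """
    s = net.membership()
    k = net.strengths
    k_im = net.weights @ s
    pc = np.zeros(k.size)
    scored = k > 0
    if not np.all(scored):
        warnings.warn("isolated node(s) assigned PC = 0", stacklevel=2)
    pc[scored] = 1.0 - np.sum((k_im[scored] / k[scored, None]) ** 2, axis=1)
    return pc, float(pc.mean())


@dataclass
class GlobalMetrics:
    path_length: float
    clustering: float
    efficiency: float


def global_metrics(weights: np.ndarray) -> GlobalMetrics:
    """Weighted characteristic path length, clustering, global efficiency.

    Distances are shortest paths on edge lengths 1/w; path length averages
    the finite pairwise distances, efficiency averages 1/distance with
    disconnected pairs contributing 0, and clustering is the mean Onnela
    geometric-mean triangle intensity (weights normalised by the maximum).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if w.min() < 0:
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("all-zero network has no global metrics")
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    path_length = float(dist[finite].mean()) if finite.any() else np.inf
    inv = np.zeros_like(dist)
    inv[finite] = 1.0 / dist[finite]
    efficiency = float(inv[off].mean())
    g = nx.from_numpy_array(w)
    clustering = float(np.mean(list(nx.clustering(g, weight="weight").values())))
    return GlobalMetrics(
        path_length=path_length, clustering=clustering, efficiency=efficiency
    )
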