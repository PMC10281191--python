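"""Binary graph construction over the sparsity sweep.

Each subject × subnetwork yields a voxel-level Pearson correlation matrix;
binarizing it at a target sparsity (the fraction of possible edges retained)
gives one undirected simple graph per point of the sparsity grid. Topology is
analyzed over the whole sweep, 0.05–0.40 in steps of 0.01, so that no single
arbitrary threshold drives the group comparison.

Edge ranking uses the signed correlation value: the strongest positive
correlations enter first and negative correlations are never selected before
positive ones, the usual binary-connectome convention. Absolute-value ranking
is available via ``rank_by_abs=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "connectivity_matrix",
    "threshold_by_sparsity",
    "sparsity_grid",
    "downsample_nodes",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric node × node functional-connectivity matrix.

    Values are Pearson correlations in [−1, 1]; the diagonal is exactly zero
    (self-connections are never edges). ``node_ids`` ties rows back to the
    originating subnetwork's node order.
    """

    values: np.ndarray
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        v = (v + v.T) / 2.0
        if np.nanmax(np.abs(v)) > 1.0 + 1e-9:
            raise ValueError("correlation values must lie in [-1, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, -1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def max_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2


@dataclass
class BinaryGraph:
    """Undirected simple graph, stored as a boolean adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = a.astype(bool)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def sparsity(self) -> float:
        """Actual density: edges divided by the maximum possible edge count."""
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        """Edges as an (m, 2) array with i < j, lexicographically sorted."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_list()))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BinaryGraph":
        nodes = sorted(g.nodes())
        index = {u: k for k, u in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for u, v in g.edges():
            if u == v:
                continue
            a[index[u], index[v]] = a[index[v], index[u]] = True
        return cls(a)

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "BinaryGraph":
        a = np.zeros((n_nodes, n_nodes), dtype=bool)
        for u, v in edges:
            if u == v:
                continue
            a[u, v] = a[v, u] = True
        return cls(a)


def connectivity_matrix(node_timeseries: np.ndarray) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of node time series.

    Parameters
    ----------
    node_timeseries
        Array of shape ``(n_nodes, n_timepoints)``.

    Constant (zero-variance) series cannot carry a correlation; their rows
    and columns are set to 0 with a warning rather than NaN, so the node is
    simply never connected.
    """
    ts = np.asarray(node_timeseries, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError("node_timeseries must be 2-D (nodes × time)")
    n_nodes, n_t = ts.shape
    if n_t < 3:
        raise ValueError(f"need at least 3 timepoints, got {n_t}")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")

    sd = ts.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant node series; their correlations are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(np.clip(r, -1.0, 1.0))


def threshold_by_sparsity(
    m: ConnectivityMatrix, s: float, rank_by_abs: bool = False
) -> BinaryGraph:
    """Binarize a connectivity matrix by keeping the top ``s`` fraction of edges.

    The edge count is round-half-up of ``s * n(n-1)/2``. Ties in correlation
    are broken by lexicographic node-pair order, which makes edge sets nested
    across increasing ``s``.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    n = m.n_nodes
    k = int(math.floor(s * m.max_edges + 0.5))
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges on {n} nodes")

    iu, ju = np.triu_indices(n, k=1)
    w = m.values[iu, ju]
    if rank_by_abs:
        w = np.abs(w)
    # stable sort on (-weight, i, j): lexsort's last key is primary
    order = np.lexsort((ju, iu, -w))[:k]
    a = np.zeros((n, n), dtype=bool)
    a[iu[order], ju[order]] = True
    return BinaryGraph(a | a.T)


def sparsity_grid(
    low: float = 0.05, high: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """The sparsity sweep: 0.05, 0.06, …, 0.40 (36 values, endpoints included)."""
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


def downsample_nodes(subnet, factor: int):
    """Pool a subnetwork's voxels into ``factor³`` blocks to shrink the graph.

    Block time series are the mean of member-voxel series; empty blocks are
    dropped. ``factor=1`` is the identity. Mirrors the resampling used to cut
    the voxel-level connectivity matrix down to a tractable size.
    """
    from .ica import SubnetworkDefinition

    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return subnet
    if subnet.node_timeseries is None:
        raise ValueError("subnetwork has no node time series to pool")

    coords = np.asarray(subnet.node_voxels)
    blocks = coords // factor
    keys, inverse = np.unique(blocks, axis=0, return_inverse=True)
    if keys.shape[0] < 2:
        raise ValueError(f"downsampling by {factor} leaves fewer than 2 nodes")
    ts = np.asarray(subnet.node_timeseries, dtype=np.float64)
    pooled = np.zeros((keys.shape[0], ts.shape[1]))
    counts = np.bincount(inverse, minlength=keys.shape[0])
    np.add.at(pooled, inverse, ts)
    pooled /= counts[:, None]
    return SubnetworkDefinition(
        label=subnet.label,
        node_voxels=keys,
        node_timeseries=pooled,
        source_component=subnet.source_component,
    )
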