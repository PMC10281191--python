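"""Global topology metrics with random-network normalization and sparsity AUC.

The ten-property suite computed for every binary graph of the sparsity sweep:

* small-world family — clustering coefficient ``Cp``, characteristic path
  length ``Lp``, and their normalized forms ``γ = Cp / Cp_rand``,
  ``λ = Lp / Lp_rand`` and small-worldness ``σ = γ/λ``, where the random
  reference is the mean over degree-preserving rewired surrogates
  (100 by default);
* efficiency family — global efficiency ``Eglobal`` (mean inverse shortest
  path length over all pairs) and local efficiency ``Elocal`` (mean global
  efficiency of each node's neighbor-induced subgraph);
* degree assortativity ``r`` (Pearson correlation of degrees across edge
  endpoints, Newman's degree-mixing coefficient);
* hierarchy ``β``, the power-law exponent of clustering versus degree,
  ``C ≈ k^(−β)``, fitted as the negative slope of log C on log k;
* synchronization ``S``, the ratio of the second-smallest to the largest
  eigenvalue of the combinatorial graph Laplacian ``D − A``.

A small-world graph satisfies ``γ > 1`` with ``λ ≈ 1``. Each metric traced
over the sparsity grid is summarized by its trapezoidal area under the curve
(AUC), the scalar unit of group comparison.

Disconnected graphs: ``Lp`` averages over reachable pairs only (a config
alternative ``lp_disconnected="inverse_eglobal"`` uses ``1/Eglobal``), which
keeps ``λ`` defined at low sparsity. Metrics that are genuinely undefined on
a graph (assortativity of a regular graph, hierarchy with too few eligible
nodes, synchronization of an edgeless graph) are returned as NaN with a
warning and excluded pairwise from AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graphs import BinaryGraph, ConnectivityMatrix, sparsity_grid, threshold_by_sparsity

__all__ = [
    "METRIC_NAMES",
    "NodalProfile",
    "NetworkMetrics",
    "MetricCurve",
    "nodal_profile",
    "smallworld_base",
    "assortativity",
    "hierarchy_beta",
    "synchronization",
    "rewire_null",
    "normalize_smallworld",
    "compute_metrics",
    "metric_curves",
    "auc",
]

#: Canonical metric order used in every table the pipeline emits.
METRIC_NAMES = (
    "Cp",
    "Lp",
    "gamma",
    "lambda",
    "sigma",
    "Eglobal",
    "Elocal",
    "assortativity",
    "hierarchy",
    "synchronization",
)


@dataclass
class NodalProfile:
    """Per-node degree, clustering coefficient and nodal efficiency."""

    degree: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray


@dataclass
class NetworkMetrics:
    """The ten global properties of one binary graph."""

    Cp: float
    Lp: float
    gamma: float
    lambda_: float
    sigma: float
    Eglobal: float
    Elocal: float
    assortativity: float
    hierarchy: float
    synchronization: float

    def as_dict(self) -> dict[str, float]:
        d = {
            "Cp": self.Cp,
            "Lp": self.Lp,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "Eglobal": self.Eglobal,
            "Elocal": self.Elocal,
            "assortativity": self.assortativity,
            "hierarchy": self.hierarchy,
            "synchronization": self.synchronization,
        }
        return d


@dataclass
class MetricCurve:
    """One metric traced over the sparsity grid, with its AUC."""

    name: str
    grid: np.ndarray
    values: np.ndarray

    @property
    def auc(self) -> float:
        return auc(self.values, self.grid)


# ---------------------------------------------------------------------------
# building blocks


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest path lengths (inf for unreachable)."""
    return shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)


def _clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(np.float64)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def nodal_profile(g: BinaryGraph) -> NodalProfile:
    """Per-node degree, triangle-based clustering, and nodal efficiency.

    ``C_i = 2·triangles(i) / (k_i (k_i − 1))`` for ``k_i ≥ 2``, else 0;
    nodal efficiency is the mean of ``1/d(i, j)`` over ``j ≠ i`` with
    ``1/∞ = 0``.
    """
    adj = g.adjacency
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _distance_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return NodalProfile(
        degree=g.degrees,
        clustering=_clustering(adj),
        efficiency=inv.sum(axis=1) / (n - 1),
    )


def smallworld_base(
    g: BinaryGraph, lp_disconnected: str = "reachable"
) -> tuple[float, float, float, float]:
    """Cp, Lp, Eglobal, Elocal of one graph.

    ``lp_disconnected`` selects how Lp treats unreachable pairs:
    ``"reachable"`` averages path length over reachable pairs only;
    ``"inverse_eglobal"`` returns ``1/Eglobal`` instead.
    """
    adj = g.adjacency
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _distance_matrix(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off

    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    eglobal = float(inv[off].sum() / (n * (n - 1)))

    if lp_disconnected == "inverse_eglobal":
        lp = 1.0 / eglobal if eglobal > 0 else float("inf")
    elif finite.any():
        lp = float(d[finite].mean())
    else:
        lp = float("nan")

    cp = float(_clustering(adj).mean())

    # local efficiency: Eglobal of each node's neighbor-induced subgraph
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        m = nbrs.size
        if m < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        ds = _distance_matrix(sub)
        with np.errstate(divide="ignore"):
            invs = 1.0 / ds
        invs[~np.isfinite(invs)] = 0.0
        np.fill_diagonal(invs, 0.0)
        eloc[i] = invs.sum() / (m * (m - 1))
    elocal = float(eloc.mean())

    return cp, lp, eglobal, elocal


def assortativity(g: BinaryGraph) -> float:
    """Degree-mixing coefficient: Pearson correlation of endpoint degrees.

    Undefined (NaN, with a warning) when all edge endpoints share one degree,
    e.g. on regular graphs.
    """
    edges = g.edge_list()
    if edges.shape[0] < 1:
        raise ValueError("assortativity needs at least one edge")
    k = g.degrees.astype(np.float64)
    x = np.concatenate([k[edges[:, 0]], k[edges[:, 1]]])
    y = np.concatenate([k[edges[:, 1]], k[edges[:, 0]]])
    if x.std() == 0:
        warnings.warn("degree-regular graph: assortativity undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hierarchy_beta(g: BinaryGraph) -> float:
    """Hierarchy exponent β from the log–log regression of clustering on degree.

    Only nodes with ``k ≥ 2`` and ``C > 0`` enter the fit (log of zero is
    undefined); at least two eligible nodes with distinct degrees are needed,
    otherwise NaN with a warning.
    """
    deg = g.degrees
    clust = _clustering(g.adjacency)
    mask = (deg >= 2) & (clust > 0)
    k = deg[mask].astype(np.float64)
    c = clust[mask]
    if k.size < 2 or np.unique(k).size < 2:
        warnings.warn("hierarchy undefined: fewer than 2 eligible nodes with distinct degrees",
                      stacklevel=2)
        return float("nan")
    slope = np.polyfit(np.log(k), np.log(c), 1)[0]
    return float(-slope)


def synchronization(g: BinaryGraph) -> float:
    """S = θ₂/θ_N of the Laplacian D − A; 0 for disconnected, NaN if edgeless."""
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    a = g.adjacency.astype(np.float64)
    lap = np.diag(a.sum(axis=1)) - a
    eig = np.linalg.eigvalsh(lap)
    theta_max = eig[-1]
    if theta_max <= 1e-12:
        warnings.warn("edgeless graph: synchronization undefined", stacklevel=2)
        return float("nan")
    return float(max(eig[1], 0.0) / theta_max)


# ---------------------------------------------------------------------------
# degree-preserving null model


def rewire_null(
    g: BinaryGraph,
    n_networks: int = 100,
    n_swap_factor: int = 100,
    seed: int | np.random.Generator | None = None,
) -> list[BinaryGraph]:
    """Degree-preserving random surrogates via repeated double-edge swaps.

    Each surrogate starts from ``g`` and attempts ``n_swap_factor × |E|``
    swaps; a swap replaces edges (a,b), (c,d) with (a,d), (c,b) and is
    rejected if it would create a self-loop or a parallel edge, so the degree
    sequence is conserved exactly. Graphs on which no swap is possible are
    returned as copies with a warning.
    """
    rng = np.random.default_rng(seed)
    edges = g.edge_list()
    m = edges.shape[0]
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")

    nulls: list[BinaryGraph] = []
    any_swapped = False
    attempts = n_swap_factor * m
    for _ in range(n_networks):
        adj = g.adjacency.copy()
        e = edges.copy()
        pick = rng.integers(0, m, size=(attempts, 2))
        flip = rng.integers(0, 2, size=attempts)
        swapped = 0
        for t in range(attempts):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            a, b = e[e1]
            c, d = e[e2]
            if flip[t]:
                c, d = d, c
            # propose (a,d) and (c,b)
            if a == d or c == b or adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = adj[b, a] = False
            adj[c, d] = adj[d, c] = False
            adj[a, d] = adj[d, a] = True
            adj[c, b] = adj[b, c] = True
            e[e1] = (a, d) if a < d else (d, a)
            e[e2] = (c, b) if c < b else (b, c)
            swapped += 1
        any_swapped = any_swapped or swapped > 0
        nulls.append(BinaryGraph(adj))
    if not any_swapped:
        warnings.warn("no degree-preserving swap was possible; nulls are copies of the input",
                      stacklevel=2)
    return nulls


def normalize_smallworld(
    g: BinaryGraph,
    nulls: list[BinaryGraph],
    lp_disconnected: str = "reachable",
) -> tuple[float, float, float]:
    """γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩, σ = γ/λ."""
    if not nulls:
        raise ValueError("need at least one null graph")
    cp, lp, _, _ = smallworld_base(g, lp_disconnected)
    null_cp = []
    null_lp = []
    for h in nulls:
        c, l, _, _ = smallworld_base(h, lp_disconnected)
        null_cp.append(c)
        null_lp.append(l)
    mean_cp = float(np.mean(null_cp))
    mean_lp = float(np.mean(null_lp))
    if mean_cp <= 0 or mean_lp <= 0:
        raise ValueError("null means must be positive to normalize")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return gamma, lam, gamma / lam


def compute_metrics(
    g: BinaryGraph,
    n_nulls: int = 100,
    n_swap_factor: int = 100,
    seed: int | np.random.Generator | None = None,
    lp_disconnected: str = "reachable",
) -> NetworkMetrics:
    """All ten global properties of one graph (γ/λ/σ via rewired nulls)."""
    cp, lp, eglobal, elocal = smallworld_base(g, lp_disconnected)
    nulls = rewire_null(g, n_networks=n_nulls, n_swap_factor=n_swap_factor, seed=seed)
    try:
        gamma, lam, sigma = normalize_smallworld(g, nulls, lp_disconnected)
    except ValueError:
        # e.g. zero null clustering on very sparse graphs: undefined, not fatal
        gamma = lam = sigma = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = assortativity(g)
        beta = hierarchy_beta(g)
        s = synchronization(g)
    return NetworkMetrics(
        Cp=cp, Lp=lp, gamma=gamma, lambda_=lam, sigma=sigma,
        Eglobal=eglobal, Elocal=elocal, assortativity=r, hierarchy=beta,
        synchronization=s,
    )


def metric_curves(
    matrix: ConnectivityMatrix,
    grid: np.ndarray | None = None,
    n_nulls: int = 100,
    n_swap_factor: int = 100,
    seed: int | np.random.Generator | None = None,
    rank_by_abs: bool = False,
    lp_disconnected: str = "reachable",
) -> dict[str, MetricCurve]:
    """Threshold at every sparsity of the grid and trace all ten metrics."""
    if grid is None:
        grid = sparsity_grid()
    grid = np.asarray(grid, dtype=np.float64)
    rng = np.random.default_rng(seed)
    values = {name: np.full(grid.size, np.nan) for name in METRIC_NAMES}
    for idx, s in enumerate(grid):
        g = threshold_by_sparsity(matrix, float(s), rank_by_abs=rank_by_abs)
        met = compute_metrics(
            g, n_nulls=n_nulls, n_swap_factor=n_swap_factor, seed=rng,
            lp_disconnected=lp_disconnected,
        ).as_dict()
        for name in METRIC_NAMES:
            values[name][idx] = met[name]
    return {name: MetricCurve(name, grid, values[name]) for name in METRIC_NAMES}


def auc(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid.

    NaN points are excluded pairwise; at least two defined points are
    required. The grid must be strictly increasing.
    """
    grid = np.asarray(grid, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if grid.ndim != 1 or grid.size != values.size:
        raise ValueError("grid and values must be 1-D and the same length")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    mask = np.isfinite(values)
    if mask.sum() < 2:
        raise ValueError("need at least 2 defined points for AUC")
    return float(np.trapezoid(values[mask], grid[mask]))
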