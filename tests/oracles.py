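"""Independent brute-force oracles used to check the graph-metric suite.

Everything here is deliberately naive — explicit loops, closed formulas —
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def triangles_per_node(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    t = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i < j < k and adj[i, j] and adj[j, k] and adj[i, k]:
                    t[i] += 1
                    t[j] += 1
                    t[k] += 1
    return t


def clustering_per_node(adj: np.ndarray) -> np.ndarray:
    tri = triangles_per_node(adj)
    deg = adj.sum(axis=1)
    out = np.zeros(len(deg))
    for i, (t, k) in enumerate(zip(tri, deg)):
        out[i] = 2.0 * t / (k * (k - 1)) if k >= 2 else 0.0
    return out


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path length over reachable pairs (NaN if none)."""
    d = floyd_warshall(adj)
    vals = [d[i, j] for i in range(len(d)) for j in range(len(d))
            if i != j and math.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def global_efficiency(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = len(d)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    out = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out += global_efficiency(sub)
    return out / n


def assortativity_edge_list(adj: np.ndarray) -> float:
    """Pearson correlation of endpoint degrees, summed over both edge directions."""
    deg = adj.sum(axis=1)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    mx, my = xs.mean(), ys.mean()
    sx = math.sqrt(((xs - mx) ** 2).mean())
    sy = math.sqrt(((ys - my) ** 2).mean())
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((xs - mx) * (ys - my)).mean() / (sx * sy))


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form simple-regression slope."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum())


def hierarchy_exponent(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1)
    clu = clustering_per_node(adj)
    keep = [(k, c) for k, c in zip(deg, clu) if k >= 2 and c > 0]
    if len(keep) < 2:
        return float("nan")
    ks = np.array([k for k, _ in keep], float)
    cs = np.array([c for _, c in keep], float)
    if np.unique(ks).size < 2:
        return float("nan")
    return -ols_slope(np.log(ks), np.log(cs))


def laplacian_sync(adj: np.ndarray) -> float:
    a = adj.astype(float)
    lap = np.diag(a.sum(axis=1)) - a
    eig = np.sort(np.linalg.eigvalsh(lap))
    if eig[-1] <= 1e-12:
        return float("nan")
    return float(max(eig[1], 0.0) / eig[-1])


def pearson_formula(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    num = ((x - x.mean()) * (y - y.mean())).sum()
    den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    return float(num / den)
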