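"""Group ICA with stability selection and back-reconstruction.

Multi-subject spatial ICA in the temporal-concatenation style: each
subject's (time × voxel) matrix is reduced by PCA along time, the reduced
matrices are stacked and reduced again at the group level, and ICA unmixes
the group subspace into spatial components (maps × courses). The ICA step is
repeated from random initializations; the pooled components of all runs are
clustered by absolute spatial correlation and each cluster's centrotype is
kept, with a stability index (mean within-cluster minus mean between-cluster
similarity) qualifying each component — the standard run-to-run robustness
check. Subject-specific maps and courses are recovered from the retained
PCA transforms (back-reconstruction), and components are matched one-to-one
against spatial templates to name the seven resting-state subnetworks.

The contrast function is Infomax (logistic nonlinearity, natural-gradient
ascent), the classical choice for the super-Gaussian spatial sources of
resting-state data; FastICA is available as a faster alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import FastICA

from .volume import VolumeSeries

__all__ = [
    "GroupPCAResult",
    "ComponentSet",
    "SubnetworkDefinition",
    "group_pca_reduce",
    "run_stabilized_ica",
    "back_reconstruct",
    "select_subnetworks",
    "extract_node_timeseries",
]


@dataclass
class GroupPCAResult:
    """Two-level PCA reduction with the transforms kept for back-reconstruction."""

    reduced: np.ndarray  # (n_group_pcs, voxels) group subspace
    subject_bases: list[np.ndarray]  # per subject (t, n_subject_pcs)
    subject_reduced: list[np.ndarray]  # per subject (n_subject_pcs, voxels)
    partitions: list[np.ndarray]  # per subject rows of the group projector
    subject_means: list[np.ndarray]  # removed voxel means
    retained_variance: float
    grid_dims: tuple[int, int, int] | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_bases)

    @property
    def n_group_pcs(self) -> int:
        return self.reduced.shape[0]

    def reconstruct_subject(self, i: int) -> np.ndarray:
        """Subject data approximated from its own reduction, (t, voxels)."""
        return self.subject_bases[i] @ self.subject_reduced[i] + self.subject_means[i]


@dataclass
class ComponentSet:
    """Stabilized group components: spatial z-maps, mixing, courses, stability."""

    group_maps: np.ndarray  # (n_components, voxels), z-scored over voxels
    group_courses: np.ndarray  # (n_components, total timepoints)
    mixing: np.ndarray  # (n_group_pcs, n_components)
    stability_index: np.ndarray  # per component, in [0, 1]
    grid_dims: tuple[int, int, int] | None = None

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]

    def stability_report(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "stability_index": [float(q) for q in self.stability_index],
        }


@dataclass
class SubnetworkDefinition:
    """A labeled subnetwork: its voxels (graph nodes) and node time series."""

    label: str
    node_voxels: np.ndarray  # (n_nodes, 3) integer voxel coordinates
    node_timeseries: np.ndarray | None = None  # (n_nodes, t)
    source_component: int = -1

    def __post_init__(self) -> None:
        self.node_voxels = np.asarray(self.node_voxels, dtype=np.int64)
        if self.node_voxels.ndim != 2 or self.node_voxels.shape[1] != 3:
            raise ValueError("node_voxels must be (n_nodes, 3)")
        if self.node_voxels.shape[0] < 2:
            raise ValueError(f"subnetwork {self.label!r} has fewer than 2 nodes")

    @property
    def n_nodes(self) -> int:
        return self.node_voxels.shape[0]


# ---------------------------------------------------------------------------
# PCA reduction


def _as_matrix(subject) -> np.ndarray:
    if isinstance(subject, VolumeSeries):
        return subject.timeseries_matrix()
    return np.asarray(subject, dtype=np.float64)


def group_pca_reduce(
    subjects,
    n_subject_pcs: int,
    n_group_pcs: int,
    rank_tol: float = 1e-10,
) -> GroupPCAResult:
    """Subject-level PCA, temporal concatenation, group-level PCA.

    Each subject's voxel-centered (t × voxel) matrix is reduced to its top
    ``n_subject_pcs`` temporal principal components; the reduced matrices
    are stacked and reduced again to ``n_group_pcs`` group components by
    exact eigendecomposition. Raises when the data rank falls below the
    requested dimensions.
    """
    mats = [_as_matrix(s) for s in subjects]
    if not mats:
        raise ValueError("no subjects given")
    t, v = mats[0].shape
    if n_subject_pcs > min(t, v):
        raise ValueError(f"n_subject_pcs={n_subject_pcs} exceeds data dims ({t}, {v})")
    if n_group_pcs > n_subject_pcs * len(mats):
        raise ValueError("n_group_pcs exceeds the concatenated subject dimension")

    bases, reduced, means = [], [], []
    for m in mats:
        mu = m.mean(axis=0, keepdims=True)
        xc = m - mu
        u, s, vt = linalg.svd(xc, full_matrices=False)
        if s[n_subject_pcs - 1] <= rank_tol * max(s[0], 1.0):
            raise ValueError(
                f"subject data rank below requested n_subject_pcs={n_subject_pcs}"
            )
        bases.append(u[:, :n_subject_pcs])
        reduced.append(s[:n_subject_pcs, None] * vt[:n_subject_pcs])
        means.append(mu)

    stacked = np.vstack(reduced)
    ug, sg, vgt = linalg.svd(stacked, full_matrices=False)
    if sg[n_group_pcs - 1] <= rank_tol * max(sg[0], 1.0):
        raise ValueError(f"group data rank below requested n_group_pcs={n_group_pcs}")
    group = sg[:n_group_pcs, None] * vgt[:n_group_pcs]
    projector = ug[:, :n_group_pcs]
    retained = float((sg[:n_group_pcs] ** 2).sum() / (sg**2).sum())

    k = n_subject_pcs
    partitions = [projector[i * k : (i + 1) * k] for i in range(len(mats))]
    grid = subjects[0].grid_dims if isinstance(subjects[0], VolumeSeries) else None
    return GroupPCAResult(
        reduced=group,
        subject_bases=bases,
        subject_reduced=reduced,
        partitions=partitions,
        subject_means=means,
        retained_variance=retained,
        grid_dims=grid,
    )


# ---------------------------------------------------------------------------
# ICA


def _whiten(group: np.ndarray) -> np.ndarray:
    """Scale the (orthogonal) group PCA rows to unit sample variance."""
    v = group.shape[1]
    norms = np.linalg.norm(group, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate group component with zero norm")
    return group * (np.sqrt(v) / norms)[:, None]


def _infomax_unmix(
    z: np.ndarray,
    rng: np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-6,
    lr: float = 0.005,
) -> np.ndarray:
    """Infomax ICA: natural-gradient ascent with a logistic nonlinearity."""
    g, v = z.shape
    w = linalg.qr(rng.standard_normal((g, g)))[0]
    eye = np.eye(g)
    step = lr
    for _ in range(max_iter):
        u = w @ z
        y = 1.0 / (1.0 + np.exp(-u))
        grad = (eye + (1.0 - 2.0 * y) @ u.T / v) @ w
        if not np.all(np.isfinite(grad)):
            # diverged: restart shrunken
            step *= 0.5
            w = linalg.qr(rng.standard_normal((g, g)))[0]
            continue
        w = w + step * grad
        if np.linalg.norm(step * grad) < tol * np.linalg.norm(w):
            break
    return w


def _single_run(z, rng, algorithm, max_iter, tol):
    if algorithm == "infomax":
        w = _infomax_unmix(z, rng, max_iter=max_iter, tol=tol)
        return w @ z
    if algorithm == "fastica":
        ica = FastICA(
            n_components=z.shape[0],
            whiten=False,
            max_iter=max_iter,
            tol=max(tol, 1e-8),
            random_state=int(rng.integers(2**31 - 1)),
        )
        return ica.fit_transform(z.T).T
    raise ValueError(f"unknown ICA algorithm {algorithm!r}")


def _orient_and_normalize(comps: np.ndarray) -> np.ndarray:
    """Unit-norm rows, sign fixed so each map's skewness is positive."""
    out = comps / np.linalg.norm(comps, axis=1, keepdims=True)
    centered = out - out.mean(axis=1, keepdims=True)
    skew = (centered**3).mean(axis=1)
    sign = np.where(skew >= 0, 1.0, -1.0)
    return out * sign[:, None]


def run_stabilized_ica(
    gpca: GroupPCAResult,
    n_runs: int = 100,
    seed: int | np.random.Generator | None = None,
    algorithm: str = "infomax",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ComponentSet:
    """Repeat ICA from random starts and keep each component cluster's centrotype.

    All runs' spatial components are pooled and clustered (average linkage on
    1 − |spatial correlation|) into as many clusters as components; the
    centrotype — the member most similar to the rest of its cluster — is
    returned with a stability index (mean within-cluster similarity minus
    mean between-cluster similarity). A single run yields degenerate indices
    of 1.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    z = _whiten(gpca.reduced)
    g = z.shape[0]

    pooled = []
    for _ in range(n_runs):
        comps = _single_run(z, rng, algorithm, max_iter, tol)
        if not np.all(np.isfinite(comps)):
            continue
        pooled.append(_orient_and_normalize(comps))
    if not pooled:
        raise RuntimeError("all ICA runs failed to converge")
    allc = np.vstack(pooled)  # (n_runs*g, voxels)

    if n_runs == 1:
        centro = allc
        stability = np.ones(g)
    else:
        sim = np.abs(np.corrcoef(allc))
        labels = AgglomerativeClustering(
            n_clusters=g, metric="precomputed", linkage="average"
        ).fit_predict(1.0 - sim)
        centro_rows, stability_list = [], []
        for c in range(g):
            members = np.nonzero(labels == c)[0]
            others = np.nonzero(labels != c)[0]
            block = sim[np.ix_(members, members)]
            if members.size == 1:
                within = 1.0
                best = members[0]
            else:
                mean_to_members = (block.sum(axis=1) - 1.0) / (members.size - 1)
                best = members[int(np.argmax(mean_to_members))]
                within = float(mean_to_members.mean())
            between = float(sim[np.ix_(members, others)].mean()) if others.size else 0.0
            centro_rows.append(allc[best])
            stability_list.append(np.clip(within - between, 0.0, 1.0))
        centro = np.asarray(centro_rows)
        stability = np.asarray(stability_list)
        order = np.argsort(-stability)
        centro, stability = centro[order], stability[order]

    # mixing such that group subspace ≈ mixing @ components
    mixing, *_ = np.linalg.lstsq(centro.T, gpca.reduced.T, rcond=None)
    mixing = mixing.T  # (n_group_pcs, n_components)

    # group-level courses: concatenated back-projected subject courses
    courses = np.vstack([
        gpca.subject_bases[i] @ (gpca.partitions[i] @ mixing)
        for i in range(gpca.n_subjects)
    ]).T

    zmaps = (centro - centro.mean(axis=1, keepdims=True)) / centro.std(
        axis=1, keepdims=True
    )
    return ComponentSet(
        group_maps=zmaps,
        group_courses=courses,
        mixing=mixing,
        stability_index=stability,
        grid_dims=gpca.grid_dims,
    )


def back_reconstruct(
    subject_index: int, gpca: GroupPCAResult, components: ComponentSet
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-specific spatial maps and time courses for every component.

    Returns ``(maps, courses)`` with maps ``(n_components, voxels)``
    z-scored over voxels and courses ``(t, n_components)``. The subject's
    retained PCA transforms are projected through the group mixing matrix;
    maps solve the subject's reduced data in least squares.
    """
    i = subject_index
    if not 0 <= i < gpca.n_subjects:
        raise IndexError(f"subject index {i} out of range")
    loading = gpca.partitions[i] @ components.mixing  # (k, n_components)
    courses = gpca.subject_bases[i] @ loading  # (t, n_components)
    maps, *_ = np.linalg.lstsq(loading, gpca.subject_reduced[i], rcond=None)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - maps.mean(axis=1, keepdims=True)) / sd
    return maps, courses


# ---------------------------------------------------------------------------
# subnetwork selection


def select_subnetworks(
    components: ComponentSet,
    templates: dict[str, np.ndarray],
    z_threshold: float = 2.0,
    match_floor: float = 0.3,
) -> list[SubnetworkDefinition]:
    """Greedy one-to-one matching of components to labeled templates.

    Spatial |correlation| between every component z-map and every template is
    computed; pairs are assigned greedily from the best match down, never
    reusing a component or a label, and only above ``match_floor``. Voxels
    with ``|z| ≥ z_threshold`` in the assigned component's group map become
    the subnetwork's nodes. If any label stays unmatched, an error lists the
    missing labels — there is no silent partial output.
    """
    if components.grid_dims is None:
        raise ValueError("component set has no grid geometry")
    grid = components.grid_dims
    labels = list(templates)
    tmat = np.asarray([np.ravel(templates[l]) for l in labels], dtype=np.float64)
    if tmat.shape[1] != components.group_maps.shape[1]:
        raise ValueError("template and component voxel counts differ")

    n_comp = components.n_components
    corr = np.zeros((n_comp, len(labels)))
    for a in range(n_comp):
        for b in range(len(labels)):
            corr[a, b] = abs(np.corrcoef(components.group_maps[a], tmat[b])[0, 1])

    assigned: dict[str, int] = {}
    work = corr.copy()
    while len(assigned) < len(labels):
        a, b = np.unravel_index(np.argmax(work), work.shape)
        if work[a, b] < match_floor:
            break
        assigned[labels[b]] = int(a)
        work[a, :] = -1.0
        work[:, b] = -1.0
    unmatched = [l for l in labels if l not in assigned]
    if unmatched:
        raise ValueError(
            f"no component matched templates above |r|={match_floor} for "
            f"labels: {unmatched}"
        )

    subnets = []
    for label in labels:
        comp = assigned[label]
        zmap = components.group_maps[comp].reshape(grid)
        mask = np.abs(zmap) >= z_threshold
        coords = np.argwhere(mask)
        if coords.shape[0] < 2:
            raise ValueError(
                f"subnetwork {label!r}: fewer than 2 voxels exceed |z|>="
                f"{z_threshold}"
            )
        subnets.append(
            SubnetworkDefinition(label=label, node_voxels=coords, source_component=comp)
        )
    return subnets


def extract_node_timeseries(
    subnet: SubnetworkDefinition, volume: VolumeSeries
) -> SubnetworkDefinition:
    """Fill a subnetwork definition with one subject's node time series."""
    x, y, z = subnet.node_voxels.T
    ts = volume.data[x, y, z, :]
    return SubnetworkDefinition(
        label=subnet.label,
        node_voxels=subnet.node_voxels,
        node_timeseries=ts,
        source_component=subnet.source_component,
    )
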