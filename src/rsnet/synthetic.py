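"""Synthetic resting-state cohorts with recoverable ground truth.

The generator emulates the study design the analysis assumes: two arms
(``control`` and ``BCI``) of 20 subjects each, 200 volumes per subject at
TR = 3 s, and seven embedded spatial networks — smooth, compact Gaussian
blobs on a fixed lattice of centers, one per resting-state-network label —
whose time courses mix linearly into every voxel with added i.i.d. Gaussian
noise. Each subject's volume is therefore an exact low-rank mixture plus
noise, so every downstream stage (ICA recovery, graph topology, group
statistics) can be tested against known ground truth without any download.

Two group effects are injected into the intervention arm, mirroring the
direction of the findings the pipeline is meant to detect:

* a *clustering deficit* in one target network (default VN): random
  within-network voxel pairs receive private shared signals, which act like
  random shortcuts in the thresholded graph and lower its normalized
  clustering γ;
* an *assortativity gain* in a second network (default DAN): the network's
  core voxels (map amplitude ≥ half peak) share an extra common course whose
  per-subject amplitude is raised in the intervention arm, strengthening
  hub–hub coupling and raising degree assortativity.

Post-intervention clinical gains (FMA-UE, 0–66) are generated to correlate
with the per-subject assortativity-coupling latent at a chosen population
correlation (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import BinaryGraph
from .volume import VolumeSeries

__all__ = [
    "RSN_LABELS",
    "CohortSpec",
    "GroupEffectSpec",
    "ClinicalRecord",
    "Cohort",
    "rsn_template_maps",
    "smoothed_courses",
    "synthesize_subject",
    "generate_clinical_scores",
    "generate_cohort",
    "generate_toy_graph",
]

#: The seven resting-state subnetwork labels, in canonical order.
RSN_LABELS = ("AUN", "DMN", "DAN", "VAN", "FPN", "SMN", "VN")

# Fixed fractional blob centers (unit cube); first seven serve the RSN labels.
_CENTERS = (
    (0.30, 0.30, 0.30),
    (0.70, 0.32, 0.30),
    (0.32, 0.70, 0.32),
    (0.70, 0.70, 0.34),
    (0.30, 0.34, 0.70),
    (0.34, 0.68, 0.70),
    (0.68, 0.32, 0.72),
    (0.66, 0.70, 0.68),
    (0.50, 0.50, 0.50),
)


@dataclass
class GroupEffectSpec:
    """Ground-truth group differences injected into the intervention arm.

    ``gamma_network``: every subject's target network carries, on top of its
    shared course, ``gamma_n_courses`` amplitude-weighted random coupling
    courses of total strength ``gamma_coupling`` — the rich sub-network
    coupling that makes its thresholded graph strongly clustered relative to
    degree-matched nulls. In the BCI arm that strength is multiplied by
    ``gamma_shift`` (< 1), so the intervention network's edge ranking
    becomes noise-driven and its normalized clustering γ drops.

    ``assort_network``: the network's supporting voxels are split by map
    amplitude into two modules, each putting a variance fraction ``w`` of
    its signal on its own module-wide course. ``w`` is the per-subject
    latent: ``assort_base`` in controls, ``assort_base + assort_gain`` in
    the BCI group, spread ``assort_subject_sd``, clipped to [0, 0.95].
    Larger ``w`` segregates the modules, so edges concentrate between
    like-degree nodes and degree assortativity rises.

    ``clinical_true_r``: population correlation between the per-subject
    module-coupling latent and the clinical gain.
    """

    gamma_network: str = "VN"
    gamma_coupling: float = 3.0
    gamma_shift: float = 0.45
    gamma_n_courses: int = 30
    assort_network: str = "DAN"
    assort_base: float = 0.1
    assort_gain: float = 0.6
    assort_subject_sd: float = 0.12
    clinical_true_r: float = 0.5
    enabled: bool = True

    def __post_init__(self) -> None:
        for label in (self.gamma_network, self.assort_network):
            if label not in RSN_LABELS:
                raise ValueError(f"unknown network label {label!r}")
        if abs(self.clinical_true_r) > 1:
            raise ValueError("|clinical_true_r| must be <= 1")

    @classmethod
    def off(cls) -> "GroupEffectSpec":
        return cls(gamma_coupling=0.0, assort_base=0.0, assort_gain=0.0,
                   enabled=False)


@dataclass
class CohortSpec:
    """Design of one synthetic cohort (defaults follow the emulated study)."""

    n_per_group: int = 20
    n_timepoints: int = 200
    grid_dims: tuple[int, int, int] = (18, 18, 18)
    tr_seconds: float = 3.0
    n_networks: int = 7
    noise_sigma: float = 0.5
    effect: GroupEffectSpec = field(default_factory=GroupEffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_timepoints <= self.n_networks:
            raise ValueError("n_timepoints must exceed n_networks")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if any(d < 6 for d in self.grid_dims):
            raise ValueError(f"degenerate grid {self.grid_dims}: every dim must be >= 6")
        if not 1 <= self.n_networks <= len(_CENTERS):
            raise ValueError(f"n_networks must be in [1, {len(_CENTERS)}]")


@dataclass
class ClinicalRecord:
    """One subject's clinical row (FMA-UE bounded to its 0–66 scale)."""

    subject_id: str
    group: str
    fmaue_pre: float
    fmaue_post: float
    age: float
    sex: str
    lesion_side: str
    etiology: str

    def __post_init__(self) -> None:
        for v in (self.fmaue_pre, self.fmaue_post):
            if not 0 <= v <= 66:
                raise ValueError(f"FMA-UE score {v} outside [0, 66]")
        if self.group not in ("control", "BCI"):
            raise ValueError(f"group must be 'control' or 'BCI', got {self.group!r}")


@dataclass
class Cohort:
    """A generated cohort with its ground truth for recovery tests."""

    subjects: list[VolumeSeries]
    clinical: pd.DataFrame
    template_maps: np.ndarray  # (n_networks, x, y, z), peak-normalized
    labels: tuple[str, ...]
    true_courses: dict[str, np.ndarray]  # subject_id -> (t, n_networks)
    assort_latent: np.ndarray  # per-subject coupling latent, clinical correlate
    spec: CohortSpec

    def write_clinical_tsv(self, path) -> None:
        self.clinical.to_csv(path, sep="\t", index=False)

    def ground_truth_json(self) -> dict:
        return {
            "labels": list(self.labels),
            "grid_dims": list(self.spec.grid_dims),
            "assort_latent": self.assort_latent.tolist(),
            "effect": vars(self.spec.effect),
            "seed": self.spec.seed,
        }


# ---------------------------------------------------------------------------
# building blocks


def rsn_template_maps(
    grid_dims: tuple[int, int, int],
    n_networks: int = 7,
    sigma_frac: float = 0.11,
) -> np.ndarray:
    """Isotropic Gaussian blob templates, one per network, peak amplitude 1.

    Blob width is ``sigma_frac × min(grid_dims)`` voxels; centers sit on a
    fixed fractional lattice so templates are identical across seeds and
    match the generating maps exactly (they double as the selection
    templates of the ICA stage).
    """
    if any(d < 6 for d in grid_dims):
        raise ValueError(f"degenerate grid {grid_dims}")
    sigma = sigma_frac * min(grid_dims)
    xs, ys, zs = (np.arange(d, dtype=np.float64) for d in grid_dims)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    maps = np.empty((n_networks, *grid_dims))
    for c in range(n_networks):
        cx, cy, cz = (_CENTERS[c][a] * (grid_dims[a] - 1) for a in range(3))
        d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        maps[c] = np.exp(-d2 / (2 * sigma**2))
        maps[c] /= maps[c].max()
    return maps


def template_node_mask(template_map: np.ndarray, z_threshold: float = 2.0) -> np.ndarray:
    """Boolean voxel mask where the z-scored template exceeds the threshold."""
    z = (template_map - template_map.mean()) / template_map.std()
    return np.abs(z) >= z_threshold


def smoothed_courses(
    n_timepoints: int, n_courses: int, rng: np.random.Generator, window: int = 3
) -> np.ndarray:
    """Temporally smoothed standard-normal courses, shape (t, n_courses).

    A moving average over ``window`` samples mimics hemodynamic
    autocorrelation; each course is re-standardized to mean 0, SD 1.
    """
    raw = rng.standard_normal((n_timepoints + window - 1, n_courses))
    kernel = np.ones(window) / window
    out = np.empty((n_timepoints, n_courses))
    for c in range(n_courses):
        out[:, c] = np.convolve(raw[:, c], kernel, mode="valid")
    out -= out.mean(axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def synthesize_subject(
    maps: np.ndarray,
    time_courses: np.ndarray,
    noise_sigma: float,
    seed: int | np.random.Generator | None,
    tr_seconds: float = 3.0,
    subject_id: str = "",
    group: str = "",
    lesion_side: str = "left",
) -> VolumeSeries:
    """Mix spatial maps and time courses into one noisy 4-D volume.

    ``data[v, t] = Σ_c maps[c, v] · time_courses[t, c] + ε``, with
    ``ε ~ N(0, noise_sigma²)`` i.i.d. over voxels and time.
    """
    maps = np.asarray(maps, dtype=np.float64)
    courses = np.asarray(time_courses, dtype=np.float64)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_components, x, y, z)")
    if courses.ndim != 2 or courses.shape[1] != maps.shape[0]:
        raise ValueError(
            f"component count mismatch: {maps.shape[0]} maps vs "
            f"{courses.shape[1]} courses"
        )
    n_comp, *grid = maps.shape
    flat = maps.reshape(n_comp, -1)
    data = courses @ flat  # (t, voxels)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    vol = data.T.reshape(*grid, courses.shape[0])
    return VolumeSeries(
        data=vol,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        group=group,
        lesion_side=lesion_side,
    )


def generate_clinical_scores(
    metric_per_subject: np.ndarray,
    true_r: float,
    seed: int | np.random.Generator | None,
    gain_mean: float | np.ndarray = 0.0,
    gain_sd: float = 1.0,
    pre: np.ndarray | None = None,
) -> np.ndarray:
    """Clinical gains with a chosen population correlation to a metric.

    ``gain = gain_mean + gain_sd · (r · z(metric) + √(1−r²) · ε)`` with
    ``ε ~ N(0,1)``, so the population correlation with the metric is exactly
    ``true_r``. When ``pre`` scores are supplied, returns post scores
    ``clip(pre + gain, 0, 66)`` and warns if more than 1% of scores clip
    (clipping attenuates the realized correlation); otherwise returns the
    raw gains.
    """
    if abs(true_r) > 1:
        raise ValueError("|true_r| must be <= 1")
    metric = np.asarray(metric_per_subject, dtype=np.float64)
    rng = np.random.default_rng(seed)
    sd = metric.std()
    z = (metric - metric.mean()) / sd if sd > 0 else np.zeros_like(metric)
    eps = rng.standard_normal(metric.size)
    gain = np.asarray(gain_mean) + gain_sd * (
        true_r * z + np.sqrt(1.0 - true_r**2) * eps
    )
    if pre is None:
        return gain
    post = np.asarray(pre, dtype=np.float64) + gain
    clipped = (post < 0) | (post > 66)
    if clipped.mean() > 0.01:
        warnings.warn(
            f"{clipped.sum()} of {post.size} post scores clipped to [0, 66]; "
            "the realized clinical correlation is attenuated", stacklevel=2,
        )
    return np.clip(post, 0.0, 66.0)


# ---------------------------------------------------------------------------
# cohort generation


def _effect_components(
    spec: CohortSpec,
    maps_flat: np.ndarray,
    group: str,
    w_subject: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject map modifications encoding the group effects.

    Returns ``(subject_maps, extra_maps)``: a copy of the base maps with
    target-network loadings redistributed, plus extra component maps whose
    courses are drawn by the caller. The clustering effect gives every
    subject's target network random coupling courses, at full strength in
    controls and shifted down in the BCI arm; the assortativity effect
    moves a variance fraction ``w_subject`` of each of the network's two
    amplitude modules onto a module-wide course (all subjects).
    """
    eff = spec.effect
    labels = RSN_LABELS[: spec.n_networks]
    base = maps_flat.copy()
    extras: list[np.ndarray] = []

    if eff.enabled and eff.gamma_coupling > 0 and eff.gamma_network in labels:
        c = labels.index(eff.gamma_network)
        m = base[c]
        support = np.nonzero(m >= 0.25 * m.max())[0]
        beta = eff.gamma_coupling * (eff.gamma_shift if group == "BCI" else 1.0)
        if beta > 0 and support.size:
            scale = beta / np.sqrt(eff.gamma_n_courses)
            for _ in range(eff.gamma_n_courses):
                load = np.zeros_like(m)
                load[support] = scale * m[support] * rng.standard_normal(support.size)
                extras.append(load)

    if eff.enabled and w_subject > 0 and eff.assort_network in labels:
        c = labels.index(eff.assort_network)
        m = base[c]
        support = np.nonzero(m >= 0.25 * m.max())[0]
        w = min(max(w_subject, 0.0), 0.95)
        order = support[np.argsort(-m[support])]
        for module in np.array_split(order, 2):
            mod_map = np.zeros_like(m)
            mod_map[module] = maps_flat[c, module] * np.sqrt(w)
            extras.append(mod_map)
        base[c, support] = m[support] * np.sqrt(1.0 - w)

    extra = (np.asarray(extras) if extras
             else np.empty((0, maps_flat.shape[1])))
    return base, extra


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full two-arm cohort of volumes plus its clinical table.

    Deterministic for a fixed ``spec.seed``: every subject's courses, noise,
    effect components and clinical scores derive from independent child
    streams of one seed sequence.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_subjects, ss_clinical, ss_covariates = root.spawn(3)

    maps = rsn_template_maps(spec.grid_dims, spec.n_networks)
    maps_flat = maps.reshape(spec.n_networks, -1)
    labels = RSN_LABELS[: spec.n_networks]
    eff = spec.effect

    n_total = 2 * spec.n_per_group
    groups = ["control"] * spec.n_per_group + ["BCI"] * spec.n_per_group
    subject_ids = [f"sub{i + 1:03d}" for i in range(n_total)]

    subjects: list[VolumeSeries] = []
    true_courses: dict[str, np.ndarray] = {}
    assort_latent = np.empty(n_total)

    child_seeds = ss_subjects.spawn(n_total)
    cov_rng = np.random.default_rng(ss_covariates)
    lesion_sides = cov_rng.choice(["left", "right"], size=n_total)
    ages = np.clip(cov_rng.normal(55.0, 12.0, size=n_total), 25, 85).round()
    sexes = cov_rng.choice(["M", "F"], size=n_total, p=[0.775, 0.225])
    etiologies = cov_rng.choice(["ischemic", "hemorrhagic"], size=n_total, p=[0.825, 0.175])

    for i, (sid, group) in enumerate(zip(subject_ids, groups)):
        rng = np.random.default_rng(child_seeds[i])
        courses = smoothed_courses(spec.n_timepoints, spec.n_networks, rng)

        if eff.enabled:
            shift = eff.assort_gain if group == "BCI" else 0.0
            w_i = max(0.0, eff.assort_base + shift + eff.assort_subject_sd * rng.standard_normal())
        else:
            w_i = 0.0
        assort_latent[i] = w_i

        base_maps, extra_maps = _effect_components(spec, maps_flat, group, w_i, rng)
        n_extra = extra_maps.shape[0]
        if n_extra:
            extra_courses = smoothed_courses(spec.n_timepoints, n_extra, rng)
            all_maps = np.concatenate(
                [base_maps.reshape(spec.n_networks, *spec.grid_dims),
                 extra_maps.reshape(n_extra, *spec.grid_dims)], axis=0,
            )
            all_courses = np.concatenate([courses, extra_courses], axis=1)
        else:
            all_maps = base_maps.reshape(spec.n_networks, *spec.grid_dims)
            all_courses = courses

        # right-lesion anatomy is generated mirrored, so the hemispheric
        # flip of preprocessing restores every network to canonical position
        if lesion_sides[i] == "right":
            all_maps = np.flip(all_maps, axis=1)

        subjects.append(
            synthesize_subject(
                all_maps,
                all_courses,
                spec.noise_sigma,
                rng,
                tr_seconds=spec.tr_seconds,
                subject_id=sid,
                group=group,
                lesion_side=str(lesion_sides[i]),
            )
        )
        true_courses[sid] = courses

    # clinical scores: pre from the emulated baseline distribution, gains
    # anchored to the two arms' mean improvements and correlated with the
    # assortativity-coupling latent
    clin_rng = np.random.default_rng(ss_clinical)
    pre = np.clip(clin_rng.normal(20.8, 11.0, size=n_total), 0.0, 66.0)
    gain_mean = np.where(np.asarray(groups) == "BCI", 9.1, 1.65)
    post = generate_clinical_scores(
        assort_latent,
        eff.clinical_true_r if eff.enabled else 0.0,
        clin_rng,
        gain_mean=gain_mean,
        gain_sd=4.5,
        pre=pre,
    )

    records = [
        ClinicalRecord(
            subject_id=sid,
            group=group,
            fmaue_pre=float(pre[i]),
            fmaue_post=float(post[i]),
            age=float(ages[i]),
            sex=str(sexes[i]),
            lesion_side=str(lesion_sides[i]),
            etiology=str(etiologies[i]),
        )
        for i, (sid, group) in enumerate(zip(subject_ids, groups))
    ]
    clinical = pd.DataFrame([vars(r) for r in records])

    return Cohort(
        subjects=subjects,
        clinical=clinical,
        template_maps=maps,
        labels=labels,
        true_courses=true_courses,
        assort_latent=assort_latent,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# fixture graphs


def generate_toy_graph(kind: str, params: dict, seed: int | None = None) -> BinaryGraph:
    """Canonical fixture graphs with documented closed-form metrics.

    Kinds: ``complete`` (n), ``ring_lattice`` (n, k even), ``star`` (n total
    nodes), ``path`` (n), ``watts_strogatz`` (n, k, p), ``erdos_renyi``
    (n, p).
    """
    p = dict(params)
    n = int(p.get("n", 0))
    if kind == "complete":
        if n < 2:
            raise ValueError("complete graph needs n >= 2")
        g = nx.complete_graph(n)
    elif kind == "ring_lattice":
        k = int(p["k"])
        if k % 2 or k <= 0 or k >= n:
            raise ValueError("ring lattice needs even k with 0 < k < n")
        g = nx.circulant_graph(n, list(range(1, k // 2 + 1)))
    elif kind == "star":
        if n < 2:
            raise ValueError("star needs n >= 2")
        g = nx.star_graph(n - 1)
    elif kind == "path":
        if n < 2:
            raise ValueError("path needs n >= 2")
        g = nx.path_graph(n)
    elif kind == "watts_strogatz":
        k = int(p["k"])
        if k % 2 or k >= n:
            raise ValueError("watts_strogatz needs even k < n")
        g = nx.watts_strogatz_graph(n, k, float(p["p"]), seed=seed)
    elif kind == "erdos_renyi":
        if n < 2:
            raise ValueError("erdos_renyi needs n >= 2")
        g = nx.gnp_random_graph(n, float(p["p"]), seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    return BinaryGraph.from_networkx(g)
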