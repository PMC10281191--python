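"""End-to-end orchestration: simulate → preprocess → ICA → graphs → statistics.

One :class:`RunConfig` (YAML-serializable) drives the whole analysis under a
single seed; a :class:`RunReport` collects every table the run produced plus
per-stage provenance, and can be written out as TSV + JSON + a readable text
summary. Parameter defaults follow the emulated study design (discard 10
volumes, 6 mm FWHM, 40 components with 100 ICA repetitions, sparsity
0.05–0.40 in 0.01 steps, 100 rewired nulls, uncorrected α = 0.05); the test
profile shrinks the cohort, the component count, the ICA repetitions, the
sparsity grid and the null count to desk scale for fast runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphs, ica, metrics, preprocess, stats, synthetic
from .volume import VolumeSeries

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report",
           "subnetwork_auc_table", "ground_truth_subnetworks"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run. Defaults match the emulated design."""

    # cohort (synthetic) or input paths
    n_per_group: int = 20
    n_timepoints: int = 200
    grid_dims: tuple[int, int, int] = (18, 18, 18)
    n_networks: int = 7
    noise_sigma: float = 0.5
    effect_enabled: bool = True
    volumes_dir: str | None = None  # load NIfTI + clinical instead of simulating
    clinical_tsv: str | None = None
    # preprocessing
    discard_n: int = 10
    fwhm_mm: float = 6.0
    # ICA
    n_components: int = 40
    n_runs: int = 100
    n_subject_pcs: int = 60
    ica_algorithm: str = "infomax"
    z_threshold: float = 2.0
    match_floor: float = 0.3
    # graphs
    downsample_factor: int = 1
    sparsity_low: float = 0.05
    sparsity_high: float = 0.40
    sparsity_step: float = 0.01
    n_nulls: int = 100
    n_swap_factor: int = 100
    rank_by_abs: bool = False
    lp_disconnected: str = "reachable"
    # statistics
    alpha: float = 0.05
    correction: str = "none"
    # bookkeeping
    seed: int = 0
    outdir: str = "rsnet_out"

    @classmethod
    def test_profile(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Desk-scale profile: small cohort, few ICA runs, coarse sweep."""
        base = dict(
            n_per_group=4,
            n_timepoints=120,
            grid_dims=(14, 14, 14),
            n_components=10,
            n_runs=5,
            n_subject_pcs=20,
            discard_n=5,
            downsample_factor=2,
            sparsity_step=0.05,
            n_nulls=10,
            n_swap_factor=10,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def sparsity_grid(self) -> np.ndarray:
        return graphs.sparsity_grid(self.sparsity_low, self.sparsity_high,
                                    self.sparsity_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid_dims" in raw:
            raw["grid_dims"] = tuple(raw["grid_dims"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    config: dict
    provenance: list[dict]
    subnetworks: pd.DataFrame
    auc_table: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    clinical_tests: pd.DataFrame
    warnings: list[str]
    elapsed_seconds: float

    def summary_json(self) -> dict:
        return {
            "config": self.config,
            "provenance": self.provenance,
            "n_subnetworks": int(len(self.subnetworks)),
            "subnetworks": self.subnetworks.to_dict(orient="records"),
            "significant": self.comparisons.loc[
                self.comparisons["significant"],
                ["network", "metric", "t", "p"],
            ].to_dict(orient="records"),
            "correlations_significant": self.correlations.loc[
                self.correlations["p"] < self.config.get("alpha", 0.05),
                ["network", "metric", "R", "p"],
            ].to_dict(orient="records"),
            "clinical_tests": self.clinical_tests.to_dict(orient="records"),
            "warnings": self.warnings,
            "elapsed_seconds": round(self.elapsed_seconds, 2),
        }

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "auc": self.auc_table.round(10).to_csv(index=False),
                "cmp": self.comparisons.round(10).to_csv(index=False),
                "cor": self.correlations.round(10).to_csv(index=False),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# reusable stage helpers


def ground_truth_subnetworks(
    cohort: synthetic.Cohort, z_threshold: float = 2.0
) -> list[ica.SubnetworkDefinition]:
    """Subnetwork definitions from the generator's own template maps.

    Bypasses the ICA stage: node sets are the voxels where the z-scored
    generating template exceeds the threshold. Used for effect-recovery and
    calibration runs where component estimation is not under test.
    """
    subnets = []
    for c, label in enumerate(cohort.labels):
        mask = synthetic.template_node_mask(cohort.template_maps[c], z_threshold)
        subnets.append(
            ica.SubnetworkDefinition(
                label=label, node_voxels=np.argwhere(mask), source_component=c
            )
        )
    return subnets


def subnetwork_auc_table(
    volumes: list[VolumeSeries],
    subnets: list[ica.SubnetworkDefinition],
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """AUC of all ten metrics for every subject × subnetwork.

    Returns a long table (subject, group, network, metric, auc) and a list
    of warnings about undefined metric values.
    """
    grid = config.sparsity_grid()
    rows = []
    notes: list[str] = []
    for vol in volumes:
        for sub in subnets:
            filled = ica.extract_node_timeseries(sub, vol)
            filled = graphs.downsample_nodes(filled, config.downsample_factor)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cm = graphs.connectivity_matrix(filled.node_timeseries)
                curves = metrics.metric_curves(
                    cm,
                    grid=grid,
                    n_nulls=config.n_nulls,
                    n_swap_factor=config.n_swap_factor,
                    seed=rng,
                    rank_by_abs=config.rank_by_abs,
                    lp_disconnected=config.lp_disconnected,
                )
            for name, curve in curves.items():
                n_undef = int(np.sum(~np.isfinite(curve.values)))
                if n_undef:
                    notes.append(
                        f"{vol.subject_id}/{sub.label}/{name}: {n_undef} undefined "
                        f"grid points excluded from AUC"
                    )
                try:
                    a = curve.auc
                except ValueError:
                    a = np.nan
                    notes.append(f"{vol.subject_id}/{sub.label}/{name}: AUC undefined")
                rows.append({
                    "subject": vol.subject_id,
                    "group": vol.group,
                    "network": sub.label,
                    "metric": name,
                    "auc": a,
                })
    return pd.DataFrame(rows), notes


def _clinical_tests(clinical: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Baseline-table and pre/post outcome statistics from the clinical TSV."""
    rows = []
    g = {name: df for name, df in clinical.groupby("group")}
    a, b = g["control"], g["BCI"]

    for col in ("age", "fmaue_pre"):
        res = stats.two_sample_t_raw(a[col], b[col], context=col)
        rows.append({"variable": col, "statistic": "t", "value": res.value,
                     "p": res.p})
    for col, level in (("sex", "M"), ("lesion_side", "left"), ("etiology", "ischemic")):
        table = [
            [(a[col] == level).sum(), (b[col] == level).sum()],
            [(a[col] != level).sum(), (b[col] != level).sum()],
        ]
        try:
            res = stats.chi_square_2x2(table, yates=True, context=col)
            rows.append({"variable": col, "statistic": "chi2", "value": res.value,
                         "p": res.p})
        except ValueError:
            res = stats.fisher_exact_2x2(table, context=col)
            rows.append({"variable": col, "statistic": "fisher_odds",
                         "value": res.value, "p": res.p})

    anova = stats.anova_pre_post(raw={
        "control": (a["fmaue_pre"].to_numpy(), a["fmaue_post"].to_numpy()),
        "BCI": (b["fmaue_pre"].to_numpy(), b["fmaue_post"].to_numpy()),
    })
    pre = stats.anova_pre_post(
        pre_a=stats.SummaryStat.from_values(a["fmaue_pre"]),
        pre_b=stats.SummaryStat.from_values(b["fmaue_pre"]),
        post_a=stats.SummaryStat.from_values(a["fmaue_post"]),
        post_b=stats.SummaryStat.from_values(b["fmaue_post"]),
    )
    for name, res in {**pre, **anova}.items():
        rows.append({"variable": f"fmaue_{name}", "statistic": res.statistic,
                     "value": res.value, "p": res.p})
    return pd.DataFrame(rows)


def _load_cohort(config: RunConfig) -> tuple[list[VolumeSeries], pd.DataFrame]:
    clinical = pd.read_csv(config.clinical_tsv, sep="\t")
    volumes = []
    for _, row in clinical.iterrows():
        path = Path(config.volumes_dir) / f"{row.subject_id}.nii.gz"
        if not path.exists():
            path = Path(config.volumes_dir) / f"{row.subject_id}.nii"
        volumes.append(
            VolumeSeries.from_nifti(
                path, subject_id=row.subject_id, group=row.group,
                lesion_side=row.lesion_side,
            )
        )
    return volumes, clinical


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order under one seed and collect the report."""
    t0 = time.time()
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_ica, ss_nulls = root.spawn(3)
    notes: list[str] = []
    provenance: list[dict] = []

    # -- stage 1: cohort ----------------------------------------------------
    if config.volumes_dir:
        volumes, clinical = _load_cohort(config)
        grid_dims = volumes[0].grid_dims
        provenance.append({"stage": "load_cohort", "n_subjects": len(volumes)})
    else:
        spec = synthetic.CohortSpec(
            n_per_group=config.n_per_group,
            n_timepoints=config.n_timepoints,
            grid_dims=config.grid_dims,
            n_networks=config.n_networks,
            noise_sigma=config.noise_sigma,
            effect=(synthetic.GroupEffectSpec() if config.effect_enabled
                    else synthetic.GroupEffectSpec.off()),
            seed=int(ss_cohort.generate_state(1)[0] % (2**31)),
        )
        cohort = synthetic.generate_cohort(spec)
        volumes, clinical = cohort.subjects, cohort.clinical
        grid_dims = config.grid_dims
        provenance.append({"stage": "simulate_cohort",
                           "n_subjects": len(volumes),
                           "n_timepoints": config.n_timepoints})
        if config.n_per_group < 10:
            notes.append(
                f"n_per_group={config.n_per_group}: group tests are underpowered "
                "at this toy scale"
            )

    # -- stage 2: preprocessing --------------------------------------------
    pre_volumes = []
    for v in volumes:
        pv, prov = preprocess.preprocess_subject(
            v, discard_n=config.discard_n, fwhm_mm=config.fwhm_mm
        )
        pre_volumes.append(pv)
    provenance.append({"stage": "preprocess", "steps": prov,
                       "n_subjects": len(pre_volumes)})

    # -- stage 3: group ICA and subnetwork selection ------------------------
    n_subject_pcs = min(config.n_subject_pcs, pre_volumes[0].n_timepoints)
    gpca = ica.group_pca_reduce(pre_volumes, n_subject_pcs, config.n_components)
    comps = ica.run_stabilized_ica(
        gpca,
        n_runs=config.n_runs,
        seed=np.random.default_rng(ss_ica),
        algorithm=config.ica_algorithm,
    )
    templates = {
        label: m
        for label, m in zip(
            synthetic.RSN_LABELS[: config.n_networks],
            synthetic.rsn_template_maps(grid_dims, config.n_networks),
        )
    }
    subnets = ica.select_subnetworks(
        comps, templates, z_threshold=config.z_threshold,
        match_floor=config.match_floor,
    )
    provenance.append({
        "stage": "group_ica",
        "n_components": comps.n_components,
        "n_runs": config.n_runs,
        "retained_variance": round(gpca.retained_variance, 6),
        "stability": comps.stability_report(),
    })
    subnet_df = pd.DataFrame([
        {"network": s.label, "n_nodes": s.n_nodes,
         "source_component": s.source_component,
         "stability": float(comps.stability_index[s.source_component])}
        for s in subnets
    ])

    # -- stage 4: graphs and metric AUCs ------------------------------------
    auc_table, auc_notes = subnetwork_auc_table(
        pre_volumes, subnets, config, np.random.default_rng(ss_nulls)
    )
    notes.extend(auc_notes)
    provenance.append({"stage": "graph_metrics",
                       "sparsity_grid": [round(float(s), 4) for s in config.sparsity_grid()],
                       "n_nulls": config.n_nulls})

    # -- stage 5: statistics -------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        comparisons = stats.compare_networks(
            auc_table, alpha=config.alpha, correction=config.correction
        )
        notes.extend(str(w.message) for w in caught)

    gain = (clinical.set_index("subject_id")["fmaue_post"]
            - clinical.set_index("subject_id")["fmaue_pre"])
    cor_rows = []
    for (network, metric), cell in auc_table.groupby(["network", "metric"]):
        merged = cell.dropna(subset=["auc"]).set_index("subject")
        if len(merged) < 3:
            continue
        try:
            res = stats.pearson_correlation(
                merged["auc"].to_numpy(), gain.loc[merged.index].to_numpy()
            )
        except ValueError:
            continue
        cor_rows.append({"network": network, "metric": metric, "R": res.R,
                         "p": res.p, "n": res.n})
    correlations = pd.DataFrame(cor_rows)
    clinical_tests = _clinical_tests(clinical, config.alpha)
    provenance.append({"stage": "group_stats", "alpha": config.alpha,
                       "correction": config.correction})

    return RunReport(
        config=config.to_dict(),
        provenance=provenance,
        subnetworks=subnet_df,
        auc_table=auc_table,
        comparisons=comparisons,
        correlations=correlations,
        clinical_tests=clinical_tests,
        warnings=notes,
        elapsed_seconds=time.time() - t0,
    )


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Persist the report: TSV tables, a JSON summary, a readable text file."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("subnetworks", report.subnetworks),
        ("auc_table", report.auc_table),
        ("comparisons", report.comparisons),
        ("correlations", report.correlations),
        ("clinical_tests", report.clinical_tests),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)

    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(report.summary_json(), fh, indent=2, sort_keys=True)
    paths.append(p)

    lines = [
        "rsnet pipeline report",
        "=====================",
        f"subnetworks selected: {len(report.subnetworks)} "
        f"({', '.join(report.subnetworks['network'])})",
        "",
        "significant group differences (uncorrected):",
    ]
    sig = report.comparisons[report.comparisons["significant"]]
    if sig.empty:
        lines.append("  none")
    for _, r in sig.iterrows():
        lines.append(f"  {r.network} {r.metric}: t={r.t:+.3f}, p={r.p:.4f}")
    lines.append("")
    lines.append(f"warnings: {len(report.warnings)}")
    lines.extend(f"  {w}" for w in report.warnings[:20])
    p = out / "report.txt"
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths
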