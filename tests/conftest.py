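"""Shared fixtures: small synthetic cohorts and one cached pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from rsnet import graphs, ica, metrics, pipeline, preprocess, synthetic


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Tiny noise-free cohort: exact rank-7 mixtures, no group effect.

    Subjects are hemisphere-flipped into canonical orientation, as the
    pipeline does before its ICA stage.
    """
    spec = synthetic.CohortSpec(
        n_per_group=3, n_timepoints=100, grid_dims=(12, 12, 12),
        noise_sigma=0.0, effect=synthetic.GroupEffectSpec.off(), seed=7,
    )
    cohort = synthetic.generate_cohort(spec)
    cohort.subjects = [preprocess.flip_hemisphere(v) for v in cohort.subjects]
    return cohort


@pytest.fixture(scope="session")
def test_profile_report():
    """One full pipeline run at the desk-scale test profile (shared)."""
    return pipeline.run_pipeline(pipeline.RunConfig.test_profile(seed=0))


def gamma_auc_by_group(
    cohort: synthetic.Cohort,
    network: str,
    seed: int,
    grid: np.ndarray,
    n_nulls: int = 6,
    n_swap_factor: int = 10,
    downsample: int = 2,
) -> dict[str, list[float]]:
    """Normalized-clustering AUC per subject via the ground-truth node path."""
    subnets = {s.label: s for s in pipeline.ground_truth_subnetworks(cohort)}
    target = subnets[network]
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {"control": [], "BCI": []}
    for vol in cohort.subjects:
        pv, _ = preprocess.preprocess_subject(vol, discard_n=10, fwhm_mm=6.0)
        sub = graphs.downsample_nodes(ica.extract_node_timeseries(target, pv), downsample)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = graphs.connectivity_matrix(sub.node_timeseries)
            vals = []
            for s in grid:
                g = graphs.threshold_by_sparsity(cm, float(s))
                nulls = metrics.rewire_null(g, n_nulls, n_swap_factor, seed=rng)
                try:
                    gm, _, _ = metrics.normalize_smallworld(g, nulls)
                except ValueError:
                    gm = float("nan")
                vals.append(gm)
        out[vol.group].append(metrics.auc(np.asarray(vals), grid))
    return out
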