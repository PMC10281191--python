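"""Synthetic cohort generator: mixing model, clinical scores, injected effects."""

import numpy as np
import pytest

from rsnet import stats, synthetic
from rsnet.synthetic import (
    CohortSpec,
    GroupEffectSpec,
    generate_clinical_scores,
    generate_cohort,
    generate_toy_graph,
    rsn_template_maps,
    smoothed_courses,
    synthesize_subject,
)

def _small_spec(**kw):
    base = dict(n_per_group=2, n_timepoints=40, grid_dims=(8, 8, 8), seed=5)
    base.update(kw)
    return CohortSpec(**base)


class TestCohortSpec:
    def test_defaults_match_study_design(self):
        spec = CohortSpec()
        assert spec.n_per_group == 20
        assert spec.n_timepoints == 200
        assert spec.tr_seconds == 3.0
        assert spec.n_networks == 7

    @pytest.mark.parametrize("kw", [
        dict(n_per_group=1),
        dict(n_timepoints=5),
        dict(noise_sigma=-0.1),
        dict(grid_dims=(5, 8, 8)),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            _small_spec(**kw)

    def test_unknown_effect_label_rejected(self):
        with pytest.raises(ValueError, match="unknown network label"):
            GroupEffectSpec(gamma_network="XXX")


class TestGenerateCohort:
    def test_cohort_dimensions(self):
        coh = generate_cohort(_small_spec(n_per_group=3))
        assert len(coh.subjects) == 6
        assert all(v.n_timepoints == 40 for v in coh.subjects)
        assert list(coh.clinical["group"]).count("control") == 3
        assert set(coh.clinical.columns) >= {
            "subject_id", "group", "fmaue_pre", "fmaue_post",
            "age", "sex", "lesion_side", "etiology",
        }

    def test_seeded_cohorts_bit_identical(self):
        a = generate_cohort(_small_spec())
        b = generate_cohort(_small_spec())
        for va, vb in zip(a.subjects, b.subjects):
            assert np.array_equal(va.data, vb.data)
        assert a.clinical.equals(b.clinical)

    def test_noiseless_cohort_is_exact_mixture(self, noiseless_cohort):
        """Without noise, regressing voxels on the true courses leaves zero residual."""
        vol = noiseless_cohort.subjects[0]
        x = vol.timeseries_matrix()  # (t, voxels)
        courses = noiseless_cohort.true_courses[vol.subject_id]
        beta, *_ = np.linalg.lstsq(courses, x, rcond=None)
        assert np.max(np.abs(x - courses @ beta)) < 1e-9
        xc = x - x.mean(axis=0)
        assert np.linalg.matrix_rank(xc, tol=1e-8) == 7

    def test_fmaue_scores_bounded(self):
        coh = generate_cohort(_small_spec(n_per_group=5))
        assert coh.clinical["fmaue_pre"].between(0, 66).all()
        assert coh.clinical["fmaue_post"].between(0, 66).all()


class TestSynthesizeSubject:
    def test_single_constant_component_reproduces_course(self):
        course = np.sin(np.linspace(0, 6, 50))[:, None]
        maps = np.ones((1, 6, 6, 6))
        v = synthesize_subject(maps, course, 0.0, seed=0)
        assert np.allclose(v.data, course[:, 0])

    def test_residual_variance_matches_noise_level(self):
        rng = np.random.default_rng(12)
        maps = rsn_template_maps((10, 10, 10), 3)
        courses = smoothed_courses(200, 3, rng)
        sigma = 0.7
        v = synthesize_subject(maps, courses, sigma, seed=3)
        x = v.timeseries_matrix()
        beta, *_ = np.linalg.lstsq(courses, x, rcond=None)
        resid = x - courses @ beta
        assert resid.var() == pytest.approx(sigma**2, rel=0.10)

    def test_orthogonal_courses_reproduce_map_overlap_correlations(self):
        # two components with orthogonal courses: voxel correlations are set
        # by the map weight vectors; check against brute-force Pearson
        t = np.arange(64)
        courses = np.column_stack([np.cos(2 * np.pi * t / 8),
                                   np.sin(2 * np.pi * t / 8)])
        maps = np.zeros((2, 6, 6, 6))
        maps[0, 0, 0, 0] = 1.0
        maps[1, 1, 0, 0] = 1.0
        maps[0, 2, 0, 0] = 1.0
        maps[1, 2, 0, 0] = 1.0  # voxel 2 loads both
        v = synthesize_subject(maps, courses, 0.0, seed=0)
        a = v.data[0, 0, 0]
        b = v.data[1, 0, 0]
        c = v.data[2, 0, 0]
        from oracles import pearson_formula
        w = np.array([[1, 0], [0, 1], [1, 1]], dtype=float)
        gram = courses.T @ courses
        def expected(i, j):
            num = w[i] @ gram @ w[j]
            return num / np.sqrt((w[i] @ gram @ w[i]) * (w[j] @ gram @ w[j]))
        assert pearson_formula(a, b) == pytest.approx(expected(0, 1), abs=1e-9)
        assert pearson_formula(a, c) == pytest.approx(expected(0, 2), abs=1e-9)

    def test_component_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            synthesize_subject(np.ones((2, 4, 4, 4)), np.ones((10, 3)), 0.0, 0)


class TestGenerateClinicalScores:
    def test_zero_correlation_independent(self):
        rng = np.random.default_rng(0)
        metric = rng.standard_normal(10_000)
        gains = generate_clinical_scores(metric, 0.0, seed=1)
        assert abs(np.corrcoef(metric, gains)[0, 1]) < 0.1

    def test_half_correlation_recovered_at_large_n(self):
        rng = np.random.default_rng(1)
        metric = rng.standard_normal(10_000)
        gains = generate_clinical_scores(metric, 0.5, seed=2)
        assert 0.47 <= np.corrcoef(metric, gains)[0, 1] <= 0.53

    def test_perfect_correlation_exact_without_clipping(self):
        rng = np.random.default_rng(2)
        metric = rng.standard_normal(500)
        gains = generate_clinical_scores(metric, 1.0, seed=3)
        assert np.corrcoef(metric, gains)[0, 1] == pytest.approx(1.0)

    def test_clipping_warns_when_frequent(self):
        metric = np.linspace(-3, 3, 200)
        pre = np.full(200, 60.0)
        with pytest.warns(UserWarning, match="clipped"):
            post = generate_clinical_scores(metric, 0.5, seed=4,
                                            gain_mean=20.0, gain_sd=5.0, pre=pre)
        assert post.max() <= 66.0


class TestToyGraphs:
    def test_complete_graph(self):
        g = generate_toy_graph("complete", {"n": 5})
        assert g.n_edges == 10
        assert np.all(g.degrees == 4)

    def test_ring_lattice(self):
        g = generate_toy_graph("ring_lattice", {"n": 20, "k": 4})
        assert g.n_edges == 40
        assert np.all(g.degrees == 4)

    def test_watts_strogatz_reproducible_mean_degree(self):
        a = generate_toy_graph("watts_strogatz", {"n": 100, "k": 8, "p": 0.1}, seed=13)
        b = generate_toy_graph("watts_strogatz", {"n": 100, "k": 8, "p": 0.1}, seed=13)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert a.degrees.mean() == pytest.approx(8.0)

    @pytest.mark.parametrize("kind,params", [
        ("complete", {"n": 1}),
        ("ring_lattice", {"n": 6, "k": 3}),
        ("watts_strogatz", {"n": 6, "k": 6, "p": 0.1}),
        ("nonsense", {"n": 5}),
    ])
    def test_invalid_kinds_rejected(self, kind, params):
        with pytest.raises(ValueError):
            generate_toy_graph(kind, params)


class TestInjectedEffects:
    def test_cohort_clinical_correlation_within_three_se(self):
        spec = CohortSpec(n_per_group=20, n_timepoints=40, grid_dims=(8, 8, 8), seed=31)
        coh = generate_cohort(spec)
        gain = coh.clinical["fmaue_post"] - coh.clinical["fmaue_pre"]
        res = stats.pearson_correlation(coh.assort_latent, gain)
        se = (1 - 0.5**2) / np.sqrt(40)
        assert abs(res.R - 0.5) <= 3 * se

    def test_population_effect_directions_at_large_n(self):
        """BCI target networks: lower normalized clustering, higher assortativity."""
        import warnings
        from rsnet import graphs as gmod, ica, metrics as mmod, pipeline, preprocess
        spec = CohortSpec(n_per_group=200, n_timepoints=100, grid_dims=(12, 12, 12),
                          seed=77)
        coh = generate_cohort(spec)
        subnets = {s.label: s for s in pipeline.ground_truth_subnetworks(coh)}
        rng = np.random.default_rng(9)
        res = {"control": {"gamma": [], "assort": []},
               "BCI": {"gamma": [], "assort": []}}
        for vol in coh.subjects:
            pv, _ = preprocess.preprocess_subject(vol, discard_n=10, fwhm_mm=6.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = ica.extract_node_timeseries(subnets["VN"], pv)
                cm = gmod.connectivity_matrix(sub.node_timeseries)
                g = gmod.threshold_by_sparsity(cm, 0.2)
                nulls = mmod.rewire_null(g, 6, 10, seed=rng)
                try:
                    gm, _, _ = mmod.normalize_smallworld(g, nulls)
                except ValueError:
                    gm = np.nan
                res[vol.group]["gamma"].append(gm)
                sub = ica.extract_node_timeseries(subnets["DAN"], pv)
                cm = gmod.connectivity_matrix(sub.node_timeseries)
                g = gmod.threshold_by_sparsity(cm, 0.2)
                res[vol.group]["assort"].append(mmod.assortativity(g))
        gam_c = np.array(res["control"]["gamma"])
        gam_b = np.array(res["BCI"]["gamma"])
        t_gamma = stats.two_sample_t_raw(gam_c[np.isfinite(gam_c)],
                                         gam_b[np.isfinite(gam_b)])
        assert np.nanmean(gam_c) > np.nanmean(gam_b)
        assert t_gamma.p < 0.01
        r_c = np.array(res["control"]["assort"])
        r_b = np.array(res["BCI"]["assort"])
        t_assort = stats.two_sample_t_raw(r_b[np.isfinite(r_b)],
                                          r_c[np.isfinite(r_c)])
        assert np.nanmean(r_b) > np.nanmean(r_c)
        assert t_assort.p < 0.01


class TestTemplates:
    def test_templates_peak_normalized_and_deterministic(self):
        a = rsn_template_maps((14, 14, 14))
        b = rsn_template_maps((14, 14, 14))
        assert a.shape == (7, 14, 14, 14)
        assert np.array_equal(a, b)
        assert np.allclose(a.max(axis=(1, 2, 3)), 1.0, atol=1e-6)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rsn_template_maps((4, 14, 14))
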