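"""Smoothness estimation, cluster finding, RFT p-values, permutation oracle."""

import numpy as np
import pytest
from scipy import stats

from longicort import make_icosphere
from longicort.change import smooth
from longicort.glm import build_design, fit_glm
from longicort.mesh import SurfaceMesh
from longicort.rft import (
    cluster_correct, cluster_p_rft, estimate_smoothness, find_clusters,
    forming_threshold, permutation_cluster_test,
)
from test_glm import _frame


def _smoothed_noise_residuals(mesh, n_subj, fwhm, seed):
    r = np.random.default_rng(seed)
    R = r.normal(size=(n_subj, mesh.n_vertices))
    return smooth(R, mesh, fwhm) if fwhm > 0 else R


class TestSmoothness:
    def test_recovers_known_fwhm(self, analysis_mesh):
        """Noise smoothed to 10 mm by the calibrated smoother reads back ~10 mm."""
        R = _smoothed_noise_residuals(analysis_mesh, 60, 10.0, seed=0)
        est = estimate_smoothness(R, analysis_mesh)
        assert abs(est.median_fwhm - 10.0) / 10.0 < 0.20
        assert est.total_resels > 0
        assert np.all(est.fwhm_triangle > 0)

    def test_rougher_field_means_more_resels(self, analysis_mesh):
        rough = estimate_smoothness(
            _smoothed_noise_residuals(analysis_mesh, 60, 0.0, seed=1), analysis_mesh)
        smooth_est = estimate_smoothness(
            _smoothed_noise_residuals(analysis_mesh, 60, 10.0, seed=1), analysis_mesh)
        assert rough.total_resels > smooth_est.total_resels

    def test_mesh_scaling_doubles_fwhm(self, small_mesh):
        R = _smoothed_noise_residuals(small_mesh, 40, 0.0, seed=2)
        est1 = estimate_smoothness(R, small_mesh)
        big = SurfaceMesh(small_mesh.vertices * 2, small_mesh.faces, "big")
        est2 = estimate_smoothness(R, big)
        assert est2.median_fwhm == pytest.approx(2 * est1.median_fwhm, rel=1e-6)

    def test_replicated_identical_residuals_rejected(self, small_mesh):
        row = np.random.default_rng(3).normal(size=small_mesh.n_vertices)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_smoothness(np.tile(row, (10, 1)), small_mesh)

    def test_too_few_subjects_rejected(self, small_mesh):
        with pytest.raises(ValueError, match="3 subjects"):
            estimate_smoothness(np.zeros((2, small_mesh.n_vertices)), small_mesh)


class TestFindClusters:
    def test_zero_map_no_clusters(self, small_mesh):
        assert find_clusters(np.zeros(small_mesh.n_vertices), 60, 0.05, small_mesh) == []

    def test_hand_built_patch_on_icosahedron(self):
        """A single supra-threshold connected patch is one cluster, exactly."""
        mesh = make_icosphere(0, 100.0)
        v0 = 0
        patch = np.r_[v0, mesh.vertex_neighbors(v0)[:2]]
        t = np.zeros(12)
        t[patch] = 3.0
        clusters = find_clusters(t, 60, 0.05, mesh)
        assert len(clusters) == 1
        assert set(clusters[0].vertices) == set(patch)
        assert clusters[0].sign == "positive"
        assert clusters[0].peak_t == 3.0

    def test_negation_swaps_signs_exactly(self, small_mesh, rng):
        t = smooth(rng.normal(size=small_mesh.n_vertices) * 3, small_mesh, 15.0)
        pos = find_clusters(t, 60, 0.05, small_mesh)
        neg = find_clusters(-t, 60, 0.05, small_mesh)
        by_members = lambda cl: sorted(tuple(sorted(c.vertices)) for c in cl)
        assert by_members(pos) == by_members(neg)
        signs = {tuple(sorted(c.vertices)): c.sign for c in pos}
        for c in neg:
            assert c.sign != signs[tuple(sorted(c.vertices))]

    def test_members_all_above_threshold_same_sign(self, small_mesh, rng):
        t = smooth(rng.normal(size=small_mesh.n_vertices) * 4, small_mesh, 12.0)
        u = forming_threshold(0.05, 60, True)
        for c in find_clusters(t, 60, 0.05, small_mesh):
            tv = t[c.vertices]
            assert np.all(tv >= u) if c.sign == "positive" else np.all(tv <= -u)


class _FakeSmoothness:
    def __init__(self, total_resels):
        self.total_resels = total_resels


class TestClusterP:
    def test_zero_extent_is_family_upper_bound(self):
        sm = _FakeSmoothness(500.0)
        p0 = cluster_p_rft(0.0, sm, 60, 2.0)
        p1 = cluster_p_rft(0.5, sm, 60, 2.0)
        assert 0 < p1 < p0 <= 1.0

    def test_monotone_in_extent(self):
        sm = _FakeSmoothness(800.0)
        ps = [cluster_p_rft(k, sm, 60, 2.0) for k in np.linspace(0, 20, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_monotone_in_search_region(self):
        big = cluster_p_rft(5.0, _FakeSmoothness(2000.0), 60, 2.0)
        small = cluster_p_rft(5.0, _FakeSmoothness(200.0), 60, 2.0)
        assert big > small

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            cluster_p_rft(1.0, _FakeSmoothness(100.0), 60, 0.0)

    def test_sign_symmetry_of_full_correction(self, analysis_mesh):
        r = np.random.default_rng(5)
        n = 40
        Y = smooth(r.normal(size=(n, analysis_mesh.n_vertices)), analysis_mesh, 10.0)
        d = build_design(_frame(n, seed=5), "group_model")
        fit = fit_glm(Y, d, "group")
        a = cluster_correct(fit.tmap, fit.residuals, analysis_mesh, fit.dof)
        b = cluster_correct(-fit.tmap, fit.residuals, analysis_mesh, fit.dof)
        key = lambda cl: sorted((tuple(sorted(c.vertices)), round(c.p, 12)) for c in cl)
        assert key(a) == key(b)


class TestPermutationOracle:
    def test_planted_effect_hits_floor(self, analysis_mesh):
        from longicort import SimulationConfig, simulate_cohort
        from longicort.change import ctspc_matrix

        cfg = SimulationConfig(seed=6, group_rate_delta=0.03,
                               planted_clusters=((10, 25.0, +1),))
        co = simulate_cohort(cfg, analysis_mesh)
        sp = smooth(ctspc_matrix(co.ct_t1, co.ct_t2, co.isi), analysis_mesh, 10.0)
        d = build_design(co.subjects.to_frame(), "group_model")
        clusters, _ = permutation_cluster_test(sp, d, "group", analysis_mesh,
                                               n_perm=99, seed=1)
        assert min(c.p for c in clusters) == pytest.approx(1 / 100)

    def test_seeded_determinism(self, small_mesh, rng):
        n = 30
        Y = rng.normal(size=(n, small_mesh.n_vertices))
        d = build_design(_frame(n, seed=7), "group_model")
        a, _ = permutation_cluster_test(Y, d, "group", small_mesh, n_perm=99, seed=3)
        b, _ = permutation_cluster_test(Y, d, "group", small_mesh, n_perm=99, seed=3)
        assert [c.p for c in a] == [c.p for c in b]

    def test_low_n_perm_warns(self, small_mesh, rng):
        Y = rng.normal(size=(30, small_mesh.n_vertices))
        d = build_design(_frame(30, seed=8), "group_model")
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_cluster_test(Y, d, "group", small_mesh, n_perm=20, seed=0)

    def test_null_permutation_p_roughly_uniform(self, small_mesh):
        """Smallest permutation p over null replicates is not systematically small."""
        mins = []
        for s in range(20):
            r = np.random.default_rng(2000 + s)
            Y = smooth(r.normal(size=(40, small_mesh.n_vertices)), small_mesh, 12.0)
            d = build_design(_frame(40, seed=s), "group_model")
            clusters, _ = permutation_cluster_test(Y, d, "group", small_mesh,
                                                   n_perm=99, seed=s)
            if clusters:
                mins.append(min(c.p for c in clusters))
        assert np.mean(np.array(mins) <= 0.05) < 0.35  # min over many clusters
        assert np.mean(mins) > 0.2
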