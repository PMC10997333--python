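"""Searchlight indexing, pattern whitening, data RDMs, model fits, and
cluster-based permutation inference."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sentstruct import synth
from sentstruct.geometry import model_rdm
from sentstruct.rsa import (FitMap, Mesh, SearchlightSpec, SourceEpochs,
                            data_rdm, fit_model, group_cluster_test,
                            multivariate_normalize, run_ssrsa,
                            searchlight_index, summary_maps)


@pytest.fixture(scope="module")
def grid_mesh():
    # regular 4-mm grid, 4 x 4 x 3 vertices
    xs, ys, zs = np.meshgrid(np.arange(4) * 4.0, np.arange(4) * 4.0,
                             np.arange(3) * 4.0, indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    return Mesh(vertex_ids=np.arange(len(coords)), coordinates=coords)


class TestSearchlightIndex:
    def test_isolated_vertex_alone(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        mesh = Mesh(np.arange(2), coords)
        nb = searchlight_index(mesh, np.arange(10.0), SearchlightSpec())
        assert list(nb.vertex_neighbors[0]) == [0]

    def test_pair_within_radius(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        mesh = Mesh(np.arange(2), coords)
        nb = searchlight_index(mesh, np.arange(10.0), SearchlightSpec())
        assert sorted(nb.vertex_neighbors[0]) == [0, 1]
        assert sorted(nb.vertex_neighbors[1]) == [0, 1]

    def test_grid_matches_brute_force(self, grid_mesh):
        nb = searchlight_index(grid_mesh, np.arange(10.0), SearchlightSpec())
        coords = grid_mesh.coordinates
        for i in range(grid_mesh.n_vertices):
            d = np.linalg.norm(coords - coords[i], axis=1)
            expected = sorted(np.flatnonzero(d <= 10.0))
            assert sorted(nb.vertex_neighbors[i]) == expected

    def test_windows_clipped_to_epoch(self, grid_mesh):
        times = np.arange(0, 600, 5.0)  # 200 Hz
        nb = searchlight_index(grid_mesh, times, SearchlightSpec())
        assert nb.window_slices[0] == (0, 7)
        assert nb.window_slices[-1] == (len(times) - 7, len(times))
        for c, (lo, hi) in zip(nb.window_centers, nb.window_slices):
            assert lo <= c < hi

    def test_empty_time_axis(self, grid_mesh):
        with pytest.raises(ValueError):
            searchlight_index(grid_mesh, [], SearchlightSpec())


class TestMultivariateNormalize:
    def test_identity_covariance_preserves_patterns(self, rng):
        X = rng.normal(size=(6, 4))
        residuals = rng.normal(size=(5000, 4))
        W = multivariate_normalize(X, residuals, shrinkage=0.0)
        # whitening by a near-identity covariance is a near-identity map
        assert np.allclose(W, X, atol=0.15)

    def test_diagonal_covariance_rescales(self, rng):
        residuals = rng.normal(size=(20000, 2)) * np.array([2.0, 1.0])
        X = np.array([[1.0, 1.0]])
        W = multivariate_normalize(X, residuals, shrinkage=0.0)
        assert W[0, 0] / W[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_whitened_residuals_near_identity(self, rng):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(C)
        residuals = rng.normal(size=(1000, 2)) @ L.T
        W = multivariate_normalize(residuals, residuals, shrinkage=0.0)
        cov = np.cov(W, rowvar=False)
        assert abs(cov[0, 1]) < 0.1

    def test_too_few_residuals(self):
        with pytest.raises(ValueError):
            multivariate_normalize(np.ones((2, 3)), np.ones((1, 3)))


class TestDataRdm:
    def test_identical_patterns_zero_distance(self, rng):
        p = rng.normal(size=6)
        rdm = data_rdm(np.stack([p, p, rng.normal(size=6)]))
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flipped_pattern_distance_two(self, rng):
        p = rng.normal(size=6)
        rdm = data_rdm(np.stack([p, -p, rng.normal(size=6)]))
        assert rdm.matrix[0, 1] == pytest.approx(2.0)

    def test_constant_pattern_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            data_rdm(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))


class TestFitModel:
    def test_identical_rdms(self, rng):
        rdm = model_rdm(rng.normal(size=8), "absolute_difference")
        assert fit_model(rdm, rdm) == pytest.approx(1.0)

    def test_rank_reversed(self):
        m = model_rdm(np.array([0.0, 1.0, 3.0, 6.0]), "absolute_difference")
        flipped = m.matrix.max() + m.matrix.min() - m.matrix
        np.fill_diagonal(flipped, 0)
        from sentstruct.geometry import RDM
        d = RDM(matrix=flipped)
        assert fit_model(m, d) == pytest.approx(-1.0)

    def test_four_condition_hand_ranked_oracle(self, rng):
        a = model_rdm(rng.normal(size=4), "absolute_difference")
        b = model_rdm(rng.normal(size=4), "absolute_difference")
        expected = spearmanr(a.condensed(), b.condensed()).statistic
        assert fit_model(a, b) == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        from sentstruct.geometry import RDM
        a = model_rdm(rng.normal(size=6), "absolute_difference")
        b = model_rdm(rng.normal(size=6), "absolute_difference")
        warped = RDM(matrix=np.sqrt(b.matrix))
        assert fit_model(a, warped) == pytest.approx(fit_model(a, b))

    def test_size_mismatch(self, rng):
        a = model_rdm(rng.normal(size=4), "absolute_difference")
        b = model_rdm(rng.normal(size=5), "absolute_difference")
        with pytest.raises(ValueError):
            fit_model(a, b)

    def test_condition_order_mismatch(self, rng):
        a = model_rdm(rng.normal(size=4), "absolute_difference",
                      condition_ids=list("abcd"))
        b = model_rdm(rng.normal(size=4), "absolute_difference",
                      condition_ids=list("abdc"))
        with pytest.raises(ValueError, match="order"):
            fit_model(a, b)


class TestRunSsrsa:
    def test_degenerate_searchlight_reduces_to_fit_model(self, rng):
        mesh = Mesh(np.arange(1), np.zeros((1, 3)))
        data = rng.normal(size=(1, 8, 1, 5))
        ep = SourceEpochs(data=data, sampling_rate=200.0)
        model = model_rdm(rng.normal(size=8), "absolute_difference")
        # a single window covering the whole epoch
        spec = SearchlightSpec(temporal_radius_ms=1000.0, time_stride=5)
        fm = run_ssrsa(ep, model, mesh, spec)
        d = data_rdm(data[0, :, 0, :])
        assert fm.rho[0, 0, 0] == pytest.approx(fit_model(model, d))

    def test_pure_noise_mean_rho_near_zero(self, rng):
        mesh = synth.generate_mesh(12, seed=0, extent_mm=15)
        data = rng.normal(size=(12, 30, 12, 20))
        ep = SourceEpochs(data=data, sampling_rate=200.0)
        model = model_rdm(rng.normal(size=30), "absolute_difference")
        fm = run_ssrsa(ep, model, mesh, SearchlightSpec(time_stride=10))
        mean = np.nanmean(fm.rho)
        sem = np.nanstd(np.nanmean(fm.rho, axis=(1, 2))) / np.sqrt(12)
        assert abs(mean) < 3 * max(sem, 1e-3)

    def test_planted_effect_elevates_rho_inside(self, small_config):
        cfg = small_config
        recs = synth.target_records(synth.generate_stimuli(cfg))
        ids = [r.sentence_id for r in recs]
        sched = np.stack([synth.depth_schedule(r, 9) for r in recs])
        model = model_rdm(sched, "cosine_distance", condition_ids=ids)
        mesh = synth.generate_mesh(cfg.n_vertices, seed=5, extent_mm=22)
        verts = np.array([0, 3, 7, 9])
        eff = synth.EffectSpec(verts, (40, 80), model, effect_size=1.0)
        ep = synth.generate_epochs(cfg, mesh, ids, [eff], seed=6)
        fm = run_ssrsa(ep, model, mesh, SearchlightSpec(time_stride=20))
        centers = fm.window_centers
        in_c = [i for i, c in enumerate(centers) if 40 <= c < 80]
        out_c = [i for i, c in enumerate(centers) if c < 30 or c >= 90]
        inside = np.nanmean(fm.rho[:, verts][:, :, in_c], axis=(1, 2))
        others = np.setdiff1d(np.arange(cfg.n_vertices), verts)
        outside = np.nanmean(fm.rho[:, others][:, :, out_c], axis=(1, 2))
        # paired across participants: inside beats outside for everyone
        assert np.all(inside > outside)


class TestGroupClusterTest:
    def test_all_zero_fits_no_clusters(self):
        mesh = synth.generate_mesh(10, seed=1, extent_mm=15)
        fm = FitMap(rho=np.zeros((6, 10, 4)), window_centers=np.arange(4))
        res = group_cluster_test(fm, mesh, n_perm=100, seed=0)
        assert res.clusters == []
        assert not res.significant_mask.any()

    def test_strong_planted_cluster_detected(self, rng):
        mesh = synth.generate_mesh(30, seed=2, extent_mm=20)
        rho = rng.normal(0, 0.1, size=(12, 30, 6))
        rho[:, :10, 2:4] += 0.5  # strong effect in 10 vertices, 2 windows
        fm = FitMap(rho=rho.clip(-1, 1), window_centers=np.arange(6))
        res = group_cluster_test(fm, mesh, n_perm=500, seed=3)
        sig = [c for c in res.clusters if c["p"] < 0.05]
        assert sig
        sig_vertices = {v for c in sig for v, _ in c["nodes"]}
        # all planted vertices recovered; only a handful of chance
        # neighbors absorbed into the significant clusters
        assert len(sig_vertices & set(range(10))) >= 8
        assert len(sig_vertices - set(range(10))) <= 5

    def test_exhaustive_flips_warning(self, rng):
        mesh = synth.generate_mesh(5, seed=3, extent_mm=15)
        fm = FitMap(rho=rng.normal(0, 0.2, size=(3, 5, 2)).clip(-1, 1),
                    window_centers=np.arange(2))
        with pytest.warns(UserWarning, match="exhaustive"):
            group_cluster_test(fm, mesh, n_perm=100, seed=0)

    def test_needs_two_participants(self):
        mesh = synth.generate_mesh(4, seed=0)
        fm = FitMap(rho=np.zeros((1, 4, 2)), window_centers=np.arange(2))
        with pytest.raises(ValueError):
            group_cluster_test(fm, mesh, n_perm=10)


class TestSummaryMaps:
    def _result(self):
        from sentstruct.rsa import ClusterResult
        t_map = np.zeros((4, 5))
        t_map[1, 2] = 3.0
        t_map[1, 3] = 3.0
        mask = np.zeros((4, 5), bool)
        mask[1, 2] = mask[1, 3] = True
        clusters = [{"nodes": [(1, 2), (1, 3)], "mass": 6.0, "p": 0.01}]
        return ClusterResult(t_map=t_map, threshold=2.0, clusters=clusters,
                             significant_mask=mask,
                             null_max_mass=np.zeros(10), cluster_alpha=0.05)

    def test_single_vertex_t_mass(self):
        out = summary_maps(self._result())
        assert out["vertex_t_mass"][1] == pytest.approx(6.0)
        assert np.all(out["vertex_t_mass"][[0, 2, 3]] == 0)

    def test_cluster_series_matches_brute_force(self):
        out = summary_maps(self._result())
        series = out["cluster_t_mass_series"][0]["t_mass_series"]
        assert np.allclose(series, [0, 0, 3.0, 3.0, 0])

    def test_empty_mask_empty_summaries(self):
        from sentstruct.rsa import ClusterResult
        res = ClusterResult(t_map=np.zeros((3, 2)), threshold=2.0,
                            clusters=[], significant_mask=np.zeros((3, 2), bool),
                            null_max_mass=np.zeros(5), cluster_alpha=0.05)
        out = summary_maps(res)
        assert np.all(out["vertex_t_mass"] == 0)
        assert out["cluster_t_mass_series"] == []

    def test_roi_peak_series(self):
        out = summary_maps(self._result(),
                           region_labels=np.array(["a", "a", "b", "b"]))
        assert out["roi_peak_t"]["a"][2] == pytest.approx(3.0)


class TestContainers:
    def test_epochs_round_trip(self, tmp_path, rng):
        ep = SourceEpochs(data=rng.normal(size=(2, 3, 4, 5)),
                          sampling_rate=200.0, epoch_label="MV",
                          sentence_ids=("a", "b", "c"))
        ep.save(tmp_path / "ep.h5")
        back = SourceEpochs.load(tmp_path / "ep.h5")
        assert np.allclose(back.data, ep.data)
        assert back.sentence_ids == ep.sentence_ids
        assert back.epoch_label == "MV"

    def test_fitmap_round_trip(self, tmp_path, rng):
        fm = FitMap(rho=rng.uniform(-1, 1, size=(2, 3, 4)),
                    window_centers=np.arange(4), model_label="m")
        fm.save(tmp_path / "fm.h5")
        back = FitMap.load(tmp_path / "fm.h5")
        assert np.allclose(back.rho, fm.rho)
        assert back.model_label == "m"

    def test_mesh_round_trip(self, tmp_path):
        mesh = synth.generate_mesh(8, seed=4)
        mesh.save(tmp_path / "mesh.tsv")
        back = Mesh.load(tmp_path / "mesh.tsv")
        assert np.allclose(back.coordinates, mesh.coordinates)
        assert list(back.region_labels) == list(mesh.region_labels)

    def test_rho_bounds_enforced(self):
        with pytest.raises(ValueError):
            FitMap(rho=np.full((1, 1, 1), 1.5), window_centers=np.arange(1))
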