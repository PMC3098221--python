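"""Kernel-PCA, flow fields, slope fits, escape typing and correlation dimension."""

import numpy as np
import pytest

from msuaflow import geometry
from msuaflow.embed import ExpansionSpec, explicit_expand, poly_kernel
from msuaflow.geometry import (
    FlowField,
    _classify_trajectory,
    correlation_dimension,
    escape_analysis,
    kernel_pca,
    likelihood_velocity_curve,
    velocity_field,
)


class TestKernelPCA:
    def test_order_one_matches_conventional_pca(self, rng):
        X = rng.standard_normal((40, 5)) @ np.diag([3, 2, 1, 0.5, 0.1])
        proj = kernel_pca(poly_kernel(X, X, 1), d=3)
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt.T[:, :3]
        for k in range(3):
            c = np.corrcoef(proj.coords[:, k], scores[:, k])[0, 1]
            assert abs(c) > 0.999

    def test_line_in_5d_explains_all_variance(self, rng):
        t = rng.uniform(-1, 1, 60)
        u = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        X = np.outer(t, u)
        proj = kernel_pca(poly_kernel(X, X, 1), d=2)
        assert proj.explained_variance[0] / proj.explained_variance.sum() > 0.999

    def test_small_set_matches_explicit_feature_map_pca(self, rng):
        X = rng.standard_normal((6, 3))
        spec = ExpansionSpec(order=2, base_dim=3)
        F = np.stack([explicit_expand(x, spec) for x in X])
        proj = kernel_pca(poly_kernel(X, X, 2), d=3)
        Fc = F - F.mean(axis=0)
        _, s, vt = np.linalg.svd(Fc, full_matrices=False)
        scores = Fc @ vt.T[:, :3]
        for k in range(3):
            c = np.corrcoef(proj.coords[:, k], scores[:, k])[0, 1]
            assert abs(c) > 0.999

    def test_full_rank_reconstructs_centered_kernel(self, rng):
        X = rng.standard_normal((12, 4))
        K = poly_kernel(X, X, 2)
        proj = kernel_pca(K, d=11)
        rec = proj.coords @ proj.coords.T
        from sklearn.preprocessing import KernelCenterer

        Kc = KernelCenterer().fit_transform(K.values.copy())
        assert np.abs(rec - Kc).max() <= 1e-8 * np.abs(Kc).max()

    def test_out_of_sample_projection_consistency(self, rng):
        X = rng.standard_normal((30, 4))
        K = poly_kernel(X, X, 2)
        proj = kernel_pca(K, d=3)
        back = proj.project(poly_kernel(X, X, 2))
        np.testing.assert_allclose(back, proj.coords, atol=1e-8)


class TestVelocityField:
    def test_constant_trajectory_zero_velocities(self):
        f = velocity_field(np.ones((10, 3)), normalize=False)
        assert np.all(f.speeds == 0)

    def test_linear_trajectory_constant_velocity(self):
        u = np.array([1.0, -2.0, 0.5])
        coords = np.outer(np.arange(10), u)
        f = velocity_field(coords, normalize=False)
        np.testing.assert_allclose(f.velocities, np.tile(u, (9, 1)))

    def test_trial_boundary_pairs_excluded(self, rng):
        coords = rng.standard_normal((18, 3))
        trials = np.array([0] * 10 + [1] * 8)
        f = velocity_field(coords, trial_ids=trials)
        assert len(f.speeds) == 9 + 7

    def test_single_point_empty_field(self):
        f = velocity_field(np.ones((1, 3)))
        assert len(f.speeds) == 0


class TestLikelihoodVelocityCurve:
    def _flow(self, speeds):
        return FlowField(
            velocities=np.zeros((len(speeds), 3)),
            speeds=np.asarray(speeds),
            index=np.arange(len(speeds)),
            normalized=True,
        )

    def test_speed_independent_likelihood_flat_slope(self, rng):
        speeds = rng.uniform(0, 1, 2000)
        like = np.exp(rng.normal(-1, 0.05, 2000))
        fit = likelihood_velocity_curve(self._flow(speeds), like, n_bins=20)
        assert abs(fit.slope) < 2 * fit.slope_se

    def test_recovers_constructed_slope(self, rng):
        speeds = rng.uniform(0, 1, 4000)
        loglike = -2.0 * speeds + rng.normal(0, 0.05, 4000)
        fit = likelihood_velocity_curve(self._flow(speeds), np.exp(loglike), n_bins=20)
        assert fit.slope == pytest.approx(-2.0, abs=3 * fit.slope_se + 0.05)
        # fit quality on clean data: RMS residual well below the paper-style
        # 1%-of-geometric-mean gate
        assert fit.rms_error < 0.01 * abs(fit.bin_means.mean())

    def test_too_few_bins_error(self, rng):
        speeds = np.full(100, 0.5)
        speeds[:2] = [0.1, 0.9]
        with pytest.raises(ValueError):
            likelihood_velocity_curve(self._flow(speeds), np.ones(100), n_bins=20)

    def test_compare_slopes_detects_difference(self, rng):
        speeds = rng.uniform(0, 1, 4000)
        f1 = likelihood_velocity_curve(
            self._flow(speeds), np.exp(-2.0 * speeds + rng.normal(0, 0.05, 4000)), 20
        )
        f2 = likelihood_velocity_curve(
            self._flow(speeds), np.exp(-0.5 * speeds + rng.normal(0, 0.05, 4000)), 20
        )
        cmp_ = geometry.compare_slopes(f1, f2)
        assert cmp_["slope_diff"] == pytest.approx(-1.5, abs=0.2)
        assert cmp_["p"] < 0.001


class TestEscapeTyping:
    @pytest.mark.parametrize(
        "member,k,expected",
        [
            ([1, 1, 1, 1, 1], 2, "a"),
            ([1, 1, 0, 1, 1], 2, "a"),  # short blip is membership noise
            ([1, 0, 0, 1, 1], 2, "b"),
            ([0, 0, 1, 1, 1], 2, "c"),
            ([1, 1, 0, 0, 0], 2, "escaped"),
            ([1, 1, 1, 0, 0], 2, "escaped"),  # misclassified in final bins
            ([0, 0, 1, 0, 0], 2, "escaped"),
            ([1, 0, 0, 1, 0], 1, "escaped"),
        ],
    )
    def test_trajectory_types(self, member, k, expected):
        assert _classify_trajectory(np.array(member, bool), k) == expected

    def test_all_correct_zero_escape(self):
        labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        rep = escape_analysis(labels, labels.copy(), np.zeros(20))
        assert rep.overall_escape_fraction == 0
        assert all(tc["a"] == 1 for tc in rep.type_counts.values())

    def test_constructed_20_percent_escape(self):
        # 10 trajectories of 5 bins; 2 built to escape (wrong final 2 bins)
        true, pred, trial = [], [], []
        for i in range(10):
            true += ["A"] * 5
            if i < 2:
                pred += ["A", "A", "A", "B", "B"]
            else:
                pred += ["A"] * 5
            trial += [i] * 5
        rep = escape_analysis(
            np.array(true, object), np.array(pred, object), np.array(trial)
        )
        assert rep.overall_escape_fraction == pytest.approx(20.0)

    def test_counts_conserve_and_types_exclusive(self, rng):
        labels = np.repeat(["A", "B", "A", "B"], 25).astype(object)
        pred = labels.copy()
        flip = rng.random(100) < 0.3
        pred[flip] = np.where(labels[flip] == "A", "B", "A")
        rep = escape_analysis(labels, pred, np.zeros(100))
        total = sum(sum(tc.values()) for tc in rep.type_counts.values())
        assert total == 4  # four maximal runs

    def test_trapping_violation_detection(self):
        true = np.array(["A"] * 5, dtype=object)
        pred = np.array(["A", "A", "A", "B", "B"], dtype=object)
        proj = np.zeros((5, 2))
        proj[4] = [10.0, 0.0]  # far outside trapping radius
        ref_coords = np.array([[0, 0], [1, 0], [0, 1], [-1, 0]], dtype=float)
        ref_labels = np.array(["A"] * 4, dtype=object)
        rep = escape_analysis(
            true, pred, np.zeros(5), projection=proj,
            ref_coords=ref_coords, ref_labels=ref_labels, rho=1.5,
        )
        assert rep.trapping_violations == pytest.approx(100.0)


class TestCorrelationDimension:
    def test_line_has_dimension_one(self, rng):
        t = rng.uniform(0, 1, 1000)
        u = np.array([1.0, 2.0, -0.5])
        pts = np.outer(np.sort(t), u) + 0.0
        res = correlation_dimension(pts, theiler_window=5)
        assert 0.9 <= res.d2_slope <= 1.1

    def test_plane_has_dimension_two(self, rng):
        a, b = rng.uniform(0, 1, (2, 2000))
        u = np.array([1.0, 0.0, 1.0])
        v = np.array([0.0, 1.0, -1.0])
        pts = np.outer(a, u) + np.outer(b, v)
        res = correlation_dimension(pts, theiler_window=5)
        assert 1.8 <= res.d2_slope <= 2.2

    def test_embedding_dim_follows_2d_plus_1(self, rng):
        t = np.sort(rng.uniform(0, 1, 600))
        pts = np.outer(t, np.ones(3))
        res = correlation_dimension(pts, theiler_window=5)
        assert res.embedding_dim_needed == int(np.ceil(2 * res.d2_slope + 1))

    def test_rotation_invariance(self, rng):
        t = rng.uniform(0, 1, 500)
        pts = np.stack([t, t**2, np.zeros_like(t)], axis=1)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        r1 = correlation_dimension(pts, theiler_window=3)
        r2 = correlation_dimension(pts @ R.T, theiler_window=3)
        assert r1.d2_slope == pytest.approx(r2.d2_slope, abs=1e-8)

    def test_correlation_sum_monotone_and_bounded(self, rng):
        pts = rng.standard_normal((300, 3))
        res = correlation_dimension(pts, theiler_window=2)
        S = res.correlation_sums
        assert np.all(np.diff(S) >= 0)
        assert 0 < S[-1] <= 1

    def test_too_few_points_error(self, rng):
        with pytest.raises(ValueError, match="200"):
            correlation_dimension(rng.standard_normal((50, 3)))
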