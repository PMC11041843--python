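import numpy as np
import pytest

from conftest import random_mixture, sample_image
from makm.fit import (
    FitConfig,
    FitTrace,
    NoUnderfitRegion,
    _chol_diag_lower_bounds,
    _objective_and_grad,
    _pack,
    _to_model,
    akm_step,
    fit_makm,
    fit_single_component,
    smart_start,
)
from makm.grid_histogram import BinGrid, GridField, joint_histogram
from makm.mixture import Bandwidth, l2_distance_sq, mixture_on_grid


def brute_force_smart_start_cov(error, mu, box_halfwidth):
    """Naive double loop over all bins and index pairs (oracle)."""
    grid = error.grid
    n = grid.n_channels
    size = 2 * box_halfwidth + 1
    pts = grid.center_points()
    e = error.values.ravel()
    widths = grid.widths
    # b(y - mu): 1/size^n inside the box, 0 outside
    b = np.ones(len(pts)) / size**n
    for d in range(n):
        b[np.abs(pts[:, d] - mu[d]) > (box_halfwidth + 0.5) * widths[d]] = 0.0
    w = float((e * b).sum())
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = (e * b * (pts[:, i] - mu[i]) * (pts[:, j] - mu[j])).sum() / w
    return w, K


class TestSmartStart:
    def test_single_spike(self):
        grid = BinGrid.regular(1, 4)  # bin width 0.25
        vals = np.zeros(4)
        vals[2] = 2.0
        mu, w, K = smart_start(GridField(grid, vals), box_halfwidth=0)
        assert mu[0] == pytest.approx(grid.centers[0][2])
        # error mass of the one-bin box: 2.0 * 0.25
        assert w == pytest.approx(0.5)

    def test_covariance_matches_brute_force(self):
        rng = np.random.default_rng(11)
        grid = BinGrid.regular(2, 12)
        for _ in range(10):
            vals = rng.normal(0.0, 1.0, size=grid.shape) + 0.5
            err = GridField(grid, vals)
            mu, w, K = smart_start(err, box_halfwidth=1)
            w_o, K_o = brute_force_smart_start_cov(err, mu, 1)
            if np.linalg.eigvalsh(0.5 * (K_o + K_o.T)).min() > 1e-10:
                np.testing.assert_allclose(K, 0.5 * (K_o + K_o.T), atol=1e-12)

    def test_nowhere_positive_signals(self):
        grid = BinGrid.regular(2, 6)
        err = GridField(grid, -np.ones(grid.shape))
        with pytest.raises(NoUnderfitRegion):
            smart_start(err, box_halfwidth=1)

    def test_tie_breaks_to_lowest_index(self):
        grid = BinGrid.regular(1, 6)
        vals = np.zeros(6)
        vals[[1, 4]] = 1.0  # identical peaks
        mu, _, _ = smart_start(GridField(grid, vals), box_halfwidth=0)
        assert mu[0] == pytest.approx(grid.centers[0][1])


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(13)
        model = random_mixture(rng, 3)
        grid = BinGrid.regular(2, 12)
        pts = grid.center_points()
        target = rng.random(len(pts))
        lower = _chol_diag_lower_bounds(3, 2, grid.widths)
        theta = np.maximum(_pack(model), lower) + 0.01
        J, grad = _objective_and_grad(theta, 3, 2, pts, target, grid.bin_volume)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            Jp, _ = _objective_and_grad(tp, 3, 2, pts, target, grid.bin_volume)
            Jm, _ = _objective_and_grad(tm, 3, 2, pts, target, grid.bin_volume)
            fd = (Jp - Jm) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestFitSingleComponent:
    def test_recovers_generating_gaussian(self):
        rng = np.random.default_rng(17)
        img = sample_image(rng, [[0.5, 0.5]], [1.0], 0.1, 100_000)
        q = joint_histogram(img, 50)
        cfg = FitConfig(mmax=1)
        model = fit_single_component(q, Bandwidth.auto(q.grid), cfg)
        assert np.abs(model.means[0] - 0.5).max() < 0.02
        assert model.weights[0] == 1.0

    def test_refinement_does_not_increase_objective(self):
        rng = np.random.default_rng(18)
        img = sample_image(rng, [[0.4, 0.6]], [1.0], 0.08, 20_000)
        q = joint_histogram(img, 30)
        cfg = FitConfig(mmax=1, bins_per_channel=30)
        trace = FitTrace()
        fit_single_component(q, Bandwidth.auto(q.grid), cfg, trace=trace)
        objs = trace.iteration_objectives[1]
        assert objs[-1] <= objs[0]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))


class TestAkmStep:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(19)
        means = np.array([[0.3, 0.3], [0.7, 0.7]])
        img = sample_image(rng, means, [0.5, 0.5], 0.08, 100_000)
        q = joint_histogram(img, 50)
        cfg = FitConfig(mmax=2)
        h = Bandwidth.auto(q.grid)
        model = fit_single_component(q, h, cfg)
        model = akm_step(model, q, h, cfg)
        fitted = model.means[np.argsort(model.means[:, 0])]
        assert np.abs(fitted - means).max() < 0.05
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(20)
        img = sample_image(rng, [[0.3, 0.4], [0.7, 0.6]], [0.5, 0.5], 0.08, 30_000)
        q = joint_histogram(img, 30)
        cfg = FitConfig(mmax=2, bins_per_channel=30)
        h = Bandwidth.auto(q.grid)
        trace = FitTrace()
        model = fit_single_component(q, h, cfg)
        akm_step(model, q, h, cfg, trace=trace)
        objs = trace.iteration_objectives[2]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))


class TestFitMakm:
    def test_mmax_one_equals_single_component(self):
        rng = np.random.default_rng(21)
        img = sample_image(rng, [[0.5, 0.5]], [1.0], 0.1, 20_000)
        q = joint_histogram(img, 30)
        cfg = FitConfig(mmax=1, bins_per_channel=30)
        model, _ = fit_makm(q, cfg)
        single = fit_single_component(q, cfg.resolve_bandwidth(q.grid), cfg)
        np.testing.assert_array_equal(model.means, single.means)
        np.testing.assert_array_equal(model.covariances, single.covariances)

    def test_three_component_recovery(self):
        rng = np.random.default_rng(22)
        means = np.array([[0.2, 0.3], [0.5, 0.7], [0.8, 0.3]])
        img = sample_image(rng, means, [1 / 3, 1 / 3, 1 / 3], 0.07, 100_000)
        q = joint_histogram(img, 50)
        model, _ = fit_makm(q, FitConfig(mmax=3))
        fitted = model.means[np.argsort(model.means[:, 0])]
        assert np.abs(fitted - means).max() < 0.05
        w = model.weights[np.argsort(model.means[:, 0])]
        assert np.abs(w - 1 / 3).max() < 0.05

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(23)
        img = sample_image(rng, [[0.3, 0.3], [0.7, 0.7]], [0.5, 0.5], 0.08, 20_000)
        q = joint_histogram(img, 30)
        cfg = FitConfig(mmax=2, bins_per_channel=30)
        m1, _ = fit_makm(q, cfg)
        m2, _ = fit_makm(q, cfg)
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.covariances, m2.covariances)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_all_covariances_spd_weights_simplex(self):
        rng = np.random.default_rng(24)
        img = sample_image(rng, [[0.3, 0.6], [0.7, 0.4]], [0.4, 0.6], 0.09, 30_000)
        q = joint_histogram(img, 30)
        model, _ = fit_makm(q, FitConfig(mmax=4, bins_per_channel=30))
        for K in model.covariances:
            assert np.linalg.eigvalsh(K).min() > 0
        assert model.weights.min() >= 0
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_early_stop_on_perfect_cover(self):
        # a histogram that IS a discretized Gaussian: after M=1 the residual
        # can become nowhere positive, stopping before mmax
        rng = np.random.default_rng(25)
        img = sample_image(rng, [[0.5, 0.5]], [1.0], 0.1, 50_000)
        q = joint_histogram(img, 30)
        model, trace = fit_makm(q, FitConfig(mmax=12, bins_per_channel=30))
        assert model.n_components <= 12


def test_pack_unpack_round_trip():
    rng = np.random.default_rng(26)
    model = random_mixture(rng, 3)
    back = _to_model(_pack(model), 3, 2)
    np.testing.assert_allclose(back.means, model.means, atol=1e-12)
    np.testing.assert_allclose(back.weights, model.weights, atol=1e-12)
    np.testing.assert_allclose(back.covariances, model.covariances, atol=1e-10)
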