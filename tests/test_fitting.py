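import numpy as np
import pytest

from dcewall import (
    ConcentrationCurve,
    PhantomSpec,
    PkCurveFit,
    PkParams,
    fit_curve,
    fit_roibased,
    fit_voxelwise,
    forward_model,
    model_jacobian,
    parameter_uncertainty,
    relative_fit_error,
    render_dynamic_series,
)
from dcewall.fitting import WallRoi

TRUTHS = {
    "patlak": PkParams("patlak", 0.043, vp=0.01),
    "tofts": PkParams("tofts", 0.018, ve=0.2),
    "extended_tofts": PkParams("extended_tofts", 0.059, vp=0.015, ve=0.25),
}


@pytest.mark.parametrize("model", list(TRUTHS))
def test_noiseless_parameter_recovery(model, aif, times_min):
    """All three models recover their generating parameters to <=0.1%."""
    truth = TRUTHS[model]
    ct = forward_model(truth, aif, times_min)
    est = PkCurveFit(model=model, aif=aif).fit(times_min, ct)
    assert est.converged_
    for name in truth.free_names:
        assert getattr(est, name + "_") == pytest.approx(
            getattr(truth, name), rel=1e-3
        ), name
    assert est.rel_fit_error_ < 0.01


def test_patlak_linear_and_iterative_solvers_agree(aif, times_min, rng):
    """Closed-form Patlak solve equals the iterative Gauss-Newton solution."""
    truth = TRUTHS["patlak"]
    y = forward_model(truth, aif, times_min) + rng.normal(0, 0.005, times_min.size)
    lin = PkCurveFit(model="patlak", aif=aif).fit(times_min, y)
    it = PkCurveFit(model="patlak", aif=aif, optimizer="gauss_newton")
    x_it, ok, _ = it._solve_gauss_newton(times_min, y, it._x0())
    assert ok
    np.testing.assert_allclose(x_it, lin.params_.as_vector(), rtol=1e-10, atol=1e-14)


def test_gauss_newton_option_matches_trust_region(aif, times_min):
    truth = TRUTHS["tofts"]
    ct = forward_model(truth, aif, times_min)
    lm = PkCurveFit(model="tofts", aif=aif, optimizer="lm").fit(times_min, ct)
    gn = PkCurveFit(model="tofts", aif=aif, optimizer="gauss_newton").fit(times_min, ct)
    assert gn.converged_
    assert gn.ktrans_ == pytest.approx(lm.ktrans_, rel=1e-6)
    assert gn.ve_ == pytest.approx(lm.ve_, rel=1e-6)


def test_all_zero_curve_degenerates_gracefully(aif, times_min):
    for model in TRUTHS:
        est = PkCurveFit(model=model, aif=aif).fit(times_min, np.zeros(times_min.size))
        assert est.ktrans_ == 0.0
        assert est.rel_fit_error_ == 0.0
        assert est.converged_
        if est.vp_ is not None:
            assert est.vp_ == 0.0


class TestRelativeFitError:
    def test_perfect_fit_is_zero(self):
        y = np.array([0.0, 0.1, 0.2])
        assert relative_fit_error(y, y) == 0.0

    def test_zero_fit_of_constant_is_100_percent(self):
        y = np.full(10, 0.7)
        assert relative_fit_error(y, np.zeros(10)) == pytest.approx(100.0)

    def test_matches_independent_recomputation(self, rng):
        y = rng.normal(0.1, 0.05, 25)
        yhat = y + rng.normal(0, 0.01, 25)
        expected = 100.0 * np.sqrt(np.mean((y - yhat) ** 2)) / np.max(np.abs(y))
        assert relative_fit_error(y, yhat) == pytest.approx(expected, rel=1e-12)
        expected_mean = 100.0 * np.sqrt(np.mean((y - yhat) ** 2)) / np.mean(np.abs(y))
        assert relative_fit_error(y, yhat, "mean") == pytest.approx(expected_mean, rel=1e-12)


class TestParameterUncertainty:
    def test_zero_residuals_give_zero_uncertainty(self, aif, times_min):
        truth = TRUTHS["patlak"]
        jac = model_jacobian(truth, aif, times_min)
        u = parameter_uncertainty(truth.as_vector(), jac, np.zeros(times_min.size))
        assert np.allclose(u, 0.0)

    def test_matches_ols_standard_errors(self, aif, times_min, rng):
        """Patlak is linear: the covariance must equal the OLS formula."""
        truth = TRUTHS["patlak"]
        y = forward_model(truth, aif, times_min) + rng.normal(0, 0.01, times_min.size)
        est = PkCurveFit(model="patlak", aif=aif).fit(times_min, y)
        x = est.params_.as_vector()
        jac = model_jacobian(est.params_, aif, times_min)
        resid = est._forward(x, times_min) - y
        n, p = jac.shape
        s2 = resid @ resid / (n - p)
        cov = s2 * np.linalg.inv(jac.T @ jac)
        expected = 100.0 * np.sqrt(np.diag(cov)) / np.abs(x)
        got = np.array([est.rel_uncertainty_[n_] for n_ in est.params_.free_names])
        assert got == pytest.approx(expected, rel=1e-9)

    def test_near_zero_parameter_reports_infinite(self):
        jac = np.column_stack([np.ones(10), np.arange(10.0)])
        u = parameter_uncertainty(np.array([0.0, 1.0]), jac, np.full(10, 0.1))
        assert np.isinf(u[0]) and np.isfinite(u[1])

    def test_monte_carlo_calibration_tofts(self, aif, times_min, rng):
        """Covariance-based sd tracks the replicate scatter within 20%."""
        truth = TRUTHS["tofts"]
        ct0 = forward_model(truth, aif, times_min)
        est = PkCurveFit(model="tofts", aif=aif)
        ks, us = [], []
        for _ in range(200):
            est.fit(times_min, ct0 + rng.normal(0, 0.01, ct0.size))
            if est.converged_:
                ks.append(est.ktrans_)
                us.append(est.rel_uncertainty_["ktrans"] / 100.0 * abs(est.ktrans_))
        ratio = np.mean(us) / np.std(ks, ddof=1)
        assert 0.8 < ratio < 1.2


class TestVoxelwiseAndRoi:
    def test_homogeneous_phantom_gives_uniform_maps(self, protocol):
        phantom = PhantomSpec(grid_shape=(20, 20, 1), r_inner=4, r_outer=6, noise_sd=0.0)
        series, truth = render_dynamic_series(phantom, protocol)
        vw = fit_voxelwise(series, truth["wall_mask"], truth["aif"], "patlak")
        kt = vw.maps["ktrans"][truth["wall_mask"]]
        assert np.nanstd(kt) < 1e-10
        assert vw.roi_mean["ktrans"] == pytest.approx(0.043, rel=1e-6)
        roi = fit_roibased(series, truth["wall_mask"], truth["aif"], "patlak")
        assert roi.params.ktrans == pytest.approx(vw.roi_mean["ktrans"], rel=1e-8)

    def test_two_region_phantom_mean_is_arithmetic_mean(self, protocol):
        shape = (20, 20, 1)
        kt_map = np.full(shape, 0.02)
        kt_map[10:, :, :] = 0.10  # split the ring into two half-rings
        phantom = PhantomSpec(
            grid_shape=shape, center=(9.5, 9.5), r_inner=4, r_outer=6,
            ktrans=kt_map, noise_sd=0.0,
        )
        series, truth = render_dynamic_series(phantom, protocol)
        wall = truth["wall_mask"]
        # the split is symmetric: equal voxel counts
        assert (kt_map[wall] == 0.02).sum() == (kt_map[wall] == 0.10).sum()
        vw = fit_voxelwise(series, wall, truth["aif"], "patlak")
        assert vw.roi_mean["ktrans"] == pytest.approx(0.06, rel=1e-6)

    def test_patlak_roi_fit_commutes_with_averaging(self, protocol):
        """Patlak is linear in its parameters: ROI-based K equals the mean K."""
        shape = (20, 20, 1)
        kt_map = np.full(shape, 0.02)
        kt_map[10:, :, :] = 0.10
        phantom = PhantomSpec(
            grid_shape=shape, center=(9.5, 9.5), r_inner=4, r_outer=6,
            ktrans=kt_map, noise_sd=0.0,
        )
        series, truth = render_dynamic_series(phantom, protocol)
        roi = fit_roibased(series, truth["wall_mask"], truth["aif"], "patlak")
        assert roi.params.ktrans == pytest.approx(0.06, rel=1e-6)

    def test_tofts_roi_fit_differs_from_voxel_mean(self, protocol):
        """The Tofts convolution is nonlinear in kep: averaging does not commute."""
        shape = (20, 20, 1)
        kt_map = np.full(shape, 0.02)
        kt_map[10:, :, :] = 0.10
        phantom = PhantomSpec(
            grid_shape=shape, center=(9.5, 9.5), r_inner=4, r_outer=6,
            ktrans=kt_map, ve=0.15, vp=0.0, generating_model="tofts", noise_sd=0.0,
        )
        series, truth = render_dynamic_series(phantom, protocol)
        vw = fit_voxelwise(series, truth["wall_mask"], truth["aif"], "tofts")
        roi = fit_roibased(series, truth["wall_mask"], truth["aif"], "tofts")
        assert roi.params.ktrans != pytest.approx(vw.roi_mean["ktrans"], rel=1e-4)

    def test_deterministic_maps(self, protocol):
        phantom = PhantomSpec(grid_shape=(16, 16, 1), r_inner=3, r_outer=5, seed=9)
        s1, t1 = render_dynamic_series(phantom, protocol)
        s2, t2 = render_dynamic_series(phantom, protocol)
        v1 = fit_voxelwise(s1, t1["wall_mask"], t1["aif"], "patlak")
        v2 = fit_voxelwise(s2, t2["wall_mask"], t2["aif"], "patlak")
        np.testing.assert_array_equal(v1.maps["ktrans"], v2.maps["ktrans"])

    def test_wall_roi_ring_membership(self):
        roi = WallRoi.from_rings((20, 20, 2), (9.5, 9.5), 4.0, 6.0)
        assert roi.n_voxels == 2 * np.sum(roi.mask[:, :, 0])
        with pytest.raises(ValueError):
            WallRoi.from_rings((20, 20, 1), (9.5, 9.5), 6.0, 4.0)


def test_too_few_points_rejected(aif):
    t = np.array([0.0, 0.3, 0.6])
    with pytest.raises(ValueError, match="time points"):
        PkCurveFit(model="extended_tofts", aif=aif).fit(t, np.zeros(3))


def test_fit_curve_wrapper_returns_result(aif, times_s, times_min):
    truth = TRUTHS["patlak"]
    ct = ConcentrationCurve(times_s, forward_model(truth, aif, times_min))
    res = fit_curve(ct, aif, "patlak")
    assert res.converged
    assert res.params.ktrans == pytest.approx(0.043, rel=1e-6)
    assert res.n_points == times_s.size
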