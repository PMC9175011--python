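"""Single-tube constrained least squares: starts, fits, and inference."""

import numpy as np
import pytest

from roppol import (FitOptions, ShapeParams, SimulationDesign, TubeData,
                    asymptotic_covariance, fit_single, initial_values,
                    rates_from_shape, simulate_single)

TRUTH = ShapeParams(lam=0.6, mu=1.0)


def _noiseless_tube(ref, step=0.1):
    design = SimulationDesign(step=step, sigma=0.0)
    return simulate_single(TRUTH, design, ref)


def test_initial_values_noiseless(ref, consts):
    tube = _noiseless_tube(ref)
    start = initial_values(tube, ref, consts)
    assert start.lam == pytest.approx(0.6, rel=1e-2)
    assert start.mu == pytest.approx(1.0, rel=1e-2)


def test_initial_values_identity_configuration(ref, consts):
    # data that literally equals U_alpha on its own grid
    tube = TubeData(x=ref.grid, y=ref.values)
    start = initial_values(tube, ref, consts)
    assert start.lam == pytest.approx(1.0, rel=1e-6)
    assert start.mu == pytest.approx(1.0, rel=1e-2)


def test_initial_lambda_scales_with_peak(ref, consts):
    tube = _noiseless_tube(ref)
    doubled = TubeData(x=tube.x, y=2.0 * tube.y)
    s1 = initial_values(tube, ref, consts)
    s2 = initial_values(doubled, ref, consts)
    assert s2.lam == pytest.approx(2.0 * s1.lam, rel=1e-12)


def test_initial_values_pathological_fallback(ref, consts):
    tube = TubeData(x=np.linspace(-15, 15, 11), y=np.full(11, -1.0))
    with pytest.warns(UserWarning, match="Riemann"):
        start = initial_values(tube, ref, consts)
    assert start.mu == 1.0


def test_noiseless_fit_is_exact(ref, consts):
    fit = fit_single(_noiseless_tube(ref), consts, ref)
    assert fit.shape.lam == pytest.approx(0.6, abs=1e-8)
    assert fit.shape.mu == pytest.approx(1.0, abs=1e-8)
    assert fit.rss < 1e-12
    assert not fit.on_boundary and fit.converged
    # sigma = 0 data gives a degenerate (zero) covariance
    assert np.abs(fit.cov_shape).max() < 1e-15


def test_optimizer_agrees_with_grid_search_oracle(ref, consts):
    # brute force over (lam, mu) in [0.1, 2]^2 at 1e-3 resolution, 7 points
    x = np.linspace(-12, 12, 7)
    truth = ShapeParams(lam=0.7, mu=1.1)
    y = truth.lam * ref.u(truth.mu * x)
    lams = np.arange(0.1, 2.0 + 1e-9, 1e-3)
    mus = np.arange(0.1, 2.0 + 1e-9, 1e-3)
    # RSS(lam, mu) is quadratic in lam given mu: expand the square
    uu = ref.u(np.outer(mus, x))  # len(mus) x 7
    suu = (uu ** 2).sum(axis=1)
    suy = (uu * y).sum(axis=1)
    syy = float((y ** 2).sum())
    rss = syy - 2.0 * np.outer(lams, suy) + np.outer(lams ** 2, suu)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    best_lam, best_mu = lams[i], mus[j]
    fit = fit_single(TubeData(x=x, y=y), consts, ref)
    assert fit.shape.lam == pytest.approx(best_lam, abs=2e-3)
    assert fit.shape.mu == pytest.approx(best_mu, abs=2e-3)


def test_fit_recovers_truth_within_three_se(ref, consts, rng):
    design = SimulationDesign(step=0.1, sigma=0.2)
    tube = simulate_single(TRUTH, design, ref, rng=rng)
    fit = fit_single(tube, consts, ref)
    se = np.sqrt(np.diag(fit.cov_shape))
    assert abs(fit.shape.mu - TRUTH.mu) < 3 * se[0]
    assert abs(fit.shape.lam - TRUTH.lam) < 3 * se[1]


def test_scale_equivariance(ref, consts, rng):
    design = SimulationDesign(step=0.1, sigma=0.2)
    tube = simulate_single(TRUTH, design, ref, rng=rng)
    a = 1.7
    scaled = TubeData(x=tube.x, y=a * tube.y)
    f1 = fit_single(tube, consts, ref)
    f2 = fit_single(scaled, consts, ref)
    assert f2.shape.lam == pytest.approx(a * f1.shape.lam, rel=1e-5)
    assert f2.shape.mu == pytest.approx(f1.shape.mu, rel=1e-5)


def test_objective_not_worse_than_start(ref, consts, rng):
    design = SimulationDesign(step=0.3, sigma=0.4)
    for _ in range(5):
        tube = simulate_single(TRUTH, design, ref, rng=rng)
        fit = fit_single(tube, consts, ref)
        start = initial_values(tube, ref, consts)
        rss_start = float(np.sum((tube.y - start.lam * ref.u(start.mu * tube.x)) ** 2))
        assert fit.rss <= rss_start + 1e-9


def test_fits_are_feasible(ref, consts, rng):
    design = SimulationDesign(step=0.6, sigma=0.4)
    for _ in range(10):
        tube = simulate_single(TRUTH, design, ref, rng=rng)
        fit = fit_single(tube, consts, ref)
        assert fit.shape.lam > 0 and fit.shape.mu > 0
        assert fit.shape.mu * consts.rtot - fit.shape.lam * ref.mass >= 0
        assert fit.rates.knf > 0 and fit.rates.kpf > 0


def test_se_shrinks_with_n(ref, consts):
    ses = {}
    for step, n in ((0.6, 51), (0.1, 301)):
        rng = np.random.default_rng(123)
        design = SimulationDesign(step=step, sigma=0.2)
        fit = fit_single(simulate_single(TRUTH, design, ref, rng=rng), consts, ref)
        ses[n] = np.sqrt(np.diag(fit.cov_shape))
    assert (ses[301] < ses[51]).all()


@pytest.mark.parametrize("sigma", [0.2, 0.4])
def test_rmse_decreases_with_n(ref, consts, sigma):
    # error of (mu, lam) shrinks as the grid refines through 51/101/301
    rmse = []
    for step in (0.6, 0.3, 0.1):
        design = SimulationDesign(step=step, sigma=sigma)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(30):
            fit = fit_single(simulate_single(TRUTH, design, ref, rng=rng), consts, ref)
            errs.append([fit.shape.mu - TRUTH.mu, fit.shape.lam - TRUTH.lam])
        rmse.append(np.sqrt(np.mean(np.square(errs), axis=0)))
    rmse = np.array(rmse)
    assert (rmse[1] < rmse[0]).all()
    assert (rmse[2] < rmse[1]).all()


def test_boundary_flag_and_withheld_covariance(ref, consts):
    # data far above any feasible profile drives the fit into the constraint
    x = np.linspace(-15, 15, 51)
    y = 5.0 * ref.u(0.3 * x)  # lam/mu ratio deep outside the feasible set
    fit = fit_single(TubeData(x=x, y=y), consts, ref,
                     FitOptions(n_restarts=2))
    if fit.on_boundary:
        assert fit.cov_shape is None
        with pytest.raises(ValueError, match="boundary"):
            asymptotic_covariance(fit, TubeData(x=x, y=y), ref)
    else:  # constraint slack must then be genuinely positive
        assert fit.shape.nu - ref.mass / consts.rtot > 1e-6


def test_ratio_matches_generating_value_in_real_data_regime(ref, consts):
    # re-simulation at the strongest observed single-tube regime
    gen = ShapeParams(lam=0.70, mu=0.99)
    gen_ratio = 1.0 / (rates_from_shape(gen, consts, ref).kpf
                       / rates_from_shape(gen, consts, ref).knf)
    design = SimulationDesign(step=0.1, sigma=0.13)
    tube = simulate_single(gen, design, ref, rng=np.random.default_rng(5))
    fit = fit_single(tube, consts, ref)
    assert fit.rates.knf / fit.rates.kpf == pytest.approx(gen_ratio, abs=0.02)
    assert gen_ratio == pytest.approx(0.64, abs=0.01)
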