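"""MISO-ARX identification: regression assembly, fitting, order selection."""

import warnings

import numpy as np
import pytest

from misoarx import (
    ARPolynomial,
    FitConfig,
    LagEstimate,
    MAWithDelay,
    SampledSignal,
    build_regression,
    filter_arma,
    fit,
    fit_arx_baseline,
    select_orders_fpe,
)
from misoarx.exceptions import UnderdeterminedError
from misoarx.templates import Subtemplate

from conftest import gaussian_bump


def as_subtemplate(signal: SampledSignal) -> Subtemplate:
    peak = int(np.argmax(np.abs(signal.samples)))
    return Subtemplate(
        waveform=signal, peak_index=peak, peak_sign=1,
        window_center=peak, window_halfwidth=signal.n,
    )


def lags_for(shifts):
    shifts = np.asarray(shifts, dtype=int)
    return LagEstimate(
        shifts=shifts,
        coefficients=np.ones(shifts.size),
        detected=np.ones(shifts.size, dtype=bool),
    )


def forward_simulate(inputs, a, bs, delays, noise=None):
    """Generate y from a known shared-denominator model (the fit oracle)."""
    n = inputs[0].n
    total = np.zeros(n)
    for u, b, d in zip(inputs, bs, delays):
        total += filter_arma(u, MAWithDelay(b, delay=d), ARPolynomial(a)).samples
    if noise is not None:
        total = total + noise
    return inputs[0].with_samples(total)


@pytest.fixture()
def two_component_truth(rng):
    u1 = gaussian_bump(500, 120, 9.0, 1.0)
    u2 = gaussian_bump(500, 330, 11.0, 0.8)
    a = np.array([0.6, -0.25])  # stable AR(2)
    bs = [np.array([1.2, -0.4]), np.array([0.7, 0.3])]
    delays = [3, 7]
    y = forward_simulate([u1, u2], a, bs, delays)
    return y, [as_subtemplate(u1), as_subtemplate(u2)], a, bs, delays


class TestBuildRegression:
    def test_scalar_projection_case(self):
        u = gaussian_bump(200, 100, 8.0)
        y = SampledSignal(2.5 * u.samples, rate=100.0)
        cfg = FitConfig(n=0, m=1, delay_refine_radius=0)
        X, t = build_regression(y, [as_subtemplate(u)], lags_for([0]), cfg)
        theta = float(X[:, 0] @ t / (X[:, 0] @ X[:, 0]))
        assert theta == pytest.approx(2.5, abs=1e-12)

    def test_column_count(self, two_component_truth):
        y, subs, *_ = two_component_truth
        cfg = FitConfig(n=2, m=3, delay_refine_radius=0)
        X, _ = build_regression(y, subs, lags_for([0, 0]), cfg)
        assert X.shape[1] == 2 + 2 * 3

    def test_underdetermined_rejected(self):
        u = gaussian_bump(8, 4, 1.0)
        y = SampledSignal(u.samples, rate=100.0)
        cfg = FitConfig(n=6, m=3, delay_refine_radius=0)
        with pytest.raises(UnderdeterminedError):
            build_regression(y, [as_subtemplate(u)], lags_for([0]), cfg)


class TestFit:
    def test_exact_recovery_noise_free(self, two_component_truth):
        y, subs, a, bs, delays = two_component_truth
        cfg = FitConfig(n=2, m=2, delay_refine_radius=0)
        est = fit(y, subs, lags_for(delays), cfg)
        assert np.allclose(est.model.shared_a.coeffs, a, atol=1e-6)
        for num, b, d in zip(est.model.numerators, bs, delays):
            assert num.delay == d
            assert np.allclose(num.coeffs, b, atol=1e-6)
        assert np.allclose(est.ep.samples, y.samples, atol=1e-6)

    def test_reconstruction_identity(self, two_component_truth, rng):
        y, subs, *_ = two_component_truth
        noisy = y.with_samples(y.samples + 0.3 * rng.standard_normal(y.n))
        est = fit(noisy, subs, lags_for([3, 7]), FitConfig(n=2, m=2))
        assert np.allclose(est.ep.samples + est.residual.samples, noisy.samples,
                           atol=1e-12)
        assert np.allclose(
            est.ep.samples,
            np.sum([c.samples for c in est.components], axis=0),
            atol=1e-12,
        )

    def test_input_orthogonal_to_pure_noise_gets_small_gain(self):
        # y is pure AR(2) noise; a localized input far from anything
        # systematic should earn a vanishing numerator as N grows
        from scipy.signal import lfilter

        rng = np.random.default_rng(7)
        n = 10_000
        noise = lfilter([1.0], [1.0, -0.5, 0.2], rng.standard_normal(n))
        y = SampledSignal(noise, rate=100.0)
        u = gaussian_bump(n, 5000, 20.0)
        est = fit(y, [as_subtemplate(u)], lags_for([0]),
                  FitConfig(n=2, m=1, delay_refine_radius=0))
        assert np.linalg.norm(est.model.numerators[0].coeffs) < 0.1

    def test_q1_lag0_identical_to_baseline(self, rng):
        u = gaussian_bump(400, 200, 10.0)
        y = SampledSignal(
            1.4 * u.samples + 0.2 * rng.standard_normal(400), rate=100.0
        )
        cfg = FitConfig(n=3, m=2, delay_refine_radius=0)
        a = fit(y, [as_subtemplate(u)], lags_for([0]), cfg)
        b = fit_arx_baseline(y, u, cfg)
        assert np.array_equal(a.model.shared_a.coeffs, b.model.shared_a.coeffs)
        assert np.array_equal(
            a.model.numerators[0].coeffs, b.model.numerators[0].coeffs
        )
        assert np.array_equal(a.ep.samples, b.ep.samples)

    def test_rls_converges_to_ols(self, two_component_truth, rng):
        y, subs, *_ = two_component_truth
        noisy = y.with_samples(y.samples + 0.1 * rng.standard_normal(y.n))
        ols = fit(noisy, subs, lags_for([3, 7]),
                  FitConfig(n=2, m=2, delay_refine_radius=0, solver="ols"))
        rls = fit(noisy, subs, lags_for([3, 7]),
                  FitConfig(n=2, m=2, delay_refine_radius=0, solver="rls"))
        assert np.allclose(
            rls.model.shared_a.coeffs, ols.model.shared_a.coeffs, atol=1e-3
        )
        for nr, no in zip(rls.model.numerators, ols.model.numerators):
            assert np.allclose(nr.coeffs, no.coeffs, atol=1e-3)

    def test_ridge_fallback_on_duplicate_inputs(self, rng):
        u = gaussian_bump(300, 150, 10.0)
        y = SampledSignal(u.samples + 0.05 * rng.standard_normal(300), rate=100.0)
        subs = [as_subtemplate(u), as_subtemplate(u)]  # identical columns
        with pytest.warns(UserWarning, match="ridge"):
            est = fit(y, subs, lags_for([0, 0]),
                      FitConfig(n=0, m=1, delay_refine_radius=0))
        assert est.model.ridge_fallback

    def test_refinement_never_increases_rss(self, two_component_truth, rng):
        y, subs, a, bs, delays = two_component_truth
        noisy = y.with_samples(y.samples + 0.2 * rng.standard_normal(y.n))
        start = lags_for([5, 5])  # both delays wrong by a few samples
        cfg0 = FitConfig(n=2, m=2, delay_refine_radius=0)
        cfg3 = FitConfig(n=2, m=2, delay_refine_radius=4)
        rss0 = fit(noisy, subs, start, cfg0).model.noise_variance
        rss3 = fit(noisy, subs, start, cfg3).model.noise_variance
        assert rss3 <= rss0 + 1e-12

    def test_undetected_component_dropped_with_warning(self, two_component_truth):
        y, subs, *_ = two_component_truth
        lag = LagEstimate(
            shifts=np.array([3, 0]),
            coefficients=np.array([1.0, 0.0]),
            detected=np.array([True, False]),
        )
        with pytest.warns(UserWarning, match="dropping"):
            est = fit(y, subs, lag, FitConfig(n=2, m=2, delay_refine_radius=0))
        assert est.model.Q == 1
        assert est.model.component_indices == (0,)
        assert np.array_equal(est.components[1].samples, np.zeros(y.n))


class TestResidualWhiteness:
    def test_whitened_residual_passes_portmanteau(self):
        # well-specified fits leave A(z)-whitened residuals that look
        # white to a Ljung-Box test at the 99% level
        from scipy.signal import lfilter
        from statsmodels.stats.diagnostic import acorr_ljungbox

        u1 = gaussian_bump(800, 200, 10.0, 1.0)
        u2 = gaussian_bump(800, 550, 12.0, 0.8)
        subs = [as_subtemplate(u1), as_subtemplate(u2)]
        a = np.array([0.6, -0.25])
        passes = 0
        n_sims = 40
        for k in range(n_sims):
            rng = np.random.default_rng(1000 + k)
            w = rng.standard_normal(800)
            noise = lfilter([1.0], np.concatenate(([1.0], -a)), w)
            y = forward_simulate(
                [u1, u2], a, [np.array([1.0, -0.3]), np.array([0.6, 0.2])],
                [3, 7], noise=noise,
            )
            est = fit(y, subs, lags_for([3, 7]),
                      FitConfig(n=2, m=2, delay_refine_radius=0))
            innov = est.model.shared_a.apply_fir(est.residual.samples)[10:]
            stat = acorr_ljungbox(innov, lags=[20])
            if float(stat["lb_pvalue"].iloc[0]) > 0.01:
                passes += 1
        assert passes >= 0.95 * n_sims


class TestOrderSelection:
    def test_single_point_grid(self, two_component_truth):
        y, subs, *_ = two_component_truth
        cfg = select_orders_fpe(y, subs, lags_for([3, 7]), [(3, 2)])
        assert (cfg.n, cfg.m) == (3, 2)

    def test_infeasible_points_skipped(self):
        u = gaussian_bump(30, 15, 2.0)
        y = SampledSignal(u.samples * 1.1, rate=100.0)
        cfg = select_orders_fpe(
            y, [as_subtemplate(u)], lags_for([0]), [(25, 3), (1, 1)]
        )
        assert (cfg.n, cfg.m) == (1, 1)

    def test_true_orders_win_at_moderate_noise(self):
        # data generated with (n, m) = (2, 2): FPE picks the true orders
        # in a clear majority of noise realizations and, like other
        # AIC-family criteria, essentially never under-selects (its
        # over-selection probability per extra parameter stays near
        # P(chi2_1 > 2) ~ 16% even asymptotically)
        from scipy.signal import lfilter

        u1 = gaussian_bump(1000, 250, 2.0, 1.0)
        u2 = gaussian_bump(1000, 700, 2.0, 0.8)
        subs = [as_subtemplate(u1), as_subtemplate(u2)]
        a = np.array([0.6, -0.25])
        bs = [np.array([1.0, -0.8]), np.array([0.7, 0.64])]
        clean = forward_simulate([u1, u2], a, bs, [3, 7])
        sig_power = np.mean(clean.samples**2)
        grid = [(n, m) for n in (1, 2, 3) for m in (1, 2, 3)]
        exact = 0
        no_under = 0
        n_sims = 50
        for k in range(n_sims):
            rng = np.random.default_rng(2000 + k)
            w = rng.standard_normal(1000)
            noise = lfilter([1.0], np.concatenate(([1.0], -a)), w)
            noise *= np.sqrt(sig_power / np.mean(noise**2))  # 0 dB
            y = clean.with_samples(clean.samples + noise)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cfg = select_orders_fpe(y, subs, lags_for([3, 7]), grid)
            exact += (cfg.n, cfg.m) == (2, 2)
            no_under += cfg.n >= 2 and cfg.m >= 2
        assert exact >= 0.5 * n_sims
        assert no_under >= 0.9 * n_sims
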