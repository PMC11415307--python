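"""Trace-to-permeability estimators: windows, slopes, rates, normalization."""

import numpy as np
import pytest
from sklearn.base import clone

from gjflux import (
    ChannelPopulation,
    EffluxParams,
    EffluxScenario,
    EffluxSlopeEstimator,
    EstimationError,
    FluorescenceCalibration,
    FluorescenceTrace,
    TransferRateEstimator,
    TransferScenario,
    detect_donor_steady_state,
    estimate_rate_discretized,
    fit_efflux_slope,
    fit_recipient_exponential,
    generate_efflux_trace,
    generate_transfer_traces,
    normalize_gj,
    normalize_hemichannel,
    recipient_solution,
    select_linear_window,
)

CAL = FluorescenceCalibration(f=5.0, f0=100.0)


def efflux_trace(rate=1e-4, noise=0.02, seed=0, vol=1.0, c0=100.0):
    scen = EffluxScenario(
        params=EffluxParams(vol_in=vol, perm=rate * vol, c_in_0=c0),
        calibration=CAL,
        noise=noise,
        seed=seed,
    )
    return generate_efflux_trace(scen)


class TestSelectLinearWindow:
    def test_exact_line_full_extent(self):
        t = np.arange(0, 1800, 10.0)
        w = select_linear_window(FluorescenceTrace(t, 500.0 - 0.4 * t))
        assert w == (t[0], t[-1])

    def test_noise_only_full_extent_and_null_slope(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 1800, 10.0)
        tr = FluorescenceTrace(t, 500.0 + 5.0 * rng.standard_normal(t.size))
        w = select_linear_window(tr)
        assert w == (t[0], t[-1])
        fit = fit_efflux_slope(tr, w)
        assert abs(fit.slope_k) < 2.0 * fit.slope_stderr  # CI contains 0

    @pytest.mark.parametrize("seed", range(5))
    def test_changepoint_window_starts_at_break(self, seed):
        # plateau for 600 s, then a clear linear decline; low imaging noise
        rng = np.random.default_rng(seed)
        t = np.arange(0, 1800, 10.0)
        cp = 600.0
        y = np.where(t < cp, 800.0, 800.0 - 0.5 * (t - cp))
        y = y * (1.0 + 0.002 * rng.standard_normal(t.size))
        w = select_linear_window(FluorescenceTrace(t, y))
        assert abs(w[0] - cp) <= 2 * 10.0  # within 2 samples
        assert w[1] == t[-1]

    def test_no_qualifying_window_raises(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 1800, 10.0)
        y = 500.0 + 100.0 * np.sin(2 * np.pi * t / 120.0)
        y += 0.5 * rng.standard_normal(t.size)
        with pytest.raises(EstimationError) as exc:
            select_linear_window(FluorescenceTrace(t, y))
        assert "n_windows_scanned" in exc.value.diagnostics

    def test_excluded_interval_not_in_window(self):
        t = np.arange(0, 1800, 10.0)
        tr = FluorescenceTrace(t, 500.0 - 0.1 * t)
        w = select_linear_window(tr, exclude=[(0.0, 900.0)])
        assert w[0] > 900.0

    def test_too_few_points_rejected(self):
        t = np.arange(0, 100, 10.0)
        with pytest.raises(ValueError):
            select_linear_window(FluorescenceTrace(t, np.ones_like(t)), min_points=20)


class TestEffluxSlope:
    def test_exact_line_slope(self):
        t = np.arange(0, 310, 10.0)
        fit = fit_efflux_slope(FluorescenceTrace(t, 500.0 - 0.4 * t), (0.0, 300.0))
        assert fit.slope_k == pytest.approx(-0.4, abs=1e-12)
        assert fit.intercept_c == pytest.approx(500.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_early_window_slope_matches_tangent(self):
        # noiseless efflux, fitted over the first 0.05 * Vol/P seconds: the
        # OLS slope equals the curve's derivative near the window midpoint,
        # i.e. the tangent slope -f*C_in(0)*P/Vol attenuated by e^(-0.025)
        tr = efflux_trace(rate=1e-3, noise=0.0)
        fit = fit_efflux_slope(tr, (0.0, 0.05 / 1e-3))
        tangent = -CAL.f * 100.0 * 1e-3
        assert fit.slope_k == pytest.approx(tangent, rel=0.03)
        t = np.arange(0.0, 51.0, 10.0)
        exact = np.asarray(CAL.to_fluorescence(
            100.0 * np.exp(-1e-3 * t)
        ))
        expected_ols = np.polyfit(t, exact, 1)[0]
        assert fit.slope_k == pytest.approx(expected_ols, rel=1e-9)

    def test_noisy_constant_slope_ci_contains_zero(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 1800, 10.0)
        tr = FluorescenceTrace(t, 600.0 + 6.0 * rng.standard_normal(t.size))
        fit = fit_efflux_slope(tr, (0.0, 1790.0))
        assert abs(fit.slope_k) < 2.0 * fit.slope_stderr

    def test_degenerate_window_rejected(self):
        t = np.arange(0, 310, 10.0)
        tr = FluorescenceTrace(t, 500.0 - 0.4 * t)
        with pytest.raises(ValueError):
            fit_efflux_slope(tr, (95.0, 104.0))  # single sample

    def test_estimator_is_sklearn_compatible(self):
        est = EffluxSlopeEstimator(min_points=15)
        assert clone(est).get_params()["min_points"] == 15
        est.set_params(r2_threshold=0.95)
        assert est.r2_threshold == 0.95


class TestDonorSteadyState:
    def test_exponential_loading_detected_near_plateau(self):
        t = np.arange(0, 930, 30.0)
        tr = FluorescenceTrace(t, 1000.0 * (1.0 - np.exp(-t / 80.0)))
        t_ss = detect_donor_steady_state(tr)
        assert 300.0 <= t_ss <= 450.0

    def test_constant_donor_first_admissible_time(self):
        t = np.arange(0, 930, 30.0)
        tr = FluorescenceTrace(t, np.full(t.size, 800.0))
        assert detect_donor_steady_state(tr) == t[0]

    def test_rising_ramp_never_steady(self):
        t = np.arange(0, 930, 30.0)
        tr = FluorescenceTrace(t, 10.0 + 2.0 * t)
        assert detect_donor_steady_state(tr) is None

    def test_short_trace_rejected(self):
        t = np.arange(0, 240, 30.0)
        with pytest.raises(ValueError):
            detect_donor_steady_state(FluorescenceTrace(t, np.full(t.size, 1.0)))


def constant_donor_pair(rate=0.0011, c1=100.0, c2_t0=5.0, f=5.0, f0=50.0):
    """Exact constant-donor pair built directly from the closed form."""
    t = np.arange(0, 930, 30.0)
    cal = FluorescenceCalibration(f=f, f0=f0)
    donor = FluorescenceTrace(t, np.asarray(cal.to_fluorescence(np.full(t.size, c1))),
                              background=f0)
    c2 = recipient_solution(c1, c2_t0, rate, 0.0, t)
    recipient = FluorescenceTrace(t, np.asarray(cal.to_fluorescence(c2)), background=f0)
    return donor, recipient


class TestRecipientExponential:
    def test_noiseless_recovery_to_tenth_percent(self):
        donor, recipient = constant_donor_pair(rate=0.0011)
        est = fit_recipient_exponential(donor, recipient)
        assert est.rate == pytest.approx(0.0011, rel=1e-3)
        assert est.method == "exponential_fit"

    def test_equilibrated_pair_unidentifiable(self):
        donor, recipient = constant_donor_pair(rate=0.0011, c2_t0=100.0)
        with pytest.raises(EstimationError):
            fit_recipient_exponential(donor, recipient)

    def test_recipient_at_background_rejected(self):
        donor, recipient = constant_donor_pair(rate=0.0011, c2_t0=5.0)
        flat = FluorescenceTrace(
            recipient.times,
            np.full(len(recipient), recipient.background),
            background=recipient.background,
        )
        with pytest.raises((ValueError, EstimationError)):
            fit_recipient_exponential(donor, flat)

    def test_noisy_monte_carlo_recovery(self):
        # 2% multiplicative noise, 30-s frames, 15-min recordings
        biases = []
        for seed in range(20):
            d, r = generate_transfer_traces(
                TransferScenario(rate=0.0011, noise=0.02, seed=seed)
            )
            biases.append(fit_recipient_exponential(d, r).rate / 0.0011 - 1.0)
        assert abs(np.median(biases)) < 0.05


class TestDiscretizedRate:
    def test_noiseless_agreement_with_truth_and_exponential(self):
        d, r = generate_transfer_traces(
            TransferScenario(rate=0.0011, noise=0.0, tau_load_s=5.0, seed=0)
        )
        disc = estimate_rate_discretized(d, r)
        expo = TransferRateEstimator(method="exponential_fit", t_ss=120.0).fit(d, r)
        assert disc.rate == pytest.approx(0.0011, rel=0.02)
        assert disc.rate == pytest.approx(expo.rate_, rel=0.05)

    def test_zero_gradient_everywhere_is_error(self):
        t = np.arange(0, 930, 30.0)
        same = FluorescenceTrace(t, np.full(t.size, 400.0), background=50.0)
        with pytest.raises(EstimationError):
            estimate_rate_discretized(same, same)

    def test_constant_recipient_gives_zero(self):
        t = np.arange(0, 930, 30.0)
        donor = FluorescenceTrace(t, np.full(t.size, 900.0), background=50.0)
        recipient = FluorescenceTrace(t, np.full(t.size, 200.0), background=50.0)
        est = estimate_rate_discretized(donor, recipient)
        assert est.rate == 0.0

    def test_per_step_diagnostics_recorded(self):
        d, r = generate_transfer_traces(TransferScenario(rate=0.0011, seed=4))
        est = estimate_rate_discretized(d, r)
        diag = est.diagnostics
        assert np.all(diag["per_step_times"] >= 120.0)
        assert diag["per_step_estimates"].shape == diag["per_step_times"].shape

    def test_resamples_unaligned_donor(self):
        d, r = generate_transfer_traces(
            TransferScenario(rate=0.0011, noise=0.0, tau_load_s=5.0, seed=0)
        )
        shifted = FluorescenceTrace(
            d.times + 1.0, np.interp(d.times + 1.0, d.times, d.values),
            background=d.background,
        )
        est = estimate_rate_discretized(shifted, r)
        assert est.rate == pytest.approx(0.0011, rel=0.05)


class TestNormalization:
    def test_hemichannel_forced_arithmetic(self):
        pop = ChannelPopulation(g_ns=3.4, gamma_ps=340.0)
        assert pop.n_po == pytest.approx(10.0)
        fit = fit_efflux_slope(
            FluorescenceTrace(np.arange(0, 310, 10.0),
                              500.0 - 0.5 * np.arange(0, 310, 10.0)),
            (0.0, 300.0),
        )
        norm = normalize_hemichannel(fit, pop)
        assert norm.value == pytest.approx(-0.05)
        assert norm.n_po_used == pytest.approx(10.0)

    def test_zero_slope_zero_value(self):
        t = np.arange(0, 310, 10.0)
        fit = fit_efflux_slope(FluorescenceTrace(t, np.full(t.size, 7.0)), (0, 300))
        assert normalize_hemichannel(fit, ChannelPopulation(2.0, 200.0)).value == 0.0

    def test_gj_forced_arithmetic(self):
        # 10 channels: 1 nS of junctional conductance at 100 pS per channel
        norm = normalize_gj(0.0011, gj_ns=1.0, gamma_j_ps=100.0)
        assert norm.value == pytest.approx(1.1e-4)
        assert normalize_gj(0.0, gj_ns=1.0, gamma_j_ps=100.0).value == 0.0

    def test_gj_invariant_to_channel_count_at_fixed_per_channel_perm(self):
        per_channel = 1.1e-4
        values = []
        for n_channels in (2.0, 10.0, 50.0):
            rate = per_channel * n_channels
            gj_ns = n_channels * 115.0 / 1e3
            values.append(normalize_gj(rate, gj_ns, 115.0).value)
        assert np.allclose(values, per_channel, rtol=1e-12)

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            normalize_gj(0.001, gj_ns=0.0, gamma_j_ps=100.0)
        with pytest.raises(ValueError):
            ChannelPopulation(g_ns=1.0, gamma_ps=0.0)


class TestEstimatorInvariances:
    def test_background_offset_invariance(self):
        tr = efflux_trace(seed=3)
        est1 = EffluxSlopeEstimator().fit(tr)
        shifted = FluorescenceTrace(
            tr.times, tr.values + 250.0, background=tr.background + 250.0
        )
        est2 = EffluxSlopeEstimator().fit(shifted)
        assert est1.slope_k_ == pytest.approx(est2.slope_k_, rel=1e-9)

        d, r = generate_transfer_traces(TransferScenario(rate=0.0011, seed=5))
        base = estimate_rate_discretized(d, r).rate
        d2 = FluorescenceTrace(d.times, d.values + 100.0, background=d.background + 100.0)
        r2 = FluorescenceTrace(r.times, r.values + 100.0, background=r.background + 100.0)
        assert estimate_rate_discretized(d2, r2).rate == pytest.approx(base, rel=1e-9)

    def test_calibration_scale_invariance_of_rates(self):
        d, r = generate_transfer_traces(TransferScenario(rate=0.0011, seed=6))
        base_disc = estimate_rate_discretized(d, r).rate
        base_exp = fit_recipient_exponential(d, r).rate
        scale = 3.0
        d2 = FluorescenceTrace(d.times, d.values * scale, background=d.background * scale)
        r2 = FluorescenceTrace(r.times, r.values * scale, background=r.background * scale)
        assert estimate_rate_discretized(d2, r2).rate == pytest.approx(base_disc, rel=1e-9)
        assert fit_recipient_exponential(d2, r2).rate == pytest.approx(base_exp, rel=1e-6)

    def test_slope_scales_linearly_with_calibration(self):
        tr = efflux_trace(noise=0.0)
        k1 = EffluxSlopeEstimator().fit(tr).slope_k_
        tr2 = FluorescenceTrace(tr.times, tr.values * 2.0, background=tr.background * 2.0)
        k2 = EffluxSlopeEstimator().fit(tr2).slope_k_
        assert k2 == pytest.approx(2.0 * k1, rel=1e-9)

    def test_slope_magnitude_nondecreasing_in_permeability(self):
        slopes = []
        for rate in (2e-5, 5e-5, 1e-4, 2e-4):
            tr = efflux_trace(rate=rate, noise=0.0)
            slopes.append(abs(EffluxSlopeEstimator().fit(tr).slope_k_))
        assert np.all(np.diff(slopes) > 0)
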