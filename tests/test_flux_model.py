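"""Closed-form flux models against trivial identities and RK4 oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gjflux import (
    EffluxParams,
    FluorescenceCalibration,
    TwoCompartmentParams,
    efflux_linear_approx,
    efflux_solution,
    recipient_solution,
    relative_fluorescence,
    simulate_two_compartment,
)
from oracles import rk4_efflux, rk4_recipient, rk4_two_compartment


class TestTwoCompartment:
    def test_zero_permeability_identity(self):
        p = TwoCompartmentParams(vol1=2.0, vol2=5.0, perm=0.0, c1_0=100.0, c2_0=0.0)
        c1, c2 = simulate_two_compartment(p, np.linspace(0, 1000, 11))
        assert np.all(c1 == 100.0)
        assert np.all(c2 == 0.0)

    def test_no_gradient_no_flux(self):
        p = TwoCompartmentParams(vol1=1.0, vol2=3.0, perm=0.02, c1_0=50.0, c2_0=50.0)
        c1, c2 = simulate_two_compartment(p, np.linspace(0, 500, 6))
        assert np.allclose(c1, 50.0, rtol=0, atol=1e-12)
        assert np.allclose(c2, 50.0, rtol=0, atol=1e-12)

    def test_matches_rk4_oracle(self):
        p = TwoCompartmentParams(vol1=1.0, vol2=1.0, perm=0.01, c1_0=100.0, c2_0=0.0)
        c1, c2 = simulate_two_compartment(p, np.array([0.0, 100.0]))
        ref = rk4_two_compartment(1.0, 1.0, 0.01, 100.0, 0.0, 100.0, h=0.01)
        assert c1[-1] == pytest.approx(ref[0], rel=1e-6)
        assert c2[-1] == pytest.approx(ref[1], rel=1e-6)

    def test_non_monotonic_times_rejected(self):
        p = TwoCompartmentParams(vol1=1.0, vol2=1.0, perm=0.01, c1_0=1.0, c2_0=0.0)
        with pytest.raises(ValueError):
            simulate_two_compartment(p, np.array([0.0, 10.0, 5.0]))
        with pytest.raises(ValueError):
            simulate_two_compartment(p, np.array([1.0, 2.0]))

    @settings(max_examples=60, deadline=None)
    @given(
        vol1=st.floats(0.1, 10.0),
        vol2=st.floats(0.1, 10.0),
        perm=st.floats(0.0, 0.1),
        c1_0=st.floats(0.0, 1000.0),
        c2_0=st.floats(0.0, 1000.0),
    )
    def test_mass_conservation(self, vol1, vol2, perm, c1_0, c2_0):
        p = TwoCompartmentParams(vol1=vol1, vol2=vol2, perm=perm, c1_0=c1_0, c2_0=c2_0)
        times = np.linspace(0, 2000, 41)
        c1, c2 = simulate_two_compartment(p, times)
        total = vol1 * c1 + vol2 * c2
        const = vol1 * c1_0 + vol2 * c2_0
        if const > 0:
            assert np.max(np.abs(total - const)) / const < 1e-9

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TwoCompartmentParams(vol1=0.0, vol2=1.0, perm=0.01, c1_0=1.0, c2_0=0.0)
        with pytest.raises(ValueError):
            TwoCompartmentParams(vol1=1.0, vol2=1.0, perm=-1.0, c1_0=1.0, c2_0=0.0)


class TestEffluxSolution:
    def test_initial_condition(self):
        p = EffluxParams(vol_in=2.0, perm=0.01, c_in_0=123.0, alpha=0.5)
        assert efflux_solution(p, 0.0) == pytest.approx(123.0, abs=1e-12)

    def test_matches_rk4_oracle(self):
        p = EffluxParams(vol_in=1.0, perm=0.01, c_in_0=100.0, alpha=0.0)
        ref = rk4_efflux(1.0, 0.01, 100.0, 0.0, 100.0, h=0.01)
        assert efflux_solution(p, 100.0) == pytest.approx(ref, rel=1e-6)

    @pytest.mark.parametrize("rate", [1e-4, 1e-3, 1e-2, 1e-1])
    def test_rk4_agreement_over_rate_grid(self, rate):
        p = EffluxParams(vol_in=1.0, perm=rate, c_in_0=100.0, alpha=0.02)
        for t_end in (200.0, 2000.0):
            ref = rk4_efflux(1.0, rate, 100.0, 0.02, t_end)
            assert efflux_solution(p, t_end) == pytest.approx(ref, rel=1e-6)

    def test_steady_state_is_alpha_over_perm(self):
        p = EffluxParams(vol_in=1.0, perm=0.01, c_in_0=100.0, alpha=0.25)
        assert efflux_solution(p, 1e7) == pytest.approx(0.25 / 0.01, rel=1e-9)

    def test_zero_permeability_limit_is_linear_ramp(self):
        p = EffluxParams(vol_in=2.0, perm=0.0, c_in_0=10.0, alpha=0.1)
        t = np.array([0.0, 100.0, 200.0])
        assert np.allclose(efflux_solution(p, t), 10.0 + 0.05 * t)


class TestEffluxLinearApprox:
    CAL = FluorescenceCalibration(f=5.0, f0=100.0)

    def test_flat_at_balance_point(self):
        # alpha = C_in(t0) * P makes production cancel efflux exactly
        p = EffluxParams(vol_in=1.0, perm=0.01, c_in_0=50.0, alpha=0.5)
        f0 = efflux_linear_approx(p, self.CAL, 0.0, 0.0)
        assert efflux_linear_approx(p, self.CAL, 0.0, 500.0) == pytest.approx(f0)

    def test_slope_negative_without_production(self):
        p = EffluxParams(vol_in=1.0, perm=0.01, c_in_0=100.0, alpha=0.0)
        vals = efflux_linear_approx(p, self.CAL, 0.0, np.array([0.0, 10.0]))
        slope = (vals[1] - vals[0]) / 10.0
        assert slope == pytest.approx(-self.CAL.f * 100.0 * 0.01 / 1.0, rel=1e-12)
        assert slope < 0

    def test_slope_equals_exact_derivative(self):
        p = EffluxParams(vol_in=2.0, perm=3e-3, c_in_0=150.0, alpha=0.05)
        t0, h = 100.0, 1e-3
        approx_slope = (
            efflux_linear_approx(p, self.CAL, t0, t0 + h)
            - efflux_linear_approx(p, self.CAL, t0, t0)
        ) / h
        exact = (
            self.CAL.to_fluorescence(efflux_solution(p, t0 + h))
            - self.CAL.to_fluorescence(efflux_solution(p, t0 - h))
        ) / (2 * h)
        assert approx_slope == pytest.approx(exact, rel=1e-8)

    @pytest.mark.parametrize("rate", [1e-3, 1e-2, 1e-1])
    def test_within_one_percent_over_short_horizon(self, rate):
        p = EffluxParams(vol_in=1.0, perm=rate, c_in_0=100.0, alpha=0.0)
        horizon = 0.1 / rate  # 0.1 * Vol_in / P
        t = np.linspace(0.0, horizon, 20)
        lin = efflux_linear_approx(p, self.CAL, 0.0, t)
        exact = self.CAL.to_fluorescence(efflux_solution(p, t))
        assert np.max(np.abs(lin - exact) / exact) < 0.01


class TestRecipientSolution:
    def test_zero_rate_identity(self):
        t = np.linspace(0, 900, 31)
        assert np.all(recipient_solution(100.0, 10.0, 0.0, 0.0, t) == 10.0)

    def test_equilibrium_fixed_point(self):
        t = np.linspace(0, 900, 31)
        assert np.allclose(recipient_solution(80.0, 80.0, 5e-3, 0.0, t), 80.0)

    def test_matches_rk4_oracle(self):
        val = recipient_solution(100.0, 10.0, 0.0011, 0.0, 600.0)
        ref = rk4_recipient(100.0, 10.0, 0.0011, 600.0, h=0.01)
        assert val == pytest.approx(ref, rel=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(
        c1=st.floats(1.0, 1000.0),
        c2_t0=st.floats(0.0, 1000.0),
        rate=st.floats(0.0, 0.1),
    )
    def test_monotone_approach_to_donor_level(self, c1, c2_t0, rate):
        t = np.linspace(0, 2000, 60)
        c2 = recipient_solution(c1, c2_t0, rate, 0.0, t)
        diffs = np.diff(c2)
        if c1 > c2_t0:
            assert np.all(diffs >= -1e-12)
        elif c1 < c2_t0:
            assert np.all(diffs <= 1e-12)
        assert np.all((c2 - c1) * (c2_t0 - c1) >= -1e-9 * max(abs(c1), 1.0))

    def test_ratio_form_matches_concentration_form(self):
        c1, c2_t0, rate = 100.0, 10.0, 0.0011
        t = np.linspace(100.0, 900.0, 20)
        ratio = relative_fluorescence(c1 / c2_t0, rate, 100.0, t)
        conc = recipient_solution(c1, c2_t0, rate, 100.0, t)
        assert np.allclose(ratio, conc / c2_t0, rtol=1e-12)

    def test_ratio_undefined_for_nonpositive_start(self):
        with pytest.raises(ValueError):
            relative_fluorescence(0.0, 0.001, 0.0, 100.0)
        with pytest.raises(ValueError):
            relative_fluorescence(-2.0, 0.001, 0.0, 100.0)
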