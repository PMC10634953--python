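import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prebotc import biophysics as B
from prebotc.biophysics import (
    GateKinetics,
    IonEnvironment,
    NeuronParameters,
    NeuronState,
    RectifierKinetics,
    membrane_derivative,
    rectifier_activation,
    rectifier_rates,
    reversal_potentials,
    steady_state,
    steady_state_gates,
    time_constant,
)

NAP_M = B.NAP_M
NAP_H = B.NAP_H
K_RECT = B.K_RECT


class TestGateKinetics:
    def test_midpoint_is_half(self):
        kin = GateKinetics(-50.0, 4.0, 1.0, -50.0, 10.0)
        assert steady_state(kin, -50.0) == pytest.approx(0.5)

    def test_nap_activation_midpoint(self):
        # persistent-sodium activation midpoint -47.1 mV
        assert steady_state(NAP_M, -47.1) == pytest.approx(0.5)

    def test_inactivation_saturates_hyperpolarized(self):
        assert steady_state(NAP_H, -120.0) == pytest.approx(1.0, abs=1e-2)

    @pytest.mark.parametrize("kin,direction", [(NAP_M, 1), (NAP_H, -1)])
    def test_monotone_in_v(self, kin, direction):
        v = np.linspace(-100, 20, 200)
        dx = np.diff(steady_state(kin, v))
        assert np.all(direction * dx > 0)

    def test_shift_translates_midpoint(self):
        kin = GateKinetics(-40.0, 5.0, 1.0, -40.0, 10.0)
        assert steady_state(kin, -42.0, shift=-2.0) == pytest.approx(0.5)

    def test_tau_peak_at_tau_half(self):
        assert time_constant(NAP_H, -60.0) == pytest.approx(5000.0)
        assert time_constant(NAP_H, -60.0, shift=3.0) < 5000.0

    @given(st.floats(-30, 30))
    @settings(max_examples=25, deadline=None)
    def test_tau_symmetric_about_peak(self, d):
        assert time_constant(NAP_M, -47.1 + d) == pytest.approx(
            time_constant(NAP_M, -47.1 - d), rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            GateKinetics(-40.0, 0.0, 1.0, -40.0, 10.0)
        with pytest.raises(ValueError):
            GateKinetics(-40.0, 5.0, -1.0, -40.0, 10.0)


class TestRectifier:
    def test_removable_singularity_limit(self):
        # alpha is continuous at V = -B_alpha, with limit A_alpha * k_alpha
        a0, _ = rectifier_rates(K_RECT, -K_RECT.B_alpha)
        assert a0 == pytest.approx(K_RECT.A_alpha * K_RECT.k_alpha, abs=1e-9)
        for eps in (1e-6, -1e-6):
            a_eps, _ = rectifier_rates(K_RECT, -K_RECT.B_alpha + eps)
            assert a_eps == pytest.approx(a0, abs=1e-6)

    def test_alpha_at_zero_mv(self):
        # direct evaluation: 0.011 * 44 / (1 - exp(-44/5))
        expected = 0.011 * 44.0 / (1.0 - math.exp(-44.0 / 5.0))
        alpha, _ = rectifier_rates(K_RECT, 0.0)
        assert alpha == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-100, 40))
    @settings(max_examples=25, deadline=None)
    def test_normalized_and_positive(self, v):
        m_inf, tau = rectifier_activation(K_RECT, v)
        assert 0 < m_inf < 1
        assert tau > 0


class TestReversalPotentials:
    def test_sodium_nernst(self, env):
        # 26.54 * ln(120/15)
        assert env.E_Na == pytest.approx(26.54 * math.log(8.0), rel=1e-12)
        assert env.E_Na == pytest.approx(55.19, abs=0.01)

    def test_potassium_zero_at_equal_concentrations(self):
        env = IonEnvironment(K_bath=125.0)
        assert env.E_K == pytest.approx(0.0, abs=1e-12)

    def test_leak_ghk_value(self, env):
        num = 1 * 15 + 42 * 125
        den = 1 * 120 + 42 * 8.5
        assert env.E_Leak == pytest.approx(-26.54 * math.log(num / den), rel=1e-12)
        assert env.E_Leak == pytest.approx(-63.74, abs=0.01)

    def test_triple(self, env):
        e_na, e_k, e_leak = reversal_potentials(env)
        assert (e_na, e_k, e_leak) == (env.E_Na, env.E_K, env.E_Leak)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            IonEnvironment(K_bath=0.0)


class TestMembraneDerivative:
    def test_no_conductances_no_current(self, env):
        p = NeuronParameters(g_Na=0, g_K=0, g_NaP=0, g_Leak=0, g_Tonic=0)
        state = steady_state_gates(p, env, -50.0)
        dv, _ = membrane_derivative(state, p, env)
        assert dv == pytest.approx(0.0)

    def test_zero_driving_force_at_reversal(self, env):
        p = NeuronParameters(g_Na=100.0, g_K=0, g_NaP=0, g_Leak=0)
        state = steady_state_gates(p, env, env.E_Na)
        dv, _ = membrane_derivative(state, p, env)
        assert dv == pytest.approx(0.0, abs=1e-9)

    def test_leak_only_fixed_point(self, env):
        p = NeuronParameters(g_Na=0, g_K=0, g_NaP=0, g_Leak=2.0, g_Tonic=0)
        state = steady_state_gates(p, env, env.E_Leak)
        dv, _ = membrane_derivative(state, p, env)
        assert dv == pytest.approx(0.0, abs=1e-12)
        below = steady_state_gates(p, env, env.E_Leak - 5)
        above = steady_state_gates(p, env, env.E_Leak + 5)
        assert membrane_derivative(below, p, env)[0] > 0
        assert membrane_derivative(above, p, env)[0] < 0

    def test_currents_linear_in_conductance(self, env):
        state = steady_state_gates(NeuronParameters(), env, -50.0)
        base = NeuronParameters(g_Na=0, g_K=0, g_NaP=0, g_Leak=0)
        dv1, _ = membrane_derivative(state, base.with_(g_NaP=2.0), env)
        dv2, _ = membrane_derivative(state, base.with_(g_NaP=4.0), env)
        assert dv2 == pytest.approx(2 * dv1, rel=1e-12)

    @given(st.floats(-90, 0), st.sampled_from([0.0, 1.0]))
    @settings(max_examples=30, deadline=None)
    def test_gate_derivatives_preserve_bounds(self, v, x):
        # at the boundary of [0,1] every gate relaxes inward
        p = NeuronParameters()
        env = IonEnvironment()
        state = NeuronState(V=v)
        for name in B.GATE_NAMES:
            setattr(state, name, x)
        _, dg = membrane_derivative(state, p, env)
        for name, d in dg.items():
            if x == 0.0:
                assert d >= 0
            else:
                assert d <= 0

    def test_state_validation(self):
        s = NeuronState(m_Na=1.5)
        with pytest.raises(ValueError):
            s.validate()

    def test_conductance_validation(self):
        with pytest.raises(ValueError):
            NeuronParameters(g_NaP=-1.0)


class TestRateTables:
    def test_tables_match_reference_functions(self, env, canonical):
        tab = B.rate_tables(canonical, env, dt=0.025)
        v_grid = np.arange(B.TABLE_V_MIN, B.TABLE_V_MAX + B.TABLE_DV / 2, B.TABLE_DV)
        # row 12/13: m_NaP steady state and rate
        idx = np.searchsorted(v_grid, -47.1)
        assert tab[12, idx] == pytest.approx(
            float(steady_state(canonical.nap_m, v_grid[idx])), rel=1e-12)
        tau = float(time_constant(canonical.nap_m, v_grid[idx]))
        assert tab[13, idx] == pytest.approx(0.025 / tau, rel=1e-12)

    def test_temperature_scales_rates(self, env, canonical):
        t1 = B.rate_tables(canonical, env, dt=0.025, tau_scale=1.0)
        t2 = B.rate_tables(canonical, env, dt=0.025, tau_scale=2.0)
        # doubling every time constant halves every relaxation factor
        assert np.allclose(t2[1::2], t1[1::2] / 2)
        assert np.allclose(t2[0::2], t1[0::2])
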