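"""Hodgkin-Huxley gating, receptor kinetics and membrane current laws."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

import trisyn
from trisyn.neuron import (NeuronState, gating_steady_states_and_taus,
                           membrane_derivative, mg_block,
                           receptor_currents, receptor_kinetics_derivative,
                           voltage_gated_currents)

from conftest import VT

volts = st.floats(min_value=-0.120, max_value=0.060)


def test_gating_midpoints():
    m, h, tau_h, n, tau_n = gating_steady_states_and_taus(-0.030)
    assert m == pytest.approx(0.5, abs=1e-12)
    assert gating_steady_states_and_taus(-0.035)[3] == pytest.approx(0.5, abs=1e-12)
    assert gating_steady_states_and_taus(-0.045)[1] == pytest.approx(0.5, abs=1e-12)


def test_m_inf_at_rest():
    # 1/(1 + e^((-30+71)/9.5)) by hand
    expected = 1.0 / (1.0 + math.exp(41.0 / 9.5))
    assert gating_steady_states_and_taus(-0.071)[0] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.0132, abs=5e-5)


@given(v1=volts, v2=volts)
def test_gating_orientation_and_bounds(v1, v2):
    lo, hi = sorted((v1, v2))
    m1, h1, th1, n1, tn1 = gating_steady_states_and_taus(lo)
    m2, h2, th2, n2, tn2 = gating_steady_states_and_taus(hi)
    for val in (m1, h1, n1, m2, h2, n2):
        assert 0.0 < val < 1.0
    for tau in (th1, tn1, th2, tn2):
        assert tau > 0.0
    if hi > lo:
        assert m2 >= m1 and n2 >= n1   # activation gates increase with V
        assert h2 <= h1                # inactivation decreases with V


def test_voltage_gated_current_identities():
    # at V = E_L with no Na/K conductance only the (zero) leak remains
    i_na, i_k, i_l = voltage_gated_currents(-0.0746, 0.5, 0.5, 0.0, 0.0,
                                            0.112, 0.0597, -0.093, -0.0746)
    assert i_na == 0.0 and i_k == 0.0 and i_l == 0.0
    # full inactivation silences the Na current
    i_na, _, _ = voltage_gated_currents(-0.020, 0.0, 0.5, 350.0, 60.0,
                                        0.112, 0.0597, -0.093, -0.0746)
    assert i_na == 0.0


def test_sodium_reversal_from_bath():
    # E_Na = (RT/F) ln(Na_syn / Na_neuron) = 26.715 mV * ln(140/15)
    e_na = VT * math.log(140.0 / 15.0)
    assert e_na * 1e3 == pytest.approx(59.67, abs=0.01)


def test_mg_block_values():
    assert mg_block(0.123, 0.0) == 1.0
    assert mg_block(-0.080, 0.0) == 1.0
    assert mg_block(0.0, 1.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57), rel=1e-12)
    expected = 1.0 / (1.0 + math.exp(0.062 * 70.0) / 3.57)
    assert mg_block(-0.070, 1.0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.0445, abs=5e-5)


@given(v1=volts, v2=volts, mg=st.floats(min_value=0.0, max_value=10.0))
def test_mg_block_monotone_increasing(v1, v2, mg):
    lo, hi = sorted((v1, v2))
    b_lo, b_hi = mg_block(lo, mg), mg_block(hi, mg)
    assert 0.0 < b_lo <= 1.0 and 0.0 < b_hi <= 1.0
    assert b_hi >= b_lo


def test_receptor_fixed_point_and_empty_state():
    assert receptor_kinetics_derivative(0.0, 0.0, 1.1e3, 190.0) == 0.0
    # AMPA at 1 mM Glu: r* = alpha c/(alpha c + beta) = 1.1/(1.1+0.19)
    r_star = 1.1e3 * 1.0 / (1.1e3 * 1.0 + 190.0)
    assert r_star == pytest.approx(0.8527, abs=5e-5)
    assert receptor_kinetics_derivative(r_star, 1.0, 1.1e3, 190.0) == pytest.approx(0.0, abs=1e-9)
    # GABA_A unbinding at beta = 0.72/ms: dr/dt = -720/s from the full state
    assert receptor_kinetics_derivative(1.0, 0.0, 5.0e2, 720.0) == -720.0


def test_receptor_kinetics_match_closed_form():
    """Two-state kinetics at fixed agonist agree with the exponential
    solution r(t) = r* + (r0 - r*) exp(-(alpha c + beta) t)."""
    alpha, beta, c = 1.1e3, 190.0, 0.3
    rate = alpha * c + beta
    r_star = alpha * c / rate
    sol = solve_ivp(lambda t, r: receptor_kinetics_derivative(r[0], c, alpha, beta),
                    (0.0, 0.02), [0.0], rtol=1e-11, atol=1e-13,
                    t_eval=[0.005, 0.02])
    exact = r_star + (0.0 - r_star) * np.exp(-rate * sol.t)
    assert np.allclose(sol.y[0], exact, rtol=1e-8)


def test_receptor_currents(prepared):
    params = prepared.config.neuron
    silent = NeuronState(v=-0.060, h=0.5, n=0.5)
    assert receptor_currents(silent, params) == (0.0, 0.0, 0.0)
    at_rev = NeuronState(v=-0.085, h=0.5, n=0.5, r_gabaa=0.7)
    assert receptor_currents(at_rev, params)[2] == pytest.approx(0.0, abs=1e-15)
    # 0.0145 mS/cm^2 * 0.5 * (-60 mV) = -0.435 uA/cm^2 = -4.35e-3 A/m^2
    half_ampa = NeuronState(v=-0.060, h=0.5, n=0.5, r_ampa=0.5)
    assert receptor_currents(half_ampa, params)[1] == pytest.approx(-4.35e-3, rel=1e-12)


def test_membrane_derivative_sign_convention():
    assert membrane_derivative(0.0, 0.0, 0.0, 0.01) == 0.0
    # a positive (depolarising) 5 uA/cm^2 stimulus raises V at 5 mV/ms
    assert membrane_derivative(0.0, 0.0, 0.05, 0.01) == pytest.approx(5.0)


def test_quiescent_at_rest_and_spiking_above_rheobase():
    cfg = trisyn.default_config(gat3_enabled=False, gabaa_placement="none",
                                duration=1.0)
    rest = trisyn.Protocol(amplitude=0.0, window_start=1e9,
                           window_duration=0.0, total_duration=1.0)
    res = trisyn.run(cfg, rest)
    assert res.spikes_pre.size == 0 and res.spikes_post.size == 0
    assert np.ptp(res.traces["v_pre"]) < 1e-6
    drive = trisyn.Protocol(amplitude=5.0, window_start=0.1,
                            window_duration=0.8, pulse_width=0.099,
                            pulse_rate=10.0, total_duration=1.0)
    res = trisyn.run(cfg, drive)
    assert res.spikes_pre.size > 10  # sustained drive -> repetitive firing


def test_gates_and_receptors_stay_bounded_while_spiking():
    """Euler at the reference dt keeps gates/open fractions in [0, 1]
    without clamping, including through spikes."""
    cfg = trisyn.default_config(duration=0.06)
    prep = trisyn.prepare(cfg)
    state = trisyn.initial_state(cfg, prep)
    for i in range(6000):
        i_app = 0.05 if i < 2000 else 0.0
        state = trisyn.step(state, prep.config, 1e-5, prep.leaks, i_app)
        for val in (state.pre.h, state.pre.n, state.pre.r_gabaa,
                    state.post.h, state.post.n, state.post.r_nmda,
                    state.post.r_ampa, state.post.r_gabaa):
            assert 0.0 <= val <= 1.0
    assert state.last_spike_pre > 0.0  # the pulse did elicit spikes
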