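"""Hodgkin-Huxley membrane and ionotropic receptor current laws.

Both neurons use the same fast-spiking conductance set: an instantaneously
activating Na+ current (m = m_inf(V)) with inactivation gate h, a delayed
rectifier K+ current with activation gate n, an ohmic leak, and two-state
ligand-gated receptor channels (NMDA with a voltage-dependent Mg2+ block,
AMPA, GABA_A).  The gating sigmoids are written in mV with the printed
midpoints and slopes; every public function takes canonical units (V, s,
S/m^2, A/m^2, mM) unless its name says otherwise.

Sign conventions: membrane currents are positive outward, so
``C dV/dt = -(sum of membrane currents) + I_app`` with a positive applied
current depolarising the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "NeuronState",
    "gating_steady_states_and_taus",
    "voltage_gated_currents",
    "mg_block",
    "receptor_kinetics_derivative",
    "receptor_currents",
    "membrane_derivative",
]


@dataclass
class NeuronState:
    """Dynamic state of one neuron (canonical units: V in volts)."""

    v: float
    h: float
    n: float
    r_nmda: float = 0.0
    r_ampa: float = 0.0
    r_gabaa: float = 0.0


@njit(cache=True)
def m_inf(v_mv):
    """Instantaneous Na+ activation; half-activation at -30 mV, slope 9.5 mV."""
    return 1.0 / (1.0 + np.exp(-(v_mv + 30.0) / 9.5))


@njit(cache=True)
def h_inf(v_mv):
    """Na+ inactivation steady state; half at -45 mV, decreasing with V."""
    return 1.0 / (1.0 + np.exp((v_mv + 45.0) / 7.0))


@njit(cache=True)
def tau_h_ms(v_mv):
    """Na+ inactivation time constant (ms): 0.1 + 0.75 sigmoid, width 6 mV."""
    return 0.1 + 0.75 / (1.0 + np.exp((v_mv + 40.5) / 6.0))


@njit(cache=True)
def n_inf(v_mv):
    """K+ activation steady state; half at -35 mV, slope 10 mV."""
    return 1.0 / (1.0 + np.exp(-(v_mv + 35.0) / 10.0))


@njit(cache=True)
def tau_n_ms(v_mv):
    """K+ activation time constant (ms): 0.1 + 0.5 sigmoid, width 15 mV."""
    return 0.1 + 0.5 / (1.0 + np.exp((v_mv + 27.0) / 15.0))


def gating_steady_states_and_taus(v: float):
    """Steady states and time constants of the voltage gates.

    Parameters
    ----------
    v : membrane potential in volts.

    Returns
    -------
    (m_inf, h_inf, tau_h, n_inf, tau_n) with time constants in seconds.
    """
    v_mv = v * 1e3
    return (
        m_inf(v_mv),
        h_inf(v_mv),
        tau_h_ms(v_mv) * 1e-3,
        n_inf(v_mv),
        tau_n_ms(v_mv) * 1e-3,
    )


@njit(cache=True)
def voltage_gated_currents(v, h, n, g_na, g_k, g_leak, e_na, e_k, e_leak):
    """Intrinsic currents (A/m^2): I_Na = g m_inf^3 h (V-E_Na), I_K = g n^4 (V-E_K),
    I_L = g (V-E_L).  E_Na/E_K are Nernst potentials of the synaptic bath
    against the fixed neuron-internal concentrations."""
    m = m_inf(v * 1e3)
    i_na = g_na * m * m * m * h * (v - e_na)
    i_k = g_k * n ** 4 * (v - e_k)
    i_leak = g_leak * (v - e_leak)
    return i_na, i_k, i_leak


@njit(cache=True)
def mg_block(v, mg):
    """Voltage-dependent Mg2+ block of the NMDA channel, in (0, 1].

    ``v`` in volts, ``mg`` in mM; factor = 1/(1 + exp(-0.062 V_mV) Mg/3.57).
    """
    return 1.0 / (1.0 + np.exp(-0.062 * v * 1e3) * mg / 3.57)


@njit(cache=True)
def receptor_kinetics_derivative(r, agonist, alpha, beta):
    """Two-state binding scheme: dr/dt = alpha [A] (1-r) - beta r.

    ``agonist`` in mM, ``alpha`` in mM^-1 s^-1, ``beta`` in s^-1.  At fixed
    agonist c the open fraction relaxes to r* = alpha c / (alpha c + beta).
    """
    return alpha * agonist * (1.0 - r) - beta * r


@njit(cache=True)
def _receptor_currents(v, r_nmda, r_ampa, r_gabaa,
                       g_nmda, g_ampa, g_gabaa,
                       e_nmda, e_ampa, e_gabaa, mg):
    i_nmda = g_nmda * r_nmda * (v - e_nmda) * mg_block(v, mg)
    i_ampa = g_ampa * r_ampa * (v - e_ampa)
    i_gabaa = g_gabaa * r_gabaa * (v - e_gabaa)
    return i_nmda, i_ampa, i_gabaa


def receptor_currents(state: NeuronState, params, mg: float | None = None):
    """Receptor-mediated currents (I_NMDA, I_AMPA, I_GABAA) in A/m^2.

    ``params`` is a canonical-unit :class:`~trisyn.params.NeuronParams`;
    ``mg`` overrides the configured Mg2+ level if given.
    """
    mg_level = params.mg if mg is None else mg
    return _receptor_currents(
        state.v, state.r_nmda, state.r_ampa, state.r_gabaa,
        params.g_nmda, params.g_ampa, params.g_gabaa,
        params.e_nmda, params.e_ampa, params.e_gabaa, mg_level,
    )


@njit(cache=True)
def membrane_derivative(i_intrinsic, i_synaptic, i_app, c_m):
    """dV/dt (V/s) from the current balance.

    ``i_intrinsic`` is the summed voltage-gated + leak current, ``i_synaptic``
    the summed receptor current, and ``i_app`` a positive-depolarising applied
    current density; all A/m^2, ``c_m`` in F/m^2.
    """
    return (-(i_intrinsic + i_synaptic) + i_app) / c_m
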