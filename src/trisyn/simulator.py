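"""State assembly, Faraday flux conversion, integration driver and result I/O.

The simulator couples the two Hodgkin-Huxley neurons, the vesicle-resource
pools and the synaptic/astrocytic concentration compartments.  Only
astrocytic membrane currents move concentrations; the neurons read the bath
(through their Nernst potentials and receptor agonists) but do not load it.
Presynaptic spikes inject Glu and K+ into the cleft; those injections are
accumulated in a mole ledger so that per-species mass balance across the two
compartments can be audited exactly.

Integration is fixed-step forward Euler at the configured dt (0.01 ms by
default).  ``run`` uses the compiled kernel; ``step`` is a pure-Python
reference used for cross-checking and for inspecting single transitions.
Runs are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import h5py
import numpy as np

from . import kernel as K
from .astro import CompartmentConcentrations
from .equilibrium import PreparedModel, prepare
from .neuron import NeuronState
from .params import (ModelConfig, config_hash, config_to_dict,
                     normalize_units)
from .release import ResourceState, apply_spike, release_into_synapse

__all__ = [
    "FullState",
    "SimResult",
    "SimulationError",
    "current_to_flux",
    "initial_state",
    "derivatives",
    "step",
    "run",
    "write_result",
    "read_result",
]

SCHEMA_VERSION = 1

_SLOT_NAMES = {slot: name for name, slot in {
    "na_syn": K.S_NA_SYN, "k_syn": K.S_K_SYN, "glu_syn": K.S_GLU_SYN,
    "ca_syn": K.S_CA_SYN, "gaba_syn": K.S_GABA_SYN,
    "na_ast": K.S_NA_AST, "k_ast": K.S_K_AST, "glu_ast": K.S_GLU_AST,
    "ca_ast": K.S_CA_AST, "gaba_ast": K.S_GABA_AST,
}.items()}


class SimulationError(RuntimeError):
    """Integration failure (non-finite state or non-positive concentration)."""


def current_to_flux(i_species: float, valence: int, area: float, volume: float,
                    faraday: float = 96480.0, compartment: str = "ast") -> float:
    """Concentration rate (mM/s) produced by a species current (A/m^2).

    ``d[X]_ast/dt = -I S_A / (z F Vol_A)`` and
    ``d[X]_syn/dt = +I S_A / (z F Vol_S)``; ``volume`` in litres, the 1e3
    factor converts mol/L to mM.
    """
    if valence == 0:
        raise ValueError("current_to_flux: valence must be non-zero")
    if volume <= 0:
        raise ValueError("current_to_flux: volume must be positive")
    rate = 1e3 * i_species * area / (valence * faraday * volume)
    if compartment == "ast":
        return -rate
    if compartment == "syn":
        return rate
    raise ValueError("compartment must be 'ast' or 'syn'")


@dataclass
class FullState:
    """Complete dynamic state at one instant (canonical units)."""

    t: float
    pre: NeuronState
    post: NeuronState
    resources: ResourceState
    syn: CompartmentConcentrations
    ast: CompartmentConcentrations
    injected_glu: float = 0.0   # cumulative externally injected Glu (mol)
    injected_k: float = 0.0     # cumulative externally injected K+ (mol)
    last_spike_pre: float = -1e9
    last_spike_post: float = -1e9

    def to_vector(self) -> np.ndarray:
        s = np.empty(K.NSTATE)
        s[K.S_V_PRE], s[K.S_H_PRE], s[K.S_N_PRE] = self.pre.v, self.pre.h, self.pre.n
        s[K.S_RG_PRE] = self.pre.r_gabaa
        s[K.S_V_POST], s[K.S_H_POST], s[K.S_N_POST] = self.post.v, self.post.h, self.post.n
        s[K.S_RN_POST], s[K.S_RA_POST], s[K.S_RG_POST] = (
            self.post.r_nmda, self.post.r_ampa, self.post.r_gabaa)
        s[K.S_X], s[K.S_Y], s[K.S_Z] = (
            self.resources.x, self.resources.y, self.resources.z)
        s[K.S_NA_SYN], s[K.S_K_SYN], s[K.S_GLU_SYN] = self.syn.na, self.syn.k, self.syn.glu
        s[K.S_CA_SYN], s[K.S_GABA_SYN] = self.syn.ca, self.syn.gaba
        s[K.S_NA_AST], s[K.S_K_AST], s[K.S_GLU_AST] = self.ast.na, self.ast.k, self.ast.glu
        s[K.S_CA_AST], s[K.S_GABA_AST] = self.ast.ca, self.ast.gaba
        s[K.S_LED_GLU], s[K.S_LED_K] = self.injected_glu, self.injected_k
        return s

    @classmethod
    def from_vector(cls, s: np.ndarray, t: float = 0.0,
                    last_spike_pre: float = -1e9,
                    last_spike_post: float = -1e9) -> "FullState":
        return cls(
            t=t,
            pre=NeuronState(v=s[K.S_V_PRE], h=s[K.S_H_PRE], n=s[K.S_N_PRE],
                            r_gabaa=s[K.S_RG_PRE]),
            post=NeuronState(v=s[K.S_V_POST], h=s[K.S_H_POST], n=s[K.S_N_POST],
                             r_nmda=s[K.S_RN_POST], r_ampa=s[K.S_RA_POST],
                             r_gabaa=s[K.S_RG_POST]),
            resources=ResourceState(x=s[K.S_X], y=s[K.S_Y], z=s[K.S_Z]),
            syn=CompartmentConcentrations(na=s[K.S_NA_SYN], k=s[K.S_K_SYN],
                                          glu=s[K.S_GLU_SYN], ca=s[K.S_CA_SYN],
                                          gaba=s[K.S_GABA_SYN]),
            ast=CompartmentConcentrations(na=s[K.S_NA_AST], k=s[K.S_K_AST],
                                          glu=s[K.S_GLU_AST], ca=s[K.S_CA_AST],
                                          gaba=s[K.S_GABA_AST]),
            injected_glu=s[K.S_LED_GLU], injected_k=s[K.S_LED_K],
            last_spike_pre=last_spike_pre, last_spike_post=last_spike_post,
        )


def initial_state(config: ModelConfig, prepared: PreparedModel | None = None
                  ) -> FullState:
    """Calibrated equilibrium state at t = 0."""
    prep = prepared or prepare(config)
    return FullState(t=0.0, pre=prep.pre0, post=prep.post0,
                     resources=prep.resources0, syn=prep.syn0, ast=prep.ast0)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _pack_params(prep: PreparedModel, protocol) -> np.ndarray:
    cfg = prep.config
    n, r, a, g = cfg.neuron, cfg.release, cfg.astro, cfg.geometry
    c = cfg.constants
    p = np.zeros(K.NPARAMS)
    p[K.P_VT] = c.thermal_voltage
    p[K.P_F_AST] = g.area_ast * 1e3 / (c.faraday * g.vol_ast)
    p[K.P_F_SYN] = g.area_ast * 1e3 / (c.faraday * g.vol_syn)
    p[K.P_MOL_SYN] = g.vol_syn / 1e3  # mM -> mol in the synaptic compartment
    p[K.P_CM] = n.c_m
    p[K.P_GNA], p[K.P_GK], p[K.P_GL], p[K.P_EL] = n.g_na, n.g_k, n.g_leak, n.e_leak
    p[K.P_GNMDA], p[K.P_GAMPA] = n.g_nmda, n.g_ampa
    p[K.P_GGABAA_PRE] = n.g_gabaa if cfg.gabaa_placement == "both" else 0.0
    p[K.P_GGABAA_POST] = (n.g_gabaa if cfg.gabaa_placement in ("both", "post_only")
                          else 0.0)
    p[K.P_ENMDA], p[K.P_EAMPA], p[K.P_EGABAA] = n.e_nmda, n.e_ampa, n.e_gabaa
    p[K.P_ANMDA], p[K.P_AAMPA], p[K.P_AGABAA] = n.alpha_nmda, n.alpha_ampa, n.alpha_gabaa
    p[K.P_BNMDA], p[K.P_BAMPA], p[K.P_BGABAA] = n.beta_nmda, n.beta_ampa, n.beta_gabaa
    p[K.P_NA_IN], p[K.P_K_IN], p[K.P_MG] = n.na_internal, n.k_internal, n.mg
    p[K.P_U], p[K.P_TAU_R], p[K.P_TAU_I] = r.u, r.tau_r, r.tau_i
    p[K.P_GLU_SCALE], p[K.P_K_RELEASE] = r.glu_scale, r.k_release
    p[K.P_RELEASE_CONT] = 1.0 if cfg.release_mode == "continuous" else 0.0
    p[K.P_INKA], p[K.P_KNAI], p[K.P_KKE] = a.i_nka_max, a.k_nai, a.k_ke
    p[K.P_INCX], p[K.P_GAMMA] = a.i_ncx_max, a.gamma
    p[K.P_AEAAT], p[K.P_BEAAT] = a.alpha_eaat, a.beta_eaat
    p[K.P_GKIR] = a.g_kir
    p[K.P_GGAT] = a.g_gat if cfg.gat3_enabled else 0.0
    p[K.P_EKIR_OFF] = a.e_kir_offset
    p[K.P_INKCC] = a.i_nkcc_max
    p[K.P_NKCC_ON] = 1.0 if cfg.nkcc_enabled else 0.0
    p[K.P_SNKAK] = cfg.nka_k_sign
    p[K.P_VA] = cfg.v_ast
    p[K.P_HRATIO] = cfg.init.h_ratio
    p[K.P_CLRATIO] = cfg.init.cl_ratio
    p[K.P_GLNA] = prep.leaks["na"]
    p[K.P_GLK] = prep.leaks["k"]
    p[K.P_GLGLU] = prep.leaks["glu"]
    p[K.P_GLCA] = prep.leaks["ca"]
    p[K.P_ZNA], p[K.P_ZK] = a.z_na, a.z_k
    p[K.P_ZGLU], p[K.P_ZCA], p[K.P_ZGABA] = a.z_glu, a.z_ca, a.z_gaba
    # protocol, converted to canonical units (amplitude arrives in uA/cm^2)
    p[K.P_AMP] = protocol.amplitude * 0.01
    p[K.P_RATE] = protocol.pulse_rate
    p[K.P_WIDTH] = protocol.pulse_width
    p[K.P_WSTART] = protocol.window_start
    p[K.P_WDUR] = protocol.window_duration
    p[K.P_THRESH] = protocol.threshold * 1e-3
    p[K.P_REFRACT] = protocol.refractory
    return p


# ---------------------------------------------------------------------------
# pure-Python reference step (mirrors the kernel)
# ---------------------------------------------------------------------------

def derivatives(state: FullState, config: ModelConfig,
                leaks: dict[str, float], i_app: float = 0.0) -> np.ndarray:
    """Continuous-part state derivative vector (kernel layout, per second)."""
    p = _cached_params(normalize_units(config), tuple(sorted(leaks.items())))
    return _python_derivatives(state.to_vector(), p, i_app)


@lru_cache(maxsize=64)
def _cached_params(cfg: ModelConfig, leaks_items: tuple) -> np.ndarray:
    return _PackShim(cfg, dict(leaks_items)).p


class _PackShim:
    """Packs parameters for a config + leak map (no protocol)."""

    def __init__(self, config: ModelConfig, leaks: dict[str, float]):
        cfg = normalize_units(config)
        prep = PreparedModel(config=cfg, syn0=None, ast0=None, leaks=leaks,
                             pre0=None, post0=None, resources0=None)
        self.p = _pack_params(prep, _NullProtocol())


class _NullProtocol:
    amplitude = 0.0
    pulse_rate = 1.0
    pulse_width = 0.0
    window_start = 0.0
    window_duration = 0.0
    threshold = 0.0
    refractory = 2e-3


def _python_derivatives(s: np.ndarray, p: np.ndarray, i_app: float) -> np.ndarray:
    from .astro import (_eaat_current, _species_currents, eaat_reversal,
                        gat_current, gat_reversal, kir_current, leak_current,
                        nernst, nka_current, ncx_current, nkcc_current)
    from .neuron import (h_inf, mg_block, n_inf, receptor_kinetics_derivative,
                         tau_h_ms, tau_n_ms, voltage_gated_currents)
    from .release import resource_derivatives

    d = np.zeros(K.NSTATE)
    vt = p[K.P_VT]
    e_na_n = vt * np.log(s[K.S_NA_SYN] / p[K.P_NA_IN])
    e_k_n = vt * np.log(s[K.S_K_SYN] / p[K.P_K_IN])

    i_na, i_k, i_l = voltage_gated_currents(
        s[K.S_V_PRE], s[K.S_H_PRE], s[K.S_N_PRE],
        p[K.P_GNA], p[K.P_GK], p[K.P_GL], e_na_n, e_k_n, p[K.P_EL])
    i_gabaa_pre = p[K.P_GGABAA_PRE] * s[K.S_RG_PRE] * (s[K.S_V_PRE] - p[K.P_EGABAA])
    d[K.S_V_PRE] = (-(i_na + i_k + i_l + i_gabaa_pre) + i_app) / p[K.P_CM]
    v_mv = s[K.S_V_PRE] * 1e3
    d[K.S_H_PRE] = (h_inf(v_mv) - s[K.S_H_PRE]) / (tau_h_ms(v_mv) * 1e-3)
    d[K.S_N_PRE] = (n_inf(v_mv) - s[K.S_N_PRE]) / (tau_n_ms(v_mv) * 1e-3)
    d[K.S_RG_PRE] = receptor_kinetics_derivative(
        s[K.S_RG_PRE], s[K.S_GABA_SYN], p[K.P_AGABAA], p[K.P_BGABAA])

    i_na, i_k, i_l = voltage_gated_currents(
        s[K.S_V_POST], s[K.S_H_POST], s[K.S_N_POST],
        p[K.P_GNA], p[K.P_GK], p[K.P_GL], e_na_n, e_k_n, p[K.P_EL])
    i_nmda = (p[K.P_GNMDA] * s[K.S_RN_POST] * (s[K.S_V_POST] - p[K.P_ENMDA])
              * mg_block(s[K.S_V_POST], p[K.P_MG]))
    i_ampa = p[K.P_GAMPA] * s[K.S_RA_POST] * (s[K.S_V_POST] - p[K.P_EAMPA])
    i_gb = p[K.P_GGABAA_POST] * s[K.S_RG_POST] * (s[K.S_V_POST] - p[K.P_EGABAA])
    d[K.S_V_POST] = (-(i_na + i_k + i_l + i_nmda + i_ampa + i_gb)) / p[K.P_CM]
    v_mv = s[K.S_V_POST] * 1e3
    d[K.S_H_POST] = (h_inf(v_mv) - s[K.S_H_POST]) / (tau_h_ms(v_mv) * 1e-3)
    d[K.S_N_POST] = (n_inf(v_mv) - s[K.S_N_POST]) / (tau_n_ms(v_mv) * 1e-3)
    d[K.S_RN_POST] = receptor_kinetics_derivative(
        s[K.S_RN_POST], s[K.S_GLU_SYN], p[K.P_ANMDA], p[K.P_BNMDA])
    d[K.S_RA_POST] = receptor_kinetics_derivative(
        s[K.S_RA_POST], s[K.S_GLU_SYN], p[K.P_AAMPA], p[K.P_BAMPA])
    d[K.S_RG_POST] = receptor_kinetics_derivative(
        s[K.S_RG_POST], s[K.S_GABA_SYN], p[K.P_AGABAA], p[K.P_BGABAA])

    d[K.S_X], d[K.S_Y], d[K.S_Z] = resource_derivatives(
        s[K.S_X], s[K.S_Y], s[K.S_Z], p[K.P_TAU_R], p[K.P_TAU_I])

    e_eaat = eaat_reversal(s[K.S_NA_SYN], s[K.S_NA_AST], p[K.P_HRATIO],
                           s[K.S_GLU_SYN], s[K.S_GLU_AST],
                           s[K.S_K_SYN], s[K.S_K_AST], vt)
    e_gat = gat_reversal(s[K.S_NA_SYN], s[K.S_NA_AST], s[K.S_GABA_SYN],
                         s[K.S_GABA_AST], p[K.P_CLRATIO], vt)
    i_eaat = _eaat_current(p[K.P_VA], e_eaat, p[K.P_AEAAT], p[K.P_BEAAT])
    i_gat = gat_current(p[K.P_VA], e_gat, p[K.P_GGAT])
    i_nka = nka_current(s[K.S_NA_AST], s[K.S_K_SYN], p[K.P_INKA],
                        p[K.P_KNAI], p[K.P_KKE])
    i_ncx = ncx_current(s[K.S_NA_AST], s[K.S_NA_SYN], s[K.S_CA_AST],
                        s[K.S_CA_SYN], p[K.P_VA], p[K.P_INCX], p[K.P_GAMMA], vt)
    e_k_ast = nernst(s[K.S_K_SYN], s[K.S_K_AST], p[K.P_ZK], vt)
    i_kir = kir_current(s[K.S_K_SYN], p[K.P_VA], e_k_ast, p[K.P_GKIR],
                        p[K.P_EKIR_OFF])
    i_nkcc = 0.0
    if p[K.P_NKCC_ON] != 0.0:
        i_nkcc = nkcc_current(s[K.S_NA_SYN], s[K.S_NA_AST], s[K.S_K_SYN],
                              s[K.S_K_AST], p[K.P_CLRATIO], p[K.P_INKCC])
    i_na_leak = leak_current(p[K.P_GLNA], p[K.P_VA],
                             nernst(s[K.S_NA_SYN], s[K.S_NA_AST], p[K.P_ZNA], vt))
    i_k_leak = leak_current(p[K.P_GLK], p[K.P_VA], e_k_ast)
    i_glu_leak = leak_current(p[K.P_GLGLU], p[K.P_VA],
                              nernst(s[K.S_GLU_SYN], s[K.S_GLU_AST], p[K.P_ZGLU], vt))
    i_ca_leak = leak_current(p[K.P_GLCA], p[K.P_VA],
                             nernst(s[K.S_CA_SYN], s[K.S_CA_AST], p[K.P_ZCA], vt))
    i_na_sp, i_k_sp, i_glu_sp, i_ca_sp, i_gaba_sp = _species_currents(
        i_eaat, i_gat, i_nka, i_ncx, i_kir, i_nkcc,
        i_na_leak, i_k_leak, i_glu_leak, i_ca_leak,
        p[K.P_SNKAK], p[K.P_NKCC_ON] != 0.0)

    f_ast, f_syn = p[K.P_F_AST], p[K.P_F_SYN]
    d[K.S_NA_AST] = -f_ast * i_na_sp / p[K.P_ZNA]
    d[K.S_NA_SYN] = f_syn * i_na_sp / p[K.P_ZNA]
    d[K.S_K_AST] = -f_ast * i_k_sp / p[K.P_ZK]
    d[K.S_K_SYN] = f_syn * i_k_sp / p[K.P_ZK]
    d[K.S_GLU_AST] = -f_ast * i_glu_sp / p[K.P_ZGLU]
    d[K.S_GLU_SYN] = f_syn * i_glu_sp / p[K.P_ZGLU]
    d[K.S_CA_AST] = -f_ast * i_ca_sp / p[K.P_ZCA]
    d[K.S_CA_SYN] = f_syn * i_ca_sp / p[K.P_ZCA]
    d[K.S_GABA_AST] = -f_ast * i_gaba_sp / p[K.P_ZGABA]
    d[K.S_GABA_SYN] = f_syn * i_gaba_sp / p[K.P_ZGABA]
    if p[K.P_RELEASE_CONT] != 0.0:
        src = p[K.P_GLU_SCALE] * s[K.S_Y]
        d[K.S_GLU_SYN] += src
        d[K.S_LED_GLU] = src * p[K.P_MOL_SYN]
    return d


def step(state: FullState, config: ModelConfig, dt: float | None = None,
         leaks: dict[str, float] | None = None, i_app: float = 0.0,
         threshold: float = 0.0, refractory: float = 2e-3) -> FullState:
    """One explicit-Euler update (pure Python reference).

    ``i_app`` is the applied current density at this step (A/m^2, canonical).
    Spike events (upward ``threshold`` crossing of V_pre, volts) trigger the
    resource jump and transmitter release at the end of the step.  Raises
    :class:`SimulationError` on non-finite states or non-positive
    concentrations.
    """
    cfg = normalize_units(config)
    if dt is None:
        dt = cfg.dt
    if leaks is None:
        raise ValueError("step requires the calibrated leak map (prepare(config).leaks)")
    p = _cached_params(cfg, tuple(sorted(leaks.items())))
    s = state.to_vector()
    d = _python_derivatives(s, p, i_app)
    s_new = s + dt * d
    t_new = state.t + dt
    last_pre, last_post = state.last_spike_pre, state.last_spike_post
    if (s[K.S_V_PRE] < threshold and s_new[K.S_V_PRE] >= threshold
            and t_new - last_pre >= refractory):
        last_pre = t_new
        x, y, z, released = apply_spike(
            s_new[K.S_X], s_new[K.S_Y], s_new[K.S_Z], cfg.release.u)
        s_new[K.S_X], s_new[K.S_Y], s_new[K.S_Z] = x, y, z
        dglu, dk = release_into_synapse(released, cfg.release.glu_scale,
                                        cfg.release.k_release)
        if cfg.release_mode == "continuous":
            dglu = 0.0
        s_new[K.S_GLU_SYN] += dglu
        s_new[K.S_K_SYN] += dk
        mol_syn = cfg.geometry.vol_syn / 1e3
        s_new[K.S_LED_GLU] += dglu * mol_syn
        s_new[K.S_LED_K] += dk * mol_syn
    if (s[K.S_V_POST] < threshold and s_new[K.S_V_POST] >= threshold
            and t_new - last_post >= refractory):
        last_post = t_new
    if not np.all(np.isfinite(s_new)):
        raise SimulationError(f"non-finite state at t = {t_new:.6f} s")
    for slot, name in _SLOT_NAMES.items():
        if s_new[slot] <= 0:
            raise SimulationError(
                f"concentration {name} became non-positive at t = {t_new:.6f} s")
    return FullState.from_vector(s_new, t=t_new, last_spike_pre=last_pre,
                                 last_spike_post=last_post)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Simulation output: decimated traces, spike times and metadata.

    Trace units: potentials and reversal potentials in mV, concentrations in
    mM, current densities in A/m^2; the time grid in seconds.  The metadata
    (config dict, hash, protocol, dt, calibrated leaks) suffices to re-run
    the simulation bit-identically.
    """

    time: np.ndarray
    traces: dict[str, np.ndarray]
    spikes_pre: np.ndarray
    spikes_post: np.ndarray
    config: dict
    config_hash: str
    protocol: dict
    dt: float
    leaks: dict[str, float]
    final_state: np.ndarray
    schema_version: int = SCHEMA_VERSION
    status: str = "ok"           # "ok" | "nonfinite" | "nonpositive"
    fail_time: float = -1.0      # time of integration failure (s; -1 if none)
    fail_detail: str = ""        # diagnostic (offending species/slot)

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.time}
        data.update(self.traces)
        return pd.DataFrame(data)

    def equals(self, other: "SimResult") -> bool:
        if set(self.traces) != set(other.traces):
            return False
        return (
            np.array_equal(self.time, other.time)
            and all(np.array_equal(self.traces[k], other.traces[k])
                    for k in self.traces)
            and np.array_equal(self.spikes_pre, other.spikes_pre)
            and np.array_equal(self.spikes_post, other.spikes_post)
            and self.config == other.config
            and self.config_hash == other.config_hash
            and self.protocol == other.protocol
            and self.dt == other.dt
            and self.leaks == other.leaks
            and np.array_equal(self.final_state, other.final_state)
            and self.status == other.status
            and self.fail_time == other.fail_time
            and self.fail_detail == other.fail_detail
        )

    def save(self, path) -> None:
        write_result(self, path)

    @classmethod
    def load(cls, path) -> "SimResult":
        return read_result(path)

    def export_csv(self, path) -> None:
        """Tabular text export: one row per output time, labelled columns."""
        self.to_dataframe().to_csv(path, index=False)


_MV_TRACES = ("v_pre", "v_post", "e_eaat", "e_gat")


def run(config: ModelConfig, protocol=None, engine: str = "numba",
        on_error: str = "raise") -> SimResult:
    """Simulate the configured tripartite synapse under a stimulus protocol.

    The equilibrium calibration (basal GABA, ambient Glu, leak conductances)
    runs before t = 0.  ``protocol=None`` uses the default pulsed protocol
    with the configured total duration.  ``engine="python"`` uses the pure
    reference integrator (slow; for cross-checks only).

    ``on_error="raise"`` (default) raises :class:`SimulationError` when the
    integration produces a non-finite state or a non-positive concentration;
    ``on_error="partial"`` instead returns the truncated result with
    ``status``, ``fail_time`` and ``fail_detail`` set - the diagnostic dump
    for a run that left the physical domain.
    """
    from .protocols import Protocol

    prep = prepare(config)
    cfg = prep.config
    if protocol is None:
        protocol = Protocol(total_duration=cfg.duration)
    p = _pack_params(prep, protocol)
    state0 = initial_state(cfg, prep)
    dt = cfg.dt
    n_steps = int(round(protocol.total_duration / dt))
    stride = max(1, int(round(cfg.record_dt / dt)))
    n_rows = n_steps // stride + 1 + (1 if n_steps % stride else 0)
    spike_cap = int(protocol.total_duration / max(protocol.refractory, 1e-4)) + 16

    if engine == "numba":
        (traces, spikes_pre, spikes_post, status, fail_time, fail_slot,
         final) = K.integrate(state0.to_vector(), p, dt, n_steps, stride,
                              n_rows, spike_cap)
    elif engine == "python":
        traces, spikes_pre, spikes_post, status, fail_time, fail_slot, final = (
            _python_integrate(state0, cfg, prep.leaks, p, protocol, dt,
                              n_steps, stride, n_rows))
    else:
        raise ValueError("engine must be 'numba' or 'python'")

    status_name = "ok"
    fail_detail = ""
    if status == K.STATUS_NONFINITE:
        status_name = "nonfinite"
        fail_detail = f"non-finite state in slot {fail_slot}"
    elif status == K.STATUS_NONPOSITIVE:
        status_name = "nonpositive"
        name = _SLOT_NAMES.get(fail_slot, str(fail_slot))
        fail_detail = f"concentration {name} became non-positive"
    if status_name != "ok" and on_error == "raise":
        raise SimulationError(f"{fail_detail} at t = {fail_time:.6f} s")

    trace_map = {}
    for j, name in enumerate(K.TRACE_COLUMNS):
        if name == "t":
            continue
        col = traces[:, j].copy()
        if name in _MV_TRACES:
            col *= 1e3
        trace_map[name] = col
    return SimResult(
        time=traces[:, 0].copy(),
        traces=trace_map,
        spikes_pre=np.asarray(spikes_pre),
        spikes_post=np.asarray(spikes_post),
        config=config_to_dict(cfg),
        config_hash=config_hash(cfg),
        protocol=protocol.to_dict(),
        dt=dt,
        leaks=dict(prep.leaks),
        final_state=np.asarray(final),
        status=status_name,
        fail_time=float(fail_time),
        fail_detail=fail_detail,
    )


def _python_integrate(state0, cfg, leaks, p, protocol, dt, n_steps, stride, n_rows):
    """Reference integrator built on :func:`step` (used for cross-checks)."""
    from .kernel import pulsed_current_kernel

    state = state0
    rows = []
    spikes_pre = []
    spikes_post = []
    status = K.STATUS_OK
    fail_time, fail_slot = -1.0, -1
    shim = _PackShim(cfg, leaks)
    for i in range(n_steps + 1):
        if i % stride == 0 or i == n_steps:
            s = state.to_vector()
            i_app = pulsed_current_kernel(i * dt, p[K.P_AMP], p[K.P_RATE],
                                          p[K.P_WIDTH], p[K.P_WSTART], p[K.P_WDUR])
            rows.append(_trace_row(i * dt, s, shim.p, i_app))
        if i == n_steps:
            break
        i_app = pulsed_current_kernel(i * dt, p[K.P_AMP], p[K.P_RATE],
                                      p[K.P_WIDTH], p[K.P_WSTART], p[K.P_WDUR])
        prev_pre, prev_post = state.last_spike_pre, state.last_spike_post
        state.t = i * dt  # keep event times on the exact kernel grid
        state = step(state, cfg, dt, leaks, i_app,
                     threshold=p[K.P_THRESH], refractory=p[K.P_REFRACT])
        if state.last_spike_pre != prev_pre:
            spikes_pre.append(state.last_spike_pre)
        if state.last_spike_post != prev_post:
            spikes_post.append(state.last_spike_post)
    traces = np.array(rows) if rows else np.empty((0, K.NCOLS))
    return (traces, np.array(spikes_pre), np.array(spikes_post), status,
            fail_time, fail_slot, state.to_vector())


def _trace_row(t, s, p, i_app):
    """Evaluate the recorded quantities at a state (mirrors the kernel rows)."""
    from .astro import (_eaat_current, _species_currents, eaat_reversal,
                        gat_current, gat_reversal, kir_current, leak_current,
                        nernst, nka_current, ncx_current, nkcc_current)

    vt = p[K.P_VT]
    row = np.zeros(K.NCOLS)
    row[0] = t
    row[1] = s[K.S_V_PRE]
    row[2] = s[K.S_V_POST]
    row[3:13] = s[[K.S_NA_SYN, K.S_K_SYN, K.S_GLU_SYN, K.S_CA_SYN, K.S_GABA_SYN,
                   K.S_NA_AST, K.S_K_AST, K.S_GLU_AST, K.S_CA_AST, K.S_GABA_AST]]
    row[13:16] = s[[K.S_X, K.S_Y, K.S_Z]]
    e_eaat = eaat_reversal(s[K.S_NA_SYN], s[K.S_NA_AST], p[K.P_HRATIO],
                           s[K.S_GLU_SYN], s[K.S_GLU_AST],
                           s[K.S_K_SYN], s[K.S_K_AST], vt)
    e_gat = gat_reversal(s[K.S_NA_SYN], s[K.S_NA_AST], s[K.S_GABA_SYN],
                         s[K.S_GABA_AST], p[K.P_CLRATIO], vt)
    row[16], row[17] = e_eaat, e_gat
    i_eaat = _eaat_current(p[K.P_VA], e_eaat, p[K.P_AEAAT], p[K.P_BEAAT])
    i_gat = gat_current(p[K.P_VA], e_gat, p[K.P_GGAT])
    i_nka = nka_current(s[K.S_NA_AST], s[K.S_K_SYN], p[K.P_INKA],
                        p[K.P_KNAI], p[K.P_KKE])
    i_ncx = ncx_current(s[K.S_NA_AST], s[K.S_NA_SYN], s[K.S_CA_AST],
                        s[K.S_CA_SYN], p[K.P_VA], p[K.P_INCX], p[K.P_GAMMA], vt)
    e_k_ast = nernst(s[K.S_K_SYN], s[K.S_K_AST], p[K.P_ZK], vt)
    i_kir = kir_current(s[K.S_K_SYN], p[K.P_VA], e_k_ast, p[K.P_GKIR],
                        p[K.P_EKIR_OFF])
    i_nkcc = 0.0
    if p[K.P_NKCC_ON] != 0.0:
        i_nkcc = nkcc_current(s[K.S_NA_SYN], s[K.S_NA_AST], s[K.S_K_SYN],
                              s[K.S_K_AST], p[K.P_CLRATIO], p[K.P_INKCC])
    i_na_leak = leak_current(p[K.P_GLNA], p[K.P_VA],
                             nernst(s[K.S_NA_SYN], s[K.S_NA_AST], p[K.P_ZNA], vt))
    i_k_leak = leak_current(p[K.P_GLK], p[K.P_VA], e_k_ast)
    i_glu_leak = leak_current(p[K.P_GLGLU], p[K.P_VA],
                              nernst(s[K.S_GLU_SYN], s[K.S_GLU_AST], p[K.P_ZGLU], vt))
    i_ca_leak = leak_current(p[K.P_GLCA], p[K.P_VA],
                             nernst(s[K.S_CA_SYN], s[K.S_CA_AST], p[K.P_ZCA], vt))
    comp = _species_currents(i_eaat, i_gat, i_nka, i_ncx, i_kir, i_nkcc,
                             i_na_leak, i_k_leak, i_glu_leak, i_ca_leak,
                             p[K.P_SNKAK], p[K.P_NKCC_ON] != 0.0)
    row[18:24] = [i_eaat, i_gat, i_nka, i_ncx, i_kir, i_nkcc]
    row[24:28] = [i_na_leak, i_k_leak, i_glu_leak, i_ca_leak]
    row[28:33] = comp
    row[33] = i_app
    return row


# ---------------------------------------------------------------------------
# result I/O (HDF5 container)
# ---------------------------------------------------------------------------

def write_result(result: SimResult, path) -> None:
    """Lossless HDF5 round-trip of traces, spikes and metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = result.schema_version
        f.attrs["config_json"] = json.dumps(result.config, sort_keys=True)
        f.attrs["config_hash"] = result.config_hash
        f.attrs["protocol_json"] = json.dumps(result.protocol, sort_keys=True)
        f.attrs["leaks_json"] = json.dumps(result.leaks, sort_keys=True)
        f.attrs["dt"] = result.dt
        f.attrs["status"] = result.status
        f.attrs["fail_time"] = result.fail_time
        f.attrs["fail_detail"] = result.fail_detail
        f.create_dataset("time", data=result.time)
        grp = f.create_group("traces")
        for name, arr in result.traces.items():
            grp.create_dataset(name, data=arr)
        f.create_dataset("spikes_pre", data=result.spikes_pre)
        f.create_dataset("spikes_post", data=result.spikes_post)
        f.create_dataset("final_state", data=result.final_state)


def read_result(path) -> SimResult:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SimulationError(
                f"result schema version {version} != supported {SCHEMA_VERSION}")
        return SimResult(
            time=f["time"][:],
            traces={name: f["traces"][name][:] for name in f["traces"]},
            spikes_pre=f["spikes_pre"][:],
            spikes_post=f["spikes_post"][:],
            config=json.loads(f.attrs["config_json"]),
            config_hash=str(f.attrs["config_hash"]),
            protocol=json.loads(f.attrs["protocol_json"]),
            leaks=json.loads(f.attrs["leaks_json"]),
            dt=float(f.attrs["dt"]),
            final_state=f["final_state"][:],
            schema_version=version,
            status=str(f.attrs["status"]),
            fail_time=float(f.attrs["fail_time"]),
            fail_detail=str(f.attrs["fail_detail"]),
        )
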