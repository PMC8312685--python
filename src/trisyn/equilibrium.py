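"""Equilibrium initialisation: leak calibration and basal-concentration solves.

The model is started from a constructed equilibrium:

1. basal synaptic GABA is the closed-form value that puts the GAT-3 reversal
   potential exactly at the astrocytic membrane potential (no net GABA flux
   at rest);
2. the ambient synaptic Glu is calibrated so the unstimulated postsynaptic
   neuron - including its tonic NMDA/AMPA/GABA_A currents - rests at the
   target potential (-71 mV by default);
3. per-species astrocytic leak conductances are chosen so every composed
   species current vanishes at the initial state (the calibration is an
   algebraic balance; conductances may come out negative);
4. both neurons start at the resting potential of their own current set,
   with gates at steady state and receptors at their binding fixed points.

With these four steps every state derivative is zero at t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from . import astro, neuron
from .astro import CompartmentConcentrations
from .neuron import NeuronState
from .params import ModelConfig, normalize_units
from .release import ResourceState

__all__ = [
    "CalibrationError",
    "solve_basal_gaba_syn",
    "calibrate_tonic_glu",
    "calibrate_leaks",
    "resting_state",
    "prepare",
    "PreparedModel",
    "evaluate_astro_currents",
]

#: denominator tolerance for the leak calibration (V)
_LEAK_DENOM_TOL = 1e-9

SPECIES = ("na", "k", "glu", "ca")


class CalibrationError(RuntimeError):
    """Equilibrium calibration could not be completed."""


def solve_basal_gaba_syn(config: ModelConfig) -> float:
    """Basal synaptic GABA (mM) such that E_GAT(t=0) = V_a exactly.

    Inverts E_GAT = (RT/F) ln((Na_s/Na_a)^2 (GABA_s/GABA_a) (Cl_s/Cl_a)).
    """
    cfg = normalize_units(config)
    init = cfg.init
    vt = cfg.thermal_voltage
    gaba_syn = (cfg.init.gaba_ast * math.exp(cfg.v_ast / vt)
                / ((init.na_syn / init.na_ast) ** 2 * init.cl_ratio))
    if not gaba_syn > 0:
        raise CalibrationError("basal GABA_syn solution is non-positive")
    return gaba_syn


def _receptor_fixed_point(agonist: float, alpha: float, beta: float) -> float:
    ac = alpha * agonist
    return ac / (ac + beta)


def _rest_current(v: float, cfg: ModelConfig, glu_syn: float, gaba_syn: float,
                  include: tuple[bool, bool, bool]) -> float:
    """Total outward membrane current at potential ``v`` with receptors at
    their fixed points; ``include`` flags (nmda, ampa, gabaa)."""
    p = cfg.neuron
    vt = cfg.thermal_voltage
    e_na = vt * math.log(cfg.init.na_syn / p.na_internal)
    e_k = vt * math.log(cfg.init.k_syn / p.k_internal)
    i_na, i_k, i_leak = neuron.voltage_gated_currents(
        v, neuron.h_inf(v * 1e3), neuron.n_inf(v * 1e3),
        p.g_na, p.g_k, p.g_leak, e_na, e_k, p.e_leak)
    total = i_na + i_k + i_leak
    use_nmda, use_ampa, use_gabaa = include
    if use_nmda:
        r = _receptor_fixed_point(glu_syn, p.alpha_nmda, p.beta_nmda)
        total += p.g_nmda * r * (v - p.e_nmda) * neuron.mg_block(v, p.mg)
    if use_ampa:
        r = _receptor_fixed_point(glu_syn, p.alpha_ampa, p.beta_ampa)
        total += p.g_ampa * r * (v - p.e_ampa)
    if use_gabaa:
        r = _receptor_fixed_point(gaba_syn, p.alpha_gabaa, p.beta_gabaa)
        total += p.g_gabaa * r * (v - p.e_gabaa)
    return total


def _solve_rest(cfg: ModelConfig, glu_syn: float, gaba_syn: float,
                include: tuple[bool, bool, bool]) -> float:
    """Lowest zero of the steady-state current balance (the resting branch)."""
    f = lambda v: _rest_current(v, cfg, glu_syn, gaba_syn, include)
    v_lo = -0.120
    f_lo = f(v_lo)
    if f_lo >= 0:
        raise CalibrationError("no hyperpolarised bracket for the resting potential")
    v = v_lo
    step = 5e-4
    while v < -0.020:
        v_hi = v + step
        if f(v_hi) > 0:
            return brentq(f, v, v_hi, xtol=1e-15, rtol=8.9e-16)
        v = v_hi
    raise CalibrationError("resting potential not found below -20 mV")


def resting_state(config: ModelConfig, which: str, glu_syn: float,
                  gaba_syn: float) -> NeuronState:
    """Equilibrium :class:`NeuronState` for the pre- or postsynaptic neuron.

    The receptor complement follows the GABA_A placement switch: the
    postsynaptic neuron always carries NMDA and AMPA receptors, the
    presynaptic neuron only a GABA_A receptor (when placed).
    """
    cfg = normalize_units(config)
    if which == "post":
        include = (True, True, cfg.gabaa_placement in ("both", "post_only"))
    elif which == "pre":
        include = (False, False, cfg.gabaa_placement == "both")
    else:
        raise ValueError("which must be 'pre' or 'post'")
    v = _solve_rest(cfg, glu_syn, gaba_syn, include)
    p = cfg.neuron
    # binding fixed points are ligand properties: they initialise the open
    # fractions even where the corresponding conductance is absent (the
    # placement switch only controls which currents exist)
    return NeuronState(
        v=v,
        h=neuron.h_inf(v * 1e3),
        n=neuron.n_inf(v * 1e3),
        r_nmda=_receptor_fixed_point(glu_syn, p.alpha_nmda, p.beta_nmda),
        r_ampa=_receptor_fixed_point(glu_syn, p.alpha_ampa, p.beta_ampa),
        r_gabaa=_receptor_fixed_point(gaba_syn, p.alpha_gabaa, p.beta_gabaa),
    )


def calibrate_tonic_glu(config: ModelConfig, gaba_syn: float | None = None) -> float:
    """Ambient synaptic Glu (mM) at which the postsynaptic neuron rests at
    the target potential.

    The intrinsic conductances alone rest the cell a few mV below the target;
    the tonic NMDA/AMPA drive of ambient cleft Glu closes the gap.  The
    calibration always uses the full receptor complement (it is a property of
    the bath, not of a particular placement switch).
    """
    cfg = normalize_units(config)
    if gaba_syn is None:
        gaba_syn = solve_basal_gaba_syn(cfg)
    target = cfg.neuron.v_rest_target
    include = (True, True, True)

    def gap(log_glu: float) -> float:
        return _solve_rest(cfg, math.exp(log_glu), gaba_syn, include) - target

    lo, hi = math.log(1e-7), math.log(1.0)
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            "target resting potential is not reachable by ambient-Glu calibration")
    log_glu = brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return math.exp(log_glu)


def evaluate_astro_currents(config: ModelConfig,
                            syn: CompartmentConcentrations,
                            ast: CompartmentConcentrations,
                            leaks: dict[str, float] | None = None,
                            ) -> astro.AstrocyteCurrents:
    """All astrocytic component and species currents at one state.

    ``leaks`` maps species name to leak conductance (S/m^2); omitted leaks
    are zero.  The GAT-3 current is forced to zero when the transporter is
    disabled.
    """
    cfg = normalize_units(config)
    vt = cfg.thermal_voltage
    a = cfg.astro
    v_a = cfg.v_ast
    e_eaat = astro.eaat_reversal(syn.na, ast.na, cfg.init.h_ratio,
                                 syn.glu, ast.glu, syn.k, ast.k, vt)
    e_gat = astro.gat_reversal(syn.na, ast.na, syn.gaba, ast.gaba,
                               cfg.init.cl_ratio, vt)
    i_eaat = astro._eaat_current(v_a, e_eaat, a.alpha_eaat, a.beta_eaat)
    i_gat = astro.gat_current(v_a, e_gat, a.g_gat) if cfg.gat3_enabled else 0.0
    i_nka = astro.nka_current(ast.na, syn.k, a.i_nka_max, a.k_nai, a.k_ke)
    i_ncx = astro.ncx_current(ast.na, syn.na, ast.ca, syn.ca, v_a,
                              a.i_ncx_max, a.gamma, vt)
    e_k = astro.nernst(syn.k, ast.k, a.z_k, vt)
    i_kir = astro.kir_current(syn.k, v_a, e_k, a.g_kir, a.e_kir_offset)
    i_nkcc = astro.nkcc_current(syn.na, ast.na, syn.k, ast.k,
                                cfg.init.cl_ratio, a.i_nkcc_max)
    leaks = leaks or {}
    leak_i = {}
    for name, z in (("na", a.z_na), ("k", a.z_k), ("glu", a.z_glu), ("ca", a.z_ca)):
        g = leaks.get(name, 0.0)
        e_x = astro.nernst(getattr(syn, name), getattr(ast, name), z, vt)
        leak_i[name] = astro.leak_current(g, v_a, e_x)
    return astro.compose_species_currents(
        i_eaat, i_gat, i_nka, i_ncx, i_kir,
        leak_i["na"], leak_i["k"], leak_i["glu"], leak_i["ca"],
        s_nka_k=cfg.nka_k_sign, i_nkcc=i_nkcc, nkcc_enabled=cfg.nkcc_enabled,
        e_eaat=e_eaat, e_gat=e_gat,
    )


def calibrate_leaks(config: ModelConfig,
                    syn: CompartmentConcentrations | None = None,
                    ast: CompartmentConcentrations | None = None,
                    ) -> dict[str, float]:
    """Leak conductances g_X (S/m^2) balancing each species current at t = 0.

    For each species X the transporter sum I_X,transport at the initial state
    is cancelled by g_X (V_a - E_X): g_X = -I_X,transport / (V_a - E_X).
    Raises :class:`CalibrationError` when a driving force is degenerate.
    """
    cfg = normalize_units(config)
    if syn is None or ast is None:
        syn_d, ast_d = _initial_concentrations(cfg)
        syn = syn or syn_d
        ast = ast or ast_d
    cur = evaluate_astro_currents(cfg, syn, ast, leaks=None)
    transport = {"na": cur.i_na, "k": cur.i_k, "glu": cur.i_glu, "ca": cur.i_ca}
    valence = {"na": cfg.astro.z_na, "k": cfg.astro.z_k,
               "glu": cfg.astro.z_glu, "ca": cfg.astro.z_ca}
    vt = cfg.thermal_voltage
    leaks = {}
    for name in SPECIES:
        if transport[name] == 0.0:
            leaks[name] = 0.0
            continue
        e_x = astro.nernst(getattr(syn, name), getattr(ast, name), valence[name], vt)
        denom = cfg.v_ast - e_x
        if abs(denom) < _LEAK_DENOM_TOL:
            raise CalibrationError(
                f"leak calibration for {name!r} is degenerate: V_a - E_{name} "
                f"= {denom:.3e} V")
        leaks[name] = -transport[name] / denom
    return leaks


def _initial_concentrations(cfg: ModelConfig
                            ) -> tuple[CompartmentConcentrations, CompartmentConcentrations]:
    init = cfg.init
    gaba_syn = init.gaba_syn if init.gaba_syn is not None else solve_basal_gaba_syn(cfg)
    glu_syn = init.glu_syn if init.glu_syn is not None else calibrate_tonic_glu(cfg, gaba_syn)
    syn = CompartmentConcentrations(na=init.na_syn, k=init.k_syn, glu=glu_syn,
                                    ca=init.ca_syn, gaba=gaba_syn)
    ast = CompartmentConcentrations(na=init.na_ast, k=init.k_ast,
                                    glu=cfg.glu_ast_basal, ca=init.ca_ast,
                                    gaba=init.gaba_ast)
    return syn, ast


@dataclass
class PreparedModel:
    """A normalised configuration with its calibrated equilibrium."""

    config: ModelConfig          # canonical units
    syn0: CompartmentConcentrations
    ast0: CompartmentConcentrations
    leaks: dict[str, float]
    pre0: NeuronState
    post0: NeuronState
    resources0: ResourceState


def prepare(config: ModelConfig) -> PreparedModel:
    """Normalise, resolve basal concentrations and calibrate the equilibrium."""
    config.validate()
    cfg = normalize_units(config)
    syn, ast = _initial_concentrations(cfg)
    leaks = calibrate_leaks(cfg, syn, ast)
    pre0 = resting_state(cfg, "pre", syn.glu, syn.gaba)
    post0 = resting_state(cfg, "post", syn.glu, syn.gaba)
    return PreparedModel(config=cfg, syn0=syn, ast0=ast, leaks=leaks,
                         pre0=pre0, post0=post0,
                         resources0=ResourceState(1.0, 0.0, 0.0))
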