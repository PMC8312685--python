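"""Astrocytic membrane transporter and channel current laws.

All currents are densities on the perisynaptic astrocytic membrane (A/m^2),
positive = net positive charge leaving the astrocyte (efflux).  Reversal
potentials come from the transporters' stoichiometries:

* EAAT-2 couples 1 Glu to 3 Na+ in, 1 H+ in, 1 K+ out (net +2 per cycle);
  its current is an inward-rectifying exponential that is always negative
  (influx), with magnitude set by how far V_a sits below E_EAAT.
* GAT-3 couples 1 GABA to 2 Na+ and 1 Cl- (net +1 per cycle) and is ohmic,
  so it reverses the moment its concentration-dependent E_GAT crosses the
  (fixed) astrocytic membrane potential: Na+ loading drives E_GAT below V_a
  and the transporter runs backwards, releasing GABA into the cleft.
* The Na+/K+-ATPase, the reversible Na+/Ca2+ exchanger and the Kir4.1
  channel complete Na+/K+/Ca2+ handling; per-species ohmic leaks (with
  calibrated, possibly negative conductances) pin the initial equilibrium.

Species currents are composed with the cycle stoichiometries::

    I_Na  = 1.5 I_EAAT + 3 I_NKA + 3 I_NCX + 2 I_GAT + I_Na,L
    I_K   = -0.5 I_EAAT + s_K 2 I_NKA + I_Kir + I_K,L      (s_K = -1 default)
    I_Glu = -0.5 I_EAAT + I_Glu,L
    I_Ca  = -2 I_NCX + I_Ca,L
    I_GABA = I_GAT

The printed K+ composition carries +2 I_NKA, which would make the pump
*export* K+; the default sign switch restores the physiological import
(3 Na+ out / 2 K+ in) and the literal sign remains available via
``nka_k_sign=+1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CompartmentConcentrations",
    "AstrocyteCurrents",
    "nernst",
    "eaat_reversal",
    "eaat_current",
    "gat_reversal",
    "gat_current",
    "nka_current",
    "ncx_current",
    "kir_current",
    "nkcc_current",
    "leak_current",
    "compose_species_currents",
    "EAAT_EXP_CLAMP",
]

# exponent guard for the EAAT exponential; beyond this the state is unphysical
EAAT_EXP_CLAMP = 50.0


@dataclass
class CompartmentConcentrations:
    """Ion/transmitter concentrations of one compartment (mM); all > 0.

    H+ and Cl- are not dynamic species: only the fixed ratios H_syn/H_ast and
    Cl_syn/Cl_ast enter the model (inside E_EAAT, E_GAT and the NKCC law),
    and they are carried at the configuration level.
    """

    na: float
    k: float
    glu: float
    ca: float
    gaba: float

    def validate(self) -> None:
        for name in ("na", "k", "glu", "ca", "gaba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name} must be positive")


@dataclass
class AstrocyteCurrents:
    """Instantaneous component currents and composed species currents (A/m^2)."""

    i_eaat: float
    i_gat: float
    i_nka: float
    i_ncx: float
    i_kir: float
    i_nkcc: float
    i_na_leak: float
    i_k_leak: float
    i_glu_leak: float
    i_ca_leak: float
    i_na: float
    i_k: float
    i_glu: float
    i_ca: float
    i_gaba: float
    e_eaat: float
    e_gat: float


@njit(cache=True)
def nernst(out_conc, in_conc, valence, vt):
    """Nernst potential E = (RT/zF) ln(out/in) in volts.

    ``vt`` is the thermal voltage RT/F; concentrations must be positive and
    the valence non-zero.
    """
    if out_conc <= 0.0 or in_conc <= 0.0:
        raise ValueError("nernst: concentrations must be positive")
    if valence == 0:
        raise ValueError("nernst: valence must be non-zero")
    return vt / valence * np.log(out_conc / in_conc)


@njit(cache=True)
def eaat_reversal(na_syn, na_ast, h_ratio, glu_syn, glu_ast, k_syn, k_ast, vt):
    """EAAT-2 reversal potential (V): (RT/2F) ln((Na_s/Na_a)^3 (H_s/H_a)
    (Glu_s/Glu_a) (K_a/K_s)); the divisor 2 is the net charge per cycle."""
    arg = (na_syn / na_ast) ** 3 * h_ratio * (glu_syn / glu_ast) * (k_ast / k_syn)
    if arg <= 0.0:
        raise ValueError("eaat_reversal: non-positive concentration ratio")
    return 0.5 * vt * np.log(arg)


@njit(cache=True)
def _eaat_current(v_a, e_eaat, alpha_eaat, beta_eaat):
    x = -beta_eaat * (v_a - e_eaat)
    if x > EAAT_EXP_CLAMP:
        x = EAAT_EXP_CLAMP
    return -alpha_eaat * np.exp(x)


def eaat_current(v_a, e_eaat, alpha_eaat, beta_eaat):
    """EAAT-2 current (A/m^2): -alpha exp(-beta (V_a - E_EAAT)); always < 0.

    The exponent is clamped at +50 (with a warning) - reaching it indicates
    an unphysical state, not a numerical subtlety.
    """
    if -beta_eaat * (v_a - e_eaat) > EAAT_EXP_CLAMP:
        warnings.warn(
            "eaat_current: exponent clamped at +50; the state is far outside "
            "the physical regime", RuntimeWarning, stacklevel=2)
    return _eaat_current(v_a, e_eaat, alpha_eaat, beta_eaat)


@njit(cache=True)
def gat_reversal(na_syn, na_ast, gaba_syn, gaba_ast, cl_ratio, vt):
    """GAT-3 reversal potential (V): (RT/F) ln((Na_s/Na_a)^2 (GABA_s/GABA_a)
    (Cl_s/Cl_a))."""
    arg = (na_syn / na_ast) ** 2 * (gaba_syn / gaba_ast) * cl_ratio
    if arg <= 0.0:
        raise ValueError("gat_reversal: non-positive concentration ratio")
    return vt * np.log(arg)


@njit(cache=True)
def gat_current(v_a, e_gat, g_gat):
    """Ohmic GAT-3 current (A/m^2); positive (GABA/Na+ efflux) iff V_a > E_GAT."""
    return g_gat * (v_a - e_gat)


@njit(cache=True)
def nka_current(na_ast, k_syn, i_nka_max, k_nai, k_ke):
    """Na+/K+-ATPase pump current (A/m^2), in (0, I_NKAmax); Hill factor 1.5
    in astrocytic Na+ and Michaelis factor in synaptic K+."""
    na15 = na_ast * np.sqrt(na_ast)
    knai15 = k_nai * np.sqrt(k_nai)
    return i_nka_max * (na15 / (na15 + knai15)) * (k_syn / (k_syn + k_ke))


@njit(cache=True)
def ncx_current(na_ast, na_syn, ca_ast, ca_syn, v_a, i_ncx_max, gamma, vt):
    """Reversible Na+/Ca2+ exchanger current (A/m^2)."""
    ef = np.exp(gamma * v_a / vt)
    er = np.exp((gamma - 1.0) * v_a / vt)
    return i_ncx_max * ((na_ast / na_syn) ** 3 * ef - (ca_ast / ca_syn) * er)


@njit(cache=True)
def kir_current(k_syn, v_a, e_k, g_kir, e_kir_offset):
    """Kir4.1 current (A/m^2): g_kir * K_syn * (V_a - E_K), with K_syn entering
    as its numeric value in mM.  ``e_kir_offset`` is an optional additive
    offset on the reversal (0 by default; the printed 0.025 V table entry is
    not used by the printed current law)."""
    return g_kir * k_syn * (v_a - (e_k + e_kir_offset))


@njit(cache=True)
def nkcc_current(na_syn, na_ast, k_syn, k_ast, cl_ratio, i_nkcc_max):
    """NKCC cotransporter current (A/m^2); optional component, excluded from
    the species compositions unless explicitly enabled."""
    arg = (na_syn / na_ast) * (k_syn / k_ast) * cl_ratio ** 2
    if arg <= 0.0:
        raise ValueError("nkcc_current: non-positive concentration ratio")
    return i_nkcc_max * np.log(arg)


@njit(cache=True)
def leak_current(g_leak, v_a, e_x):
    """Per-species ohmic leak I_X,L = g_X (V_a - E_X); g_X may be negative
    (it is an algebraic balance term, not a physical channel fit)."""
    return g_leak * (v_a - e_x)


@njit(cache=True)
def _species_currents(i_eaat, i_gat, i_nka, i_ncx, i_kir, i_nkcc,
                      i_na_leak, i_k_leak, i_glu_leak, i_ca_leak,
                      s_nka_k, nkcc_on):
    i_na = 1.5 * i_eaat + 3.0 * i_nka + 3.0 * i_ncx + 2.0 * i_gat + i_na_leak
    i_k = -0.5 * i_eaat + s_nka_k * 2.0 * i_nka + i_kir + i_k_leak
    i_glu = -0.5 * i_eaat + i_glu_leak
    i_ca = -2.0 * i_ncx + i_ca_leak
    i_gaba = i_gat
    if nkcc_on:
        i_na = i_na + i_nkcc
        i_k = i_k + i_nkcc
    return i_na, i_k, i_glu, i_ca, i_gaba


def compose_species_currents(i_eaat, i_gat, i_nka, i_ncx, i_kir,
                             i_na_leak=0.0, i_k_leak=0.0, i_glu_leak=0.0,
                             i_ca_leak=0.0, *, s_nka_k=-1.0, i_nkcc=0.0,
                             nkcc_enabled=False, e_eaat=np.nan, e_gat=np.nan,
                             ) -> AstrocyteCurrents:
    """Compose per-species astrocytic currents from the component currents.

    Returns an :class:`AstrocyteCurrents` record; see the module docstring
    for the stoichiometric map and the NKA sign switch.
    """
    i_na, i_k, i_glu, i_ca, i_gaba = _species_currents(
        i_eaat, i_gat, i_nka, i_ncx, i_kir, i_nkcc,
        i_na_leak, i_k_leak, i_glu_leak, i_ca_leak,
        s_nka_k, nkcc_enabled,
    )
    return AstrocyteCurrents(
        i_eaat=i_eaat, i_gat=i_gat, i_nka=i_nka, i_ncx=i_ncx, i_kir=i_kir,
        i_nkcc=i_nkcc, i_na_leak=i_na_leak, i_k_leak=i_k_leak,
        i_glu_leak=i_glu_leak, i_ca_leak=i_ca_leak,
        i_na=i_na, i_k=i_k, i_glu=i_glu, i_ca=i_ca, i_gaba=i_gaba,
        e_eaat=e_eaat, e_gat=e_gat,
    )
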