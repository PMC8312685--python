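"""Astrocytic transporter laws, reversal potentials and species composition."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import trisyn
from trisyn.astro import (compose_species_currents, eaat_current, eaat_reversal,
                          gat_current, gat_reversal, kir_current, leak_current,
                          nernst, nka_current, ncx_current, nkcc_current)
from trisyn.simulator import current_to_flux

from conftest import VT

conc = st.floats(min_value=1e-5, max_value=500.0)
ratio = st.floats(min_value=1e-3, max_value=1e3)


# --- Nernst -----------------------------------------------------------------

def test_nernst_values():
    assert nernst(7.7, 7.7, 1, VT) == 0.0
    assert nernst(4.0, 130.0, 1, VT) * 1e3 == pytest.approx(
        VT * 1e3 * math.log(4.0 / 130.0), rel=1e-12)
    assert nernst(4.0, 130.0, 1, VT) * 1e3 == pytest.approx(-93.00, abs=0.01)
    assert nernst(2.0, 1e-4, 2, VT) * 1e3 == pytest.approx(132.29, abs=0.01)


def test_nernst_errors():
    with pytest.raises(ValueError):
        nernst(-1.0, 4.0, 1, VT)
    with pytest.raises(ValueError):
        nernst(4.0, 0.0, 1, VT)
    with pytest.raises(ValueError):
        nernst(4.0, 4.0, 0, VT)


# --- EAAT-2 -----------------------------------------------------------------

def test_eaat_reversal_unit_ratios_zero():
    assert eaat_reversal(15.0, 15.0, 1.0, 2.0, 2.0, 9.0, 9.0, VT) == 0.0


def test_eaat_reversal_default_state():
    # (vt/2)(3 ln(140/15) + ln(1e-4/1.5) + ln(130/4)) ~ +7.56 mV
    e = eaat_reversal(140.0, 15.0, 1.0, 1e-4, 1.5, 4.0, 130.0, VT)
    expected = 0.5 * VT * (3 * math.log(140 / 15) + math.log(1e-4 / 1.5)
                           + math.log(130 / 4))
    assert e == pytest.approx(expected, rel=1e-12)
    assert e * 1e3 == pytest.approx(7.56, abs=0.01)


def test_eaat_reversal_falls_with_astrocytic_glu():
    es = [eaat_reversal(140.0, 15.0, 1.0, 1e-4, g, 4.0, 130.0, VT)
          for g in (1.5, 5.0, 10.0)]
    assert es[0] > es[1] > es[2]


def test_eaat_current_scale_and_limit():
    assert eaat_current(-0.080, -0.080, 2e-4, 29.2) == pytest.approx(-2e-4, rel=1e-12)
    i = eaat_current(-0.080, 0.0076, 2e-4, 29.2)
    assert i == pytest.approx(-2e-4 * math.exp(29.2 * 0.0876), rel=1e-12)
    assert i == pytest.approx(-2.58e-3, abs=2e-5)
    # far above reversal the inward-rectifying exponential vanishes from below
    tail = eaat_current(0.5, -0.080, 2e-4, 29.2)
    assert -1e-10 < tail < 0.0


def test_eaat_current_clamp_warns():
    with pytest.warns(RuntimeWarning):
        i = eaat_current(-0.080, 2.0, 2e-4, 29.2)
    assert i == pytest.approx(-2e-4 * math.exp(50.0), rel=1e-12)


@given(dv1=st.floats(-0.15, 0.15), dv2=st.floats(-0.15, 0.15))
def test_eaat_current_negative_and_monotone(dv1, dv2):
    lo, hi = sorted((dv1, dv2))
    i_lo = eaat_current(-0.080 + lo, -0.080, 2e-4, 29.2)
    i_hi = eaat_current(-0.080 + hi, -0.080, 2e-4, 29.2)
    assert i_lo < 0.0 and i_hi < 0.0
    assert i_hi >= i_lo  # magnitude shrinks as V_a rises above E_EAAT


# --- GAT-3 ------------------------------------------------------------------

def test_gat_reversal_values():
    assert gat_reversal(15.0, 15.0, 2.0, 2.0, 1.0, VT) == 0.0
    e = gat_reversal(140.0, 15.0, 1e-3, 2.0, 130.0 / 40.0, VT)
    assert e * 1e3 == pytest.approx(-52.23, abs=0.01)
    # raising astrocytic Na+ from 15 to 20 mM lowers E_GAT by 2 vt ln(20/15)
    e2 = gat_reversal(140.0, 20.0, 1e-3, 2.0, 130.0 / 40.0, VT)
    assert (e - e2) == pytest.approx(2 * VT * math.log(20.0 / 15.0), rel=1e-10)
    assert (e - e2) * 1e3 == pytest.approx(15.37, abs=0.01)


def test_gat_current_ohmic():
    assert gat_current(-0.080, -0.080, 210.0) == 0.0
    assert gat_current(-0.080, -0.085, 210.0) == pytest.approx(1.05, rel=1e-12)
    assert gat_current(-0.080, -0.075, 210.0) == pytest.approx(-1.05, rel=1e-12)


# --- NKA, NCX, Kir, NKCC ----------------------------------------------------

def test_nka_half_saturations_and_value():
    assert nka_current(1.5, 4.0, 0.1081, 1.5, 10.0) == pytest.approx(
        0.1081 * 0.5 * (4.0 / 14.0), rel=1e-12)
    assert nka_current(15.0, 10.0, 0.1081, 1.5, 10.0) == pytest.approx(
        0.1081 * (15.0 ** 1.5 / (15.0 ** 1.5 + 1.5 ** 1.5)) * 0.5, rel=1e-12)
    assert nka_current(15.0, 4.0, 0.1081, 1.5, 10.0) == pytest.approx(0.02994, abs=2e-5)


@given(na1=conc, na2=conc, k=conc)
def test_nka_monotone_bounded(na1, na2, k):
    lo, hi = sorted((na1, na2))
    i_lo = nka_current(lo, k, 0.1081, 1.5, 10.0)
    i_hi = nka_current(hi, k, 0.1081, 1.5, 10.0)
    assert 0.0 < i_lo < 0.1081 and 0.0 < i_hi < 0.1081
    assert i_hi >= i_lo


def test_ncx_equilibrium_and_resting_value():
    assert ncx_current(15.0, 15.0, 2.0, 2.0, 0.0, 0.01, 0.5, VT) == pytest.approx(0.0, abs=1e-18)
    # direct arithmetic oracle at the default resting state
    expected = 0.01 * ((15.0 / 140.0) ** 3 * math.exp(0.5 * -0.080 / VT)
                       - (1e-4 / 2.0) * math.exp(-0.5 * -0.080 / VT))
    got = ncx_current(15.0, 140.0, 1e-4, 2.0, -0.080, 0.01, 0.5, VT)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(5.17e-7, rel=2e-3)


def test_ncx_monotone_in_na_ast():
    base = ncx_current(15.0, 140.0, 1e-4, 2.0, -0.080, 0.01, 0.5, VT)
    up = ncx_current(16.0, 140.0, 1e-4, 2.0, -0.080, 0.01, 0.5, VT)
    assert up > base


def test_kir_law():
    e_k = nernst(4.0, 130.0, 1, VT)
    assert kir_current(4.0, e_k, e_k, 1440.0, 0.0) == 0.0
    i1 = kir_current(4.0, e_k + 0.013, e_k, 1440.0, 0.0)
    i2 = kir_current(8.0, e_k + 0.013, e_k, 1440.0, 0.0)
    assert i2 == pytest.approx(2.0 * i1, rel=1e-12)
    assert kir_current(4.0, -0.080, -0.093, 1440.0, 0.0) == pytest.approx(74.88, rel=1e-10)


def test_nkcc_law():
    assert nkcc_current(15.0, 15.0, 4.0, 4.0, 1.0, 0.02) == 0.0
    expected = 0.02 * math.log((140 / 15) * (4 / 130) * 3.25 ** 2)
    assert nkcc_current(140.0, 15.0, 4.0, 130.0, 3.25, 0.02) == pytest.approx(
        expected, rel=1e-12)


# --- composition ------------------------------------------------------------

def test_compose_zero_components():
    cur = compose_species_currents(0.0, 0.0, 0.0, 0.0, 0.0)
    assert (cur.i_na, cur.i_k, cur.i_glu, cur.i_ca, cur.i_gaba) == (0, 0, 0, 0, 0)


def test_compose_eaat_stoichiometry():
    cur = compose_species_currents(-2e-3, 0.0, 0.0, 0.0, 0.0)
    assert cur.i_na == pytest.approx(-3e-3)
    assert cur.i_k == pytest.approx(1e-3)
    assert cur.i_glu == pytest.approx(1e-3)
    assert cur.i_ca == 0.0 and cur.i_gaba == 0.0


def test_compose_gat_stoichiometry():
    cur = compose_species_currents(0.0, 1.0, 0.0, 0.0, 0.0)
    assert cur.i_na == pytest.approx(2.0)
    assert cur.i_gaba == pytest.approx(1.0)


def test_nka_potassium_sign_switch():
    imp = compose_species_currents(0.0, 0.0, 0.1, 0.0, 0.0, s_nka_k=-1.0)
    exp = compose_species_currents(0.0, 0.0, 0.1, 0.0, 0.0, s_nka_k=+1.0)
    assert imp.i_k == pytest.approx(-0.2)   # default: pump imports K+
    assert exp.i_k == pytest.approx(+0.2)   # literal printed sign: exports
    assert imp.i_na == exp.i_na == pytest.approx(0.3)


def test_glutamate_uptake_sign_chain():
    """EAAT-2 uptake (I_EAAT < 0) with z_Glu = -1 must *raise* astrocytic Glu
    and lower synaptic Glu - the double sign flip is the chief bug risk."""
    cur = compose_species_currents(-2e-3, 0.0, 0.0, 0.0, 0.0)
    d_ast = current_to_flux(cur.i_glu, -1, 1.4137e-13, 1.885e-17, compartment="ast")
    d_syn = current_to_flux(cur.i_glu, -1, 1.4137e-13, 8.5883e-16, compartment="syn")
    assert d_ast > 0.0 and d_syn < 0.0


def test_reversed_gat_releases_gaba():
    """A Na+-loaded astrocyte (E_GAT below V_a) produces a positive GAT-3
    current: Na+/GABA efflux into the cleft."""
    e = gat_reversal(140.0, 40.0, 3.5e-4, 2.0, 3.25, VT)
    assert e < -0.080
    i_gat = gat_current(-0.080, e, 210.0)
    cur = compose_species_currents(0.0, i_gat, 0.0, 0.0, 0.0)
    d_gaba_syn = current_to_flux(cur.i_gaba, 1, 1.4137e-13, 8.5883e-16,
                                 compartment="syn")
    assert i_gat > 0.0 and d_gaba_syn > 0.0


# --- properties and the randomized oracle grid ------------------------------

@given(f=st.floats(min_value=0.1, max_value=10.0))
def test_reversals_linear_in_log_ratio(f):
    base = gat_reversal(140.0, 15.0, 1e-3, 2.0, 3.25, VT)
    shifted = gat_reversal(140.0 * f, 15.0, 1e-3, 2.0, 3.25, VT)
    assert shifted - base == pytest.approx(2 * VT * math.log(f), abs=1e-12)
    base_e = eaat_reversal(140.0, 15.0, 1.0, 1e-4, 1.5, 4.0, 130.0, VT)
    shifted_e = eaat_reversal(140.0 * f, 15.0, 1.0, 1e-4, 1.5, 4.0, 130.0, VT)
    assert shifted_e - base_e == pytest.approx(1.5 * VT * math.log(f), abs=1e-12)


def test_current_laws_match_independent_oracle_grid():
    """Every current law agrees with independently coded direct evaluation
    to 1e-10 relative error over a 1000-point randomized grid."""
    rng = np.random.default_rng(20210712)
    for _ in range(1000):
        na_s, na_a, k_s, k_a = rng.uniform(0.5, 300.0, 4)
        glu_s, glu_a, gaba_s, gaba_a = rng.uniform(1e-5, 20.0, 4)
        ca_s, ca_a = rng.uniform(1e-5, 5.0, 2)
        h_r, cl_r = rng.uniform(0.2, 5.0, 2)
        v_a = rng.uniform(-0.12, 0.02)
        # reversal potentials
        assert eaat_reversal(na_s, na_a, h_r, glu_s, glu_a, k_s, k_a, VT) == pytest.approx(
            VT / 2 * math.log((na_s / na_a) ** 3 * h_r * (glu_s / glu_a) * (k_a / k_s)),
            rel=1e-10)
        e_gat = VT * math.log((na_s / na_a) ** 2 * (gaba_s / gaba_a) * cl_r)
        assert gat_reversal(na_s, na_a, gaba_s, gaba_a, cl_r, VT) == pytest.approx(
            e_gat, rel=1e-10, abs=1e-14)
        # currents
        e_ref = rng.uniform(-0.1, 0.1)
        if -29.2 * (v_a - e_ref) <= 50.0:
            assert eaat_current(v_a, e_ref, 2e-4, 29.2) == pytest.approx(
                -2e-4 * math.exp(-29.2 * (v_a - e_ref)), rel=1e-10)
        assert gat_current(v_a, e_gat, 210.0) == pytest.approx(
            210.0 * (v_a - e_gat), rel=1e-10, abs=1e-14)
        assert nka_current(na_a, k_s, 0.1081, 1.5, 10.0) == pytest.approx(
            0.1081 * (na_a ** 1.5 / (na_a ** 1.5 + 1.5 ** 1.5)) * (k_s / (k_s + 10.0)),
            rel=1e-10)
        assert ncx_current(na_a, na_s, ca_a, ca_s, v_a, 0.01, 0.5, VT) == pytest.approx(
            0.01 * ((na_a / na_s) ** 3 * math.exp(0.5 * v_a / VT)
                    - (ca_a / ca_s) * math.exp(-0.5 * v_a / VT)),
            rel=1e-10, abs=1e-16)
        e_k = VT * math.log(k_s / k_a)
        assert kir_current(k_s, v_a, e_k, 1440.0, 0.0) == pytest.approx(
            1440.0 * k_s * (v_a - e_k), rel=1e-10, abs=1e-14)
        assert leak_current(0.3, v_a, e_k) == pytest.approx(
            0.3 * (v_a - e_k), rel=1e-10, abs=1e-16)
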