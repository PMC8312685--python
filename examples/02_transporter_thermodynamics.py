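"""Reversal potentials of the two coupled astrocytic transporters.

Evaluates E_EAAT and E_GAT across astrocytic Na+ loads and basal astrocytic
Glu levels.  EAAT-2 sits far above the astrocytic membrane potential (so it
always takes Glu up), while GAT-3 starts at the membrane potential and
reverses as soon as Na+ accumulates.
"""

import trisyn

vt = trisyn.Constants().thermal_voltage
V_A = -0.080  # astrocytic membrane potential (V)

print("E_EAAT vs basal astrocytic Glu (Na 140/15, K 4/130, Glu_syn 1 uM):")
for glu_ast in (1.5, 5.0, 10.0):
    e = trisyn.eaat_reversal(140.0, 15.0, 1.0, 1e-3, glu_ast, 4.0, 130.0, vt)
    print(f"  Glu_ast = {glu_ast:4.1f} mM  ->  E_EAAT = {e*1e3:+7.2f} mV"
          f"   (driving force {(e - V_A)*1e3:+.1f} mV: uptake)")

print()
print("E_GAT vs astrocytic Na+ (GABA 3.54e-4/2 mM, Cl 130/40):")
gaba_syn = trisyn.solve_basal_gaba_syn(trisyn.default_config())
for na_ast in (15.0, 16.0, 18.0, 20.0, 25.0):
    e = trisyn.gat_reversal(140.0, na_ast, gaba_syn, 2.0, 130.0 / 40.0, vt)
    i = trisyn.gat_current(V_A, e, 210.0)
    mode = "efflux (GABA release)" if i > 0 else "uptake"
    print(f"  Na_ast = {na_ast:4.1f} mM  ->  E_GAT = {e*1e3:+7.2f} mV, "
          f"I_GAT = {i:+8.3f} A/m^2  {mode}")

print()
print("A few mM of astrocytic Na+ loading moves E_GAT tens of mV below the")
print("membrane potential: that thermodynamic shift, driven by EAAT-2's")
print("3 Na+ per Glu stoichiometry, is what reverses GAT-3 and releases")
print("astrocytic GABA into the cleft.")
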