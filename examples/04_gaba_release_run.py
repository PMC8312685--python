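"""EAAT-2 -> GAT-3 coupling under stimulation (scaled protocol).

Simulates the full model (GAT-3 on, GABA_A receptors on both neurons,
basal astrocytic Glu 1.5 mM) under a 20 s stimulus window and reports the
transporter-coupling observables: astrocytic Na+ loading, the E_GAT dip
below the astrocytic membrane potential, and synaptic GABA accumulation.
"""

import trisyn

cfg = trisyn.default_config(glu_ast_basal=1.5, duration=30.0)
protocol = trisyn.Protocol(window_start=5.0, window_duration=20.0,
                           total_duration=30.0)
res = trisyn.run(cfg, protocol, on_error="partial")

t, tr = res.time, res.traces
in_win = t >= protocol.window_start
print(f"status             : {res.status}"
      + (f" at t = {res.fail_time:.2f} s ({res.fail_detail})"
         if res.status != "ok" else ""))
print(f"pre / post spikes  : {res.spikes_pre.size} / {res.spikes_post.size}")
print(f"peak Na_ast        : {tr['na_ast'].max():.3f} mM (from 15.000)")
print(f"min  K_ast         : {tr['k_ast'].min():.1f} mM (from 130.0)")
print(f"peak K_syn         : {tr['k_syn'].max():.2f} mM (from 4.00)")
print(f"min E_GAT - V_a    : {(tr['e_gat'][in_win] - (-80.0)).min():+.5f} mV")
print(f"peak GABA_syn      : {tr['gaba_syn'].max():.3e} mM "
      f"(baseline {tr['gaba_syn'][0]:.3e})")
print(f"peak Glu_syn       : {tr['glu_syn'].max():.3f} mM")

print()
print("A negative 'min E_GAT - V_a' confirms the transporter reverses during")
print("stimulation (GABA efflux).  In this faithful parameterisation the")
print("excursion is fractions of a mV and the released GABA stays near its")
print("sub-micromolar baseline - far below the ~1 mM receptor K_d - so the")
print("published postsynaptic suppression does not emerge.")
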