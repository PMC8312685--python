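# trisyn — a tripartite glutamatergic synapse simulator

`trisyn` is a biophysical simulator of a glutamatergic synapse ensheathed by
a perisynaptic astrocyte, written for computational neuroscientists who want
to study how astrocytic transporter thermodynamics feed back on neuronal
excitability. It couples:

* **two Hodgkin–Huxley neurons** (presynaptic and postsynaptic) with an
  instantaneously activating Na⁺ current (`I_Na = g_Na m_∞³ h (V − E_Na)`),
  a delayed-rectifier K⁺ current (`g_K n⁴`), an ohmic leak, and two-state
  ligand-gated receptor channels — NMDA (with the voltage-dependent Mg²⁺
  block `1/(1 + e^{−0.062V} [Mg]/3.57)`), AMPA and GABA_A;
* **three-pool vesicle resources** (recovered *x*, active *y*, inactive *z*;
  `dx/dt = z/τ_r − U x δ(t − t_sp)` …) releasing `0.1 mM × U x` of glutamate
  and a small amount of K⁺ into the cleft at every presynaptic spike;
* **an astrocytic compartment** at fixed membrane potential `V_a` whose
  EAAT-2, GAT-3, Na⁺/K⁺-ATPase, Na⁺/Ca²⁺-exchanger and Kir4.1 currents move
  Na⁺, K⁺, Glu, Ca²⁺ and GABA between the synaptic and astrocytic
  compartments via Faraday's law, `d[X]_ast/dt = −I_X S_A / (z_X F Vol_A)`.

The scientific focus is the thermodynamic **coupling of EAAT-2 and GAT-3**:
glutamate uptake imports 3 Na⁺ per cycle, the Na⁺ load pulls the GAT-3
reversal potential

```
E_GAT = (RT/F) ln( (Na_syn/Na_ast)² · (GABA_syn/GABA_ast) · (Cl_syn/Cl_ast) )
```

below `V_a`, and the ohmic transporter `I_GAT = g_GAT (V_a − E_GAT)`
reverses, releasing astrocytic GABA into the cleft — a candidate mechanism
for tonic inhibition at excitatory synapses.

## Worked example

```python
import trisyn

cfg = trisyn.default_config(glu_ast_basal=1.5, duration=30.0)
protocol = trisyn.Protocol(window_start=5.0, window_duration=20.0,
                           total_duration=30.0)
res = trisyn.run(cfg, protocol, on_error="partial")
print(res.spikes_pre.size, res.traces["na_ast"].max(),
      res.traces["gaba_syn"].max())
```

Running `examples/04_gaba_release_run.py` (which does the above and a little
more) prints:

```
status             : nonpositive at t = 8.60 s (concentration ca_ast became non-positive)
pre / post spikes  : 210 / 214
peak Na_ast        : 15.268 mM (from 15.000)
min  K_ast         : 102.7 mM (from 130.0)
peak K_syn         : 12.08 mM (from 4.00)
min E_GAT - V_a    : -0.00031 mV
peak GABA_syn      : 3.663e-04 mM (baseline 3.536e-04)
peak Glu_syn       : 0.206 mM
```

Reading: the stimulus evokes presynaptic firing, EAAT-2 activity loads the
astrocyte with Na⁺ (15.00 → 15.27 mM), E_GAT dips below the astrocytic
membrane potential (negative `min E_GAT − V_a`, i.e. GAT-3 reverses and
releases GABA), synaptic K⁺ rises and astrocytic K⁺ falls. The run ends
early because astrocytic Ca²⁺ collapses through zero — positivity is
enforced by failure, and this domain exit is itself a property of the
printed parameter set, analysed in the methods note.

The other examples cover the equilibrium calibration and resting potential
(`01`), transporter reversal-potential thermodynamics (`02`), the pulsed
presynaptic drive (`03`) and the full factorial design over basal astrocytic
Glu × feedback variant (`05`). Each builds its own inputs and prints what
it computes.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the simulator from scratch, (t1) the mean presynaptic
firing rate under the pulsed 5 µA/cm² protocol with all GABA feedback
disabled, measured over a 10 s stimulus segment, and (t2) the settled
postsynaptic membrane potential after 5 s without stimulation. The model is
fully deterministic; `--seed` is accepted for interface uniformity only.

## Layout

```
src/trisyn/
  params.py       configuration, units, validation, serialization
  neuron.py       HH gating, receptor kinetics, membrane currents
  release.py      three-pool vesicle resources and per-spike release
  astro.py        transporter/channel laws, reversal potentials, composition
  equilibrium.py  basal-GABA and ambient-Glu solves, leak calibration
  kernel.py       numba forward-Euler integration kernel (0.01 ms steps)
  simulator.py    state assembly, flux conversion, run/step, HDF5+CSV I/O
  protocols.py    stimulus protocol, spike detection, rates, study runner
docs/methods.md   model description, numerical choices, known limitations
examples/         one narrative script per capability
```
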