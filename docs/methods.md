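# Methods

## Model

The simulator describes one glutamatergic synapse as three coupled
compartments: a presynaptic terminal, a postsynaptic terminal and a
perisynaptic astrocytic process, with a shared synaptic (cleft) bath. The
dynamic species are Na⁺, K⁺, Glu, Ca²⁺ and GABA in the cleft and in the
astrocyte; H⁺ and Cl⁻ enter only as fixed trans-membrane ratios inside
transporter reversal potentials. Only astrocytic membrane currents move
concentrations; the neurons sense the bath (through Nernst potentials and
receptor agonists) but do not load it, except for the spike-triggered
injection of Glu and K⁺ by the presynaptic terminal.

### Neurons

Both neurons use the same fast-spiking conductance set (C_m = 1 µF/cm²,
g_Na = 35, g_K = 6, g_L = 0.0112 mS/cm², E_L = −74.6 mV):

* `I_Na = g_Na m_∞(V)³ h (V − E_Na)` with `m_∞ = 1/(1+e^{−(V+30)/9.5})`,
  `h_∞ = 1/(1+e^{(V+45)/7})`, `τ_h = 0.1 + 0.75/(1+e^{(V+40.5)/6})` ms;
* `I_K = g_K n⁴ (V − E_K)` with `n_∞ = 1/(1+e^{−(V+35)/10})`,
  `τ_n = 0.1 + 0.5/(1+e^{(V+27)/15})` ms;
* `E_Na = (RT/F) ln(Na_syn/Na_neuron)` and likewise for K⁺, with fixed
  neuron-internal Na⁺ = 15 mM and K⁺ = 130 mM, recomputed every step from
  the dynamic cleft concentrations.

The typeset gating exponents in the source tables are ambiguous; we adopt
the orientation in which activation gates increase and the inactivation gate
decreases with V, using the printed midpoints (−30, −35, −45 mV), slopes
(9.5, 10, 7) and time-constant parameters (−40.5/6, −27/15 under the
`1/(1+e^{−(V−θ)/σ})`, σ < 0 convention).

Receptors are two-state binding schemes `dr/dt = α[A](1−r) − βr` with the
printed rate constants (α in M⁻¹ms⁻¹ ≡ mM⁻¹s⁻¹); NMDA carries the Mg²⁺
block `1/(1 + e^{−0.062 V_mV}[Mg]/3.57)` with [Mg] = 1 mM by default (not
printed; common convention, configurable). The presynaptic membrane carries
a GABA_A conductance (when placed) plus the applied stimulus; the
postsynaptic membrane carries NMDA + AMPA + GABA_A. Applied current is
stored as a positive, depolarising stimulus density.

### Release

A three-pool resource model (recovered x, active y, inactive z; U = 0.5,
τ_r = 0.8 s, τ_i = 3 ms) governs release. At each presynaptic spike
(upward 0 mV crossing, 2 ms refractory guard) a fraction U·x moves from x to
y and the cleft receives `0.1 mM × (U x)` of Glu instantaneously plus
`k_release` of K⁺. The alternative continuous-source reading (a Glu source
proportional to y(t), `d[Glu]_syn/dt += 0.1 mM·s⁻¹ × y`) is implemented
behind `release_mode="continuous"`; the impulse interpretation is the
default so that synaptic Glu clearance is attributable solely to EAAT-2.
`k_release` is not printed in the source ("a small amount"); the default is
0.05 mM per spike — small against the 4 mM resting cleft K⁺.

### Astrocyte

The astrocytic membrane potential V_a is held constant (−80 mV by default,
the stated resting value; configurable). Component currents (A/m², positive
= efflux of positive charge):

| current | law |
|---|---|
| EAAT-2 | `I = −α e^{−β(V_a − E_EAAT)}`, `E_EAAT = (RT/2F) ln((Na_s/Na_a)³ (H_s/H_a)(Glu_s/Glu_a)(K_a/K_s))` |
| GAT-3 | `I = g_GAT (V_a − E_GAT)`, `E_GAT = (RT/F) ln((Na_s/Na_a)² (GABA_s/GABA_a)(Cl_s/Cl_a))` |
| NKA | `I = I_max · Na_a^1.5/(Na_a^1.5 + K_Nai^1.5) · K_s/(K_s + K_Ke)` |
| NCX | `I = I_max ((Na_a/Na_s)³ e^{γFV_a/RT} − (Ca_a/Ca_s) e^{(γ−1)FV_a/RT})` |
| Kir4.1 | `I = g_Kir · K_syn · (V_a − E_K)`, K_syn as its numeric value in mM |
| leak | `I_X,L = g_X (V_a − E_X)` per species, E_X the Nernst potential |

Species compositions: `I_Na = 1.5 I_EAAT + 3 I_NKA + 3 I_NCX + 2 I_GAT +
I_Na,L`; `I_K = −0.5 I_EAAT − 2 I_NKA + I_Kir + I_K,L`; `I_Glu = −0.5 I_EAAT
+ I_Glu,L`; `I_Ca = −2 I_NCX + I_Ca,L`; `I_GABA = I_GAT`. The printed K⁺
composition carries `+2 I_NKA`, which would make the pump *export* K⁺,
contradicting its 3 Na⁺-out/2 K⁺-in cycle and the accompanying narrative;
the default sign restores import and the literal sign is available via
`nka_k_sign=+1`. GABA carries one net elementary charge per GAT-3 cycle
(2 Na⁺ + 1 Cl⁻ + 1 GABA), so an effective z_GABA = +1 is used in the flux
conversion; z_Glu = −1 as printed. An NKCC law is implemented but excluded
from the compositions (and its magnitude defaults to zero) since the source
prints the law without using it. The table entry "E_Kir = 0.025 V" is not
referenced by the printed Kir law; it is exposed as an optional additive
offset on the Kir driving force, unused by default.

Currents convert to concentration rates by Faraday's law with the
perisynaptic area S_A = 1.4137·10⁻¹³ m² and volumes Vol_A = 1.885·10⁻¹⁷ L,
Vol_S = 8.5883·10⁻¹⁶ L; the same current changes both compartments with
opposite signs, so species moles are conserved across the pair up to the
explicit injection ledger.

## Equilibrium construction

Initial concentrations are not printed in the source; the defaults are
standard mammalian values (cleft/astrocyte: Na 140/15, K 4/130, Ca 2/10⁻⁴,
GABA_ast 2 mM; H ratio from pH 7.3/7.2; Cl ratio 130/40), all configurable.
The run starts from a constructed equilibrium:

1. **Basal synaptic GABA** solves `E_GAT(t=0) = V_a` in closed form
   (≈ 3.54·10⁻⁴ mM at the defaults) — no net GABA flux at rest.
2. **Ambient synaptic Glu** is calibrated so the unstimulated postsynaptic
   neuron rests at −71 mV. The intrinsic conductances rest the cell at
   ≈ −74.3 mV; the printed −71 mV ("calculated at equilibrium values") is
   reachable only with a tonic receptor current, and ambient cleft Glu is
   the physiologically meaningful knob. The calibrated value, ≈ 4.6·10⁻³
   mM (4.6 µM), is realistic ambient glutamate. The calibration uses the
   full receptor complement and is a bath property, identical across
   placement variants.
3. **Leak conductances** per species balance the transporter sum at t = 0:
   `g_X = −I_X,transport/(V_a − E_X)`. These are algebraic balance terms,
   not channel fits, and can be negative; at the defaults the K⁺ leak is
   ≈ −5.76·10³ S/m² (balancing the very large Kir term) and the Ca²⁺ leak
   is ≈ −4.9·10⁻⁶ S/m².
4. Neurons start at the resting potential of their own current set (solved
   by bisection to machine precision), gates at steady state, receptor open
   fractions at their binding fixed points.

Every state derivative is < 10⁻¹² (solver units) at t = 0, and the
integrator holds the equilibrium over at least 10⁴ steps. Persistence over
much longer horizons is *not* guaranteed: the calibrated K⁺ balance is a
genuine equilibrium but linearly unstable (growth rate ≈ 32 s⁻¹, see below),
so 1-ulp rounding residuals would amplify over ~1 s horizons once perturbed.

## Numerics

* Fixed-step forward Euler, dt = 0.01 ms (the source's scheme and step);
  larger steps allowed by explicit override. Traces are decimated to 1 ms
  by default; spike times are detected inside the kernel at full resolution
  (upward 0 mV crossing, 2 ms refractory) and release is applied at the end
  of the step in which the crossing is detected.
* All computation in SI-based canonical units (V, s, A/m², S/m², F/m²),
  except concentrations in mM (every law uses ratios; the mol/L↔mM factor
  appears once, in the flux conversion).
* The EAAT exponent is clamped at +50 with a warning — reaching it means
  the state has left the physical regime, not a numerical subtlety.
* Concentration positivity is enforced by failure, never clamping; a failed
  run can be returned as a truncated result with diagnostics
  (`on_error="partial"`).
* Runs are deterministic and bit-reproducible; the pure-Python reference
  integrator reproduces the numba kernel bit-for-bit on test horizons.

## What the simulated world does and does not establish

All inputs are generated by the package itself (protocol + printed
parameter tables); there is no external data. Green unit/property tests
establish that each printed current law, the composition stoichiometry, the
flux conversion, the equilibrium construction and the conservation
properties are implemented exactly as stated. They do not establish that
the printed parameter set reproduces the study's reported phenomenology —
it demonstrably does not, as follows.

## Known limitations and model pathologies

These are robust properties of the faithful implementation (verified at
dt = 0.01 ms and 0.002 ms, with the reference and compiled integrators):

1. **The presynaptic neuron cannot be paced at 10 Hz.** With g_L = 0.0112
   mS/cm² the membrane time constant is ~89 ms, and the Na⁺ window current
   (m_∞³h_∞ overlap around −50 mV) dwarfs the leak. The resting state
   (−74.3 mV) coexists with a stable ~30–60 Hz spiking limit cycle whose
   inter-spike voltage stays near −60 mV: a single evoked spike latches
   tonic firing at zero applied current. No square-pulse width of the
   5 µA/cm² stimulus yields one spike per pulse (short pulses integrate
   across the 89 ms time constant; any spike latches the oscillation), so
   the "10 Hz presynaptic rate" of the source protocol is unattainable.
   The default pulse width stays at 10 ms.
2. **Kir4.1 dominates K⁺ handling.** At the printed g_Kir = 1440 S/m² the
   resting Kir current is ~75 A/m² — three orders above every transporter —
   and is balanced by an equally large negative calibrated leak. The pair
   pins the cleft/astrocyte K⁺ ratio to the E_K ≈ V_a manifold: the
   calibrated equilibrium is unstable (λ ≈ +32 s⁻¹) toward that manifold,
   and spike-injected cleft K⁺ is buffered *into* the astrocyte, so during
   sustained activity astrocytic K⁺ first falls (EAAT counter-transport)
   but then rises far above baseline — the reported sustained astrocytic K⁺
   *decrease* cannot be reproduced.
3. **Astrocytic Ca²⁺ collapses.** The calibrated Ca²⁺ leak conductance is
   negative, which makes the leak anti-restoring (efflux grows as Ca_ast
   falls); once the K⁺ excursion drives NKA/Na⁺ off baseline, NCX reverses
   and Ca_ast reaches zero within seconds of stimulation. The run then
   stops with a positivity failure — the documented behaviour, surfaced via
   `status="nonpositive"`.
4. **GABA release is thermodynamically clamped far below receptor
   sensitivity.** GAT-3 reverses as published (E_GAT dips below V_a in
   every stimulated run), but with g_GAT = 210 S/m² the transporter is stiff
   enough to hold E_GAT within a fraction of a mV of V_a, so synaptic GABA
   tracks its equilibrium value ≈ 0.03 mM × (Na_ast/Na_syn)². With the
   printed GABA_A kinetics (K_d = β/α = 1.44 mM) the resulting sub-µM GABA
   cannot generate appreciable inhibition: the published presynaptic
   slowdown and full postsynaptic suppression do not emerge.
5. **dt sensitivity.** The latched oscillation is not phase-locked to the
   stimulus, so spike counts on stimulated protocols shift by a few percent
   when dt is halved; the quiescent and sub-threshold behaviours are
   dt-robust.

The acceptance tests assert the *published* claims at their stated
tolerances and are left failing where the stated world cannot meet them;
the analysis above is the package's account of why.

## Open design choices (resolved)

* V_a = −80 mV, Mg²⁺ = 1 mM, initial concentrations, Cl⁻/H⁺ ratios:
  repository defaults as listed, all configurable.
* k_release = 0.05 mM per spike (unprinted magnitude).
* NKCC magnitude defaults to 0 A/m² (law printed without a magnitude or a
  role in the compositions).
* Glu injection: instantaneous per-spike increment (continuous-source
  variant behind a switch).
* The same firing-rate windowing (1 s, 10 % overlap) is used wherever rates
  are reported.
* No CLI: the importable API plus `examples/` is the interface; plotting is
  left to the caller (results export to pandas/CSV/HDF5).
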