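# Methods

## The model

`eadkit` implements a rabbit ventricular myocyte action-potential model in
the Shannon–Bers family, authored for this package with the structural
features needed to separate voltage-driven from Ca-driven
afterdepolarizations:

- **Compartments.** A 33 pL cell with myoplasm (65 %), submembrane space
  split into a junctional pool (JXN, 0.5 % of cell volume, receiving 90 %
  of `I_CaL` and the SR release flux) and a subsarcolemmal pool (SL, 2 %),
  and the SR split into junctional (JSR, with calsequestrin buffering) and
  network (NSR) stores. JXN↔SL and SL↔myoplasm Ca exchange are linear
  diffusive fluxes; the SL↔myoplasm strength `J_Caslmyo`
  (7.4485·10⁻¹³ l/ms control) is one of the five adjustable parameters.
- **Membrane currents.** Fast Na current (m³hj), inward rectifier `I_K1`,
  rapid delayed rectifier `I_Kr` (with inactivation-type rectification),
  slow delayed rectifier `I_Ks` (conductance `G_Ks` = 1.23 mS/µF control),
  transient outward `I_to`, Na/K pump, sarcolemmal Ca pump, Na and Ca
  background currents, Na/Ca exchanger (density `I_NCX_bar` = 5 A/F
  control, Shannon–Bers kinetics, allosteric Ca activation), and a GHK
  L-type Ca current (`P_Ca` = 2.7·10⁻⁴ cm/s control) gated by activation
  `d`, voltage inactivation `f`, a slow voltage inactivation `f₂`
  (τ = 3.5 s), and a Ca-dependent inactivation gate `f_Ca` per submembrane
  compartment.
- **Ca cycling.** SERCA uptake into the NSR (forward–reverse Hill form),
  NSR→JSR transfer (τ = 10 ms), a passive SR leak, and RyR release
  `J_rel = k_max·O·([Ca]_JSR − [Ca]_JXN)` with `k_max` = 0.2 ms⁻¹ control.
  RyR gating uses four states (closed, open, open-inactivated,
  closed-inactivated): opening is proportional to [Ca]²_JXN and scaled by
  a store-load sensitization factor (Hill form in [Ca]_JSR), open-state
  inactivation is Ca-dependent, closed-state inactivation is kept ten-fold
  weaker so that Ca-induced opening is not suffocated at burst onset. This
  gives the Ca subsystem a genuine load–release–refill limit cycle under
  voltage clamp in the strong-release/strong-uptake regime.
- **The non-monotonic `f_ss`.** The steady-state voltage inactivation of
  `I_CaL` is a falling sigmoid (midpoint −35 mV) plus a late rising
  component (amplitude 0.4, midpoint +50 mV). The late elevation re-admits
  Ca entry at depolarized plateau voltages; it is the structural substrate
  of the Ca-driven mechanisms, and the `flattened` variant (curve held at
  its minimum above the argmin) removes it.

Buffering: five cytosolic buffers (troponin C low/high, calmodulin,
myosin, SR-membrane sites) and the sarcolemmal low/high-affinity sites in
JXN and SL are ODE buffers; effective on-rates for the sarcolemmal sites
are diffusion-limited (10 mM⁻¹ms⁻¹, dissociation constants as in the
parent lineage) so that the buffer–Ca exchange stays inside the explicit
integrator's stability region. Calsequestrin uses the rapid-buffer
approximation (its kinetics are far faster than every other Ca process).
[K]_i is fixed at 135 mM and Na is a single intracellular pool: potassium
depletion and Na compartment gradients are negligible on the ≤ 20 s
horizons simulated here.

## Integration

Explicit Euler at dt = 0.01 ms is the reference scheme; the nine
Hodgkin–Huxley gates advance by their exact exponential relaxation
(Rush–Larsen update) because the Na-activation rate (~200 ms⁻¹ at rest)
lies outside the forward-Euler stability region at this step. Membrane
voltage, concentrations, RyR states and buffers use the forward-Euler
update. Step-halving changes the stored voltage trace by less than
0.5 mV everywhere past the first 5 ms; across the ~130 mV/ms upstroke the
same comparison is bounded by 1 mV, corresponding to a timing shift of a
few microseconds. Trace storage is decimated to 1 ms by default.

Clamps are honored inside the right-hand side: a clamped state variable
(membrane voltage, or both submembrane Ca pools simultaneously) has its
derivative forced to zero and its value imposed each step; a clamped
current (`I_CaL`, `I_NCX`) is substituted both in the voltage equation
and in the ion-flux equations, split between compartments by the same
fractions as the free current. Hold-at-onset and ramp clamps resolve
their reference level from the instantaneous current at window onset.

The initial condition is the rested state after 20 s of unstimulated
relaxation at control parameters (computed once per session and cached);
residual drift is below 10⁻⁴ per ms in every state variable, dominated by
the ultra-slow Na balance.

## Detection and classification

An EAD is a local maximum of V_m with prominence ≥ 1 mV and width ≥ 2
blocks on a 10 ms block-averaged copy of the trace (a hump spans tens of
ms, whereas sampling noise decorrelates between blocks), whose preceding
minimum — the point where dV/dt turns positive — lies in the −70…+20 mV
band. Oscillations of any signal are counted as local maxima with
prominence above 5 % of the signal range in the analysis window; "the
subsystem oscillates" always means at least two qualifying cycles. APD is
measured to −75 mV; repolarization failure means no crossing within the
10 s single-stimulus horizon, or APD beyond the pacing interval in paced
runs. Phase labels compare the mean signed lag between V_m and Ca
turning points with the mean cycle period (in-phase < 10 %, out-of-phase
> 40 %).

The classifier runs the decision tree described in `eadkit.dissect`:
baseline AP → repolarization-failure gate → Ca-trace gate (no Ca cycling
at all ⇒ Ca-transient driven, type IV) → submembrane-Ca clamps at the
lowest/highest level of the EAD-phase range (V_m oscillations persist ⇒
voltage-driven, type I) → V_m clamps at the lowest/highest plateau level
(Ca oscillations persist ⇒ Ca-driven, type II) → otherwise
coupling-driven (type III) when the baseline Ca truly cycles, or type IV
when the "oscillation" was a single passive hump. Confirmatory runs
(constant `I_NCX` / `I_CaL` clamps for type II; the 0.5× scaled Ca-trace
clamp for type IV) are recorded as evidence but do not decide the label.

## Design choices where the design was open

- The five adjustable parameters enter as multiplicative factors on their
  control values; a derived parameter set is flagged so scaling cannot be
  applied twice.
- Monte Carlo sampling is log-uniform over [0.1, 10] (symmetric around
  control on the log scale); linear-uniform is available.
- Clamp windows default to [first EAD takeoff, end of repolarization +
  2 s]; clamp levels come from the EAD-phase range of the clamped signal.
- The flattening rule is "hold at the minimum beyond the argmin"; the
  tabulated-curve operation and the compiled kernel implement the same
  rule and are cross-checked in the tests.
- Several kinetic constants of the model (the `I_Ks` activation midpoint,
  slope and time-constant profile; the amplitude, midpoint and slope of
  the late `f_ss` elevation; the RyR burst-termination constants; the
  slow `f₂` gate) are this package's own calibration, chosen during model
  development so that the control cell is quiescent at rest and paces
  normally, the voltage oscillator produces finite EAD trains inside a
  band of the `alpha(P_Ca)`–`alpha(G_Ks)` plane, the Ca subsystem can
  limit-cycle under voltage clamp at strong release/uptake, and a single
  large Ca transient can carry one EAD. They are ordinary model constants,
  not exposed scan parameters.

## What the synthetic generator does and does not emulate

`eadkit.synthetic` produces stylized AP/Ca trace pairs: a template AP
with a damped-sinusoid EAD train (decay constant two periods) inserted in
the repolarization phase, a phase-shifted Ca copy or a single prolonged
Ca transient, and i.i.d. Gaussian noise. Ground truth (hump count,
takeoff times, per-hump amplitudes, phase lag) is carried in the trace
metadata, which is what makes detector recall/specificity testable
exactly. The generator has no membrane or Ca-cycling physics: passing
detector tests on it validates the *detectors*, not the model, and says
nothing about real signals beyond the morphological features it copies.

## Known limitations

- The model is an independent reconstruction of its family, not a
  re-implementation of a specific published code; quantitative agreement
  with figure-level values of any particular model is approximate. In
  particular, at the representative "coupling" parameter point the
  voltage subsystem of this model still oscillates under a fixed-Ca
  clamp, so that point classifies as voltage-driven rather than
  coupling-driven, and the Monte Carlo composition under-represents the
  Ca-oscillation-driven class relative to stronger-coupled models.
- Flattening `f_ss` strongly reduces, but does not exactly zero, the
  Ca-dependent mechanism fractions in this model: the flattened curve
  retains its minimum value (≈ 0.03) at all plateau voltages, which at
  large `alpha(P_Ca)` still admits enough Ca entry for occasional
  Ca-driven classifications.
- The junctional and subsarcolemmal Ca pools are *not* nearly identical
  during the release phase: the local-control trigger works through a
  junctional gradient (ratio up to ~4 during the transient, decaying
  through the plateau). Clamping "submembrane Ca" sets both pools to a
  common value, which is exact for the clamp semantics but coarser than
  in a model whose two pools track each other tightly.
- Euler stability, not accuracy, dictates several kinetic choices
  (buffer on-rates, RyR closure rate); a stiff solver would admit faster
  kinetics but would break bit-reproducibility of the fixed-step
  reference scheme.
- No stochastic RyR gating, no tissue coupling, no bifurcation-theoretic
  analysis: the mechanism labels are operational (clamp-based), not
  dynamical-systems classifications.
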