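# Methods

## Model

The taste-bud cell is a single isopotential compartment with membrane
capacitance C_m and four currents: a transient Na⁺ current (g_Na·m³h), a
delayed-rectifier K⁺ current (g_K·n⁴), an ohmic leak, and the TMC4 chloride
current. Gates obey first-order kinetics dx/dt = (x∞(V) − x)/τ(V) with
Boltzmann steady states x∞(V) = 1/(1 + exp(−(V − V½)/k)) (k < 0 for
inactivation) and a bell-shaped time constant
τ(V) = τ_min + (τ_max − τ_min)/cosh((V − V½)/(2|k|)), bounded by
[τ_min, τ_max].

The membrane equation is C_m dV/dt = −(ΣI_ion + I_app). The applied current
sits inside the bracket, so a negative command depolarizes; this is the only
convention under which the protocol set is self-consistent (a +10 pA hold
keeps the cell at −70 mV, below its −65 mV rest, while −140 pA and −15 pA
commands fire it).

Stimulus pulses use **step-command semantics**: a pulse's amplitude is the
commanded current while it is active, replacing the holding current — exactly
how clamp software delivers a step from a holding level. A −15 pA / 500 ms
command on a +10 pA hold therefore applies −15 pA, a 25 pA step. Under the
alternative (additive) reading the same protocol would net only −5 pA, leaving
a ~2 mV margin between rest and the repetitive-firing threshold; no
conductance set we explored makes the full phenomenology robust in that
regime, and we consider the command reading the physiological one.

Reversal potentials come from the Nernst equation with R = 8.314462618
J·mol⁻¹·K⁻¹ and F = 96485.332 C·mol⁻¹, treating concentrations as activities.
Standard conditions are [Na⁺]ₒ/ᵢ = 150/6, [K⁺]ₒ/ᵢ = 5.4/140,
[Cl⁻]ₒ/ᵢ = 150/30 mM at 298.15 K (recordings were made near 25 °C), giving
E_Na = +82.7, E_K = −83.6, E_Cl = −41.35 mV. The temperature is a config
field; no Q10 scaling is applied.

## TMC4

TMC4 is modelled as an outwardly rectifying conductance with an ohmic driving
force:

    I_TMC4 = g_max · s · b · aᵣ · a(V) · (V − E_rev)

where s is the expression multiplier (the 0–3 "conductance amplification"
axis), b ∈ [0, 1] a pharmacological block factor, aᵣ ∈ (0, 1] an anion-species
amplitude factor (chloride ≡ 1), and a(V) Boltzmann activation. Amplitude
factors never move the reversal, matching the observation that anion
substitution scales current amplitude with unchanged E_rev. The current is
Ca²⁺-independent by contract (the `ca_i` argument exists only for interface
symmetry with the ANO1 comparator, which is Hill-gated in Ca²⁺ with
ca_half = 400 nM, n_H = 2 — round-number defaults for a channel activating in
the hundreds-of-nanomolar range).

Two TMC4 configurations ship:

- **Heterologous (whole-cell) defaults** — g_max = 10 nS, V½ = 0 mV,
  k = 25 mV, instantaneous gating, fixed E_rev = −27.6 mV (KCl pipette) or
  −25.6 mV (NMDG-Cl pipette). The fixed reversals are the measured whole-cell
  values; they differ from the Nernst E_Cl because recording-solution anion
  compositions are not part of this model. V½ and k are artifact choices
  giving strong outward rectification (|I(−100)| < 0.15·|I(+100)|) with small
  inward currents, and are config-overridable.
- **Cell-model block** — g_max = 3 nS, V½ = +20 mV, k = 18 mV,
  E_rev = Nernst E_Cl, and **first-order activation with τ_act = 1.5 ms**.
  The more positive midpoint keeps the channel silent between spikes (no
  standing depolarizing Cl⁻ efflux at the −58 mV inter-spike baseline, which
  otherwise drives the cell into depolarization block at high expression
  factors), and the activation lag delays the chloride current into the
  repolarization phase. The lag is the mechanistically meaningful choice
  here: with instantaneous gating the TMC4 current is maximal exactly at the
  spike peak, where its main effect is to shave the peak — and since the cell
  is calibrated to a fixed peak with TMC4 present, the TMC4-free comparison
  limb then repolarizes *faster*, inverting the expected dV/dt contrast. A
  ~1.5 ms activation constant is unresolvable in 400 ms voltage-clamp steps,
  so both configurations are consistent with the same quasi-steady I–V data.

## Calibration

Anchors: V_rest = −65 mV at I_app = 0; V = −70 mV at I_app = +10 pA; spike
peak +50 mV for a −140 pA / 1 ms command; repetitive firing under
−15 pA / 500 ms.

- **Stage 1 (exact).** With Na⁺/K⁺/TMC4 gates at steady state, the two
  fixed-point constraints are linear in (g_L, g_L·E_leak):
  g_L = (i_hold − ΔI_other)/(V_rest − V_held), then
  E_leak = V_rest + I_other(V_rest)/g_L. Anchors with V_rest = V_held are
  rejected as inconsistent.
- **Stage 2.** g_Na is scaled by Brent root-finding so the evoked spike peak
  equals the anchor; above firing threshold the peak is a smooth, increasing
  function of g_Na. The two stages are iterated twice (rescaling g_Na
  perturbs stage 1 only through the sub-pA subthreshold Na⁺ current).
- **Verification.** The result must reproduce all four anchors (0.5 mV on
  potentials, 1 pA on the holding current, 5 mV on the peak) and fire ≥ 2
  spikes in the 500 ms train; otherwise a calibration error names the
  violated constraint.

The remaining defaults (C_m = 10 pF; gate parameters m: −54/3.5 mV,
τ 0.05–0.25 ms; h: −58/−3.5 mV, τ 0.3–6 ms; n: −48/4 mV, τ 1–8 ms;
g_K = 10 nS; base g_Na = 120 nS, calibrated to ≈ 82 nS) are artifact choices
selected so the calibrated cell satisfies every anchor simultaneously: the
cell must be quiescent at −65 mV yet fire repetitively from a baseline only a
few millivolts higher, which demands a low-threshold, steep Na⁺ activation;
K⁺ is kept small and slow enough that repolarization has a substantial TMC4
component while still providing the after-hyperpolarization that sustains
repetitive firing. The h and n steepness values are set so no stable
depolarized fixed point survives near E_Cl — with shallower gates the
TMC4-amplified cell fires a few spikes and then locks up at ≈ −41 mV. These
are modelling choices, not measured taste-cell gating constants; only the
anchor values themselves are experimental.

## Protocol integration

Current clamp integrates piecewise between pulse edges (the command is
constant on each segment) with LSODA, rtol 1e−8, atol 1e−10, and the internal
step capped at 0.05 ms during pulses ≤ 5 ms so brief stimuli are never
stepped over. Output is sampled on a uniform grid (default 0.01 ms). The
initial state is the steady state under the holding current, gates at their
steady values. Integration is deterministic: identical inputs give
bitwise-identical traces, and halving the tolerances moves sampled voltages
by < 0.1 mV.

Voltage clamp assumes an ideal clamp: V follows the command exactly, the
capacitive transient is cancelled, and the reported sweep is the total ionic
current with gates relaxing toward their steady states at the command
potential. Step mode reproduces the standard family (hold −60 mV, 400 ms
steps from −100 to +100 mV in 10 mV increments → 21 sweeps); ramp mode runs
−100 → +100 mV in 300 ms. At the end of a 400 ms step every gate is at
steady state to machine precision, so steady sweep currents equal the
algebraic channel sums — an equivalence the test suite enforces at 1e−6.

Steady states are found by scalar root-finding (Brent, 481-point bracketing
scan over [−120, 0] mV) on the steady I–V relation, returning the most
hyperpolarized root whose finite-difference Jacobian has all eigenvalue real
parts negative. The holding current for a target potential is the algebraic
−I_ion(V_target), verified by re-solving the steady state (round-trip
tolerance 0.01 mV); an unstable target raises an error rather than returning
a current that cannot hold the cell.

## Analysis conventions

- **I–V extraction**: window-mean current per sweep; the default window is
  the last 10 % of the step (quasi-steady region). The published traces mark
  selection points only graphically, so the window is an explicit parameter.
- **Reversal estimation**: linear interpolation between the adjacent
  opposite-sign I–V points; with several crossings the most negative-voltage
  one is returned (the physiological branch for an outward rectifier). On a
  10 mV grid the Boltzmann curvature biases the estimate by ≈ −0.5 mV
  (−28.1 mV recovered for a true −27.6 mV); this is inherent to
  interpolation on the published step protocol, not noise. Curves that never
  change sign raise an error — with very small inward currents the reversal
  is genuinely indeterminate.
- **Inhibition ratio**: I_blocker/I_control at the +60 mV step
  (window means); |I_control| < 1 pA is rejected as undefined.
- **Spike detection**: local maxima above a 0 mV threshold, ≥ 5 ms apart
  (closer peaks merge, keeping the larger). dV/dt uses central differences on
  the uniform grid with no smoothing — simulated traces are noise-free; a
  moving-average pre-filter is the caller's responsibility for noisy input.
  AP duration is the time above the detection threshold around the peak
  (half-height duration is not defined in the source experiments).
- **Cycle length**: the mean of *all* successive inter-peak intervals within
  the stimulus window; with fewer than two spikes it is reported as absent,
  never zero. (Excluding the first interval would change values by < 2 % in
  the default sweep and no conclusion in the package depends on the choice.)

## Synthetic data

All generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; fixtures carry their ground truth in metadata.

- `gen_vc_sweeps`: model voltage-clamp sweeps plus i.i.d. Gaussian current
  noise (default σ = 5 pA for recovery tests).
- `gen_ap_trace`: difference-of-exponentials spike templates (rise 0.5 ms,
  decay 2 ms, peak +50 mV) on a flat baseline, placed so the declared spike
  time is the waveform peak.
- `gen_expression_table`: log-normal background expression (ln-mean 1.0,
  ln-SD 1.5, spanning ~0.01–10³ RPKM as in tissue RNA-seq) with background
  CvP/Epi ratios drawn strictly below the screen threshold and planted
  candidates strictly above it, so the planted set is exactly the
  filter-passing set.

What the generators do **not** emulate: capacitive spikes, series-resistance
and liquid-junction errors, drift, correlated noise, overdispersed counts or
normalization artefacts in expression data. Passing recovery tests therefore
demonstrates correctness of the operators under clean assumptions, not
robustness to real recording pathology.

## Problem sizes

The default test and acceptance workloads are sized for interactive runs: one
calibration (~2 s), 21-sweep step families at 0.1 ms sampling, 2 s of
current clamp at 0.01 ms, a 7-factor × 520 ms conductance sweep at 0.02 ms,
20-seed reversal recovery, and 50 × 1000-gene screen tables. Everything is
deterministic except where a noise seed is explicit.

## Limitations

- Gating parameters are calibrated constructs; only the anchor values are
  experimental. No claim is made that they equal any published taste-cell
  kinetics.
- The driving force is ohmic, not Goldman–Hodgkin–Katz; at the strongly
  asymmetric physiological Cl⁻ concentrations a GHK flux would bend the I–V
  between the reversal and large positive potentials.
- Single compartment, single cell: no taste-bud network, transmitter
  release, or receptor-potential generator upstream of the injected current.
- The expression screen validates the filter logic on synthetic tables; the
  published candidate count depends on the full sequencing dataset and is
  not reproduced here.
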