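# Methods

## The model and what the package computes

`atrialaf` studies how the ionic remodeling of persistent atrial
fibrillation (PeAF) reshapes the human atrial action potential (AP) and
the reentrant waves it supports. The cell model is the
Courtemanche–Ramirez–Nattel (CRN) human atrial myocyte (Am J Physiol
1998, 275:H301): 21 state variables — membrane potential, 15 gating
variables, intracellular Na⁺/K⁺/Ca²⁺ and two sarcoplasmic-reticulum (SR)
Ca²⁺ compartments — and 12 membrane currents. We keep the membrane sign
convention throughout: inward current negative, `dV/dt = −(I_ion +
I_stim)/C_m` with C_m = 1 µF/cm².

PeAF electrical remodeling is a fixed multiplicative recipe on seven
parameters: G_Na −10%, G_to −70%, G_CaL −50% (variant *PeAF1*) or −70%
(*PeAF2*), G_Kur −50%, maximal SR-uptake-compartment Ca²⁺ −20%,
G_K1 +100%, maximal Na⁺/Ca²⁺-exchange (NCX) rate +40%. Single-factor
variants (*ICaL50*, *ICaL70*, *IK1x2*) isolate the two dominant players.

On top of the cell model sit four analyses:

1. **Parameter sensitivity of APD** — 20 parameters are perturbed by
   i.i.d. lognormal scale factors (median 1, log-SD σ = 0.1); each
   variant is paced to steady state at 1 Hz; z-scored log APD is
   regressed on z-scored log scale factors, giving dimensionless signed
   sensitivities and a fit quality R².
2. **Charge-integral decomposition of rate adaptation** — per-current
   charges Q_i = ∫ I_i dt over a fixed beat window (stimulus at 20 ms,
   rest by 500 ms) at steady 0.5 Hz and 2 Hz; ΔQ_i = Q_i(0.5 Hz) −
   Q_i(2 Hz). With inward negative, ΔQ < 0 marks a current that carries
   more depolarizing charge at the slow rate and therefore *promotes*
   APD rate adaptation. The NCX current is additionally split into its
   outward (reverse) phase, from stimulus onset to the first zero
   crossing, and its inward (forward) phase, from that crossing to the
   current's minimum.
3. **Monodomain tissue** — operator-split reaction–diffusion on a 1D
   cable (128 nodes) and a 2D sheet (full size 600×600 = 15 cm × 15 cm)
   with D = 0.001 cm²/ms, Δx = 0.025 cm, zero-flux boundaries.
   Conduction velocity, the dynamic APD-restitution protocol with its
   maximal slope S_max (3-point sliding linear fits of APD₉₀ vs
   diastolic interval), and cross-field S1–S2 reentry induction.
4. **Phase singularities (PS)** — per-node phase by time-delay embedding
   of V (delay τ = 10 ms, origin V* = −50 mV); a PS is a 2×2 plaquette
   around which the wrapped phase winds by ±2π. PS activity is
   normalized as 1000·N/N_frames/frame-interval(ms)/area(cm²), in
   s⁻¹·cm⁻².

## Measurement conventions

* APD is read at the fixed threshold V = −70.8 mV (the 90%-repolarization
  voltage of the control 1 Hz AP), linearly interpolated between samples;
  upward-to-downward crossing.
* Resting membrane potential (RMP) is the diastolic minimum over the
  last 50 ms before the final stimulus.
* Stimuli are 2 ms rectangular pulses at twice the capture threshold,
  which is found per cycle length by bisection (capture = an AP on every
  beat of a 10-beat run) to 1% relative precision.
* Steady pacing runs 250 s per rate; a final beat-to-beat APD change
  below 1 ms is reported as the steadiness diagnostic, and alternans or
  lost capture is flagged, never silently dropped.
* The adaptation curve applies its rates as a descending-BCL staircase
  (2000 → 330 ms, 250 s each, each rate continuing the previous state),
  the standard dynamic protocol; the slope is the chord between BCL
  2000 ms (0.5 Hz) and 500 ms (2 Hz). Fresh-start runs per rate are
  available (`staircase=False`) and give a noticeably smaller control
  slope because intracellular Na⁺ is still equilibrating at 250 s.

## Numerics

* **Single cell**: Rush–Larsen exponential updates for the 12
  voltage-gated gates, forward Euler for V, concentrations and the
  Ca²⁺/SR-release gates, fixed Δt = 0.02 ms. Validated against a
  brute-force 1 µs all-Euler oracle that shares no code path with the
  production integrator: APD agrees within 0.7 ms and peak V within
  1 mV on a stimulated beat; the two independent transcriptions of the
  rate equations agree to machine precision state-by-state.
* **Speed**: every voltage-dependent quantity (gate steady states,
  per-step Rush–Larsen decay factors, voltage-shaped current
  coefficients) is pre-tabulated on a 0.1 mV grid with linear
  interpolation, and Nernst potentials are cached per node and refreshed
  when a concentration drifts (0.1% for Na⁺/K⁺, 1% for Ca²⁺; worst-case
  E_Ca error 0.13 mV on a current with conductance 0.00113 nS/pF). Time
  is an integer count of 5 µs ticks; admissible step sizes are integer
  multiples of the smallest level so stimulus edges and sample instants
  are hit exactly.
* **Tissue**: operator splitting (reaction step, then explicit
  five-point diffusion at the same Δt), zero-flux via mirrored boundary
  nodes; CFL is checked at configuration time. The step adapts between
  its configured bounds — it drops to the floor whenever any node
  exceeded 5 mV/ms in the previous step and grows one level per step
  otherwise. The full-size configuration keeps the 0.01–0.1 ms bounds;
  because a reentrant sheet always contains a wavefront, that pins the
  global step at its floor, so the routine desk-scale runs use a 0.05 ms
  floor (cable and sheet). Halving the sheet floor to 0.025 ms changes
  the voltage field by 0.8 mV on average with a <1% wavefront shift;
  halving the 0D step changes APD by <1 ms.
* Degenerate inputs: rate formulas patch their removable singularities
  (−47.13, −14.1, −10, 7.9, 19.9 mV) with analytic limits; the
  razor-thin SR-release sigmoids are branch-shortcut outside ±35
  argument widths; non-finite states abort with the failure time.

## Problem sizes for routine verification

The test suite and the reproduction script use sizes that run in minutes
on one core, chosen once as the package's verification conditions:

* sensitivity fit quality: 200 trials, 60 s pacing (R² ≈ 0.97);
* sensitivity *structure*: 60-trial populations, two seeds, with 1000 s
  of pacing per control trial (see "slow Na⁺" below) and 250 s for
  PeAF, at Δt = 0.1 ms (the coarse step shifts APD ≈ 1 ms uniformly
  across trials and cancels in the coefficients);
* charge decomposition and RMPs: full 250 s pacing;
* restitution: the complete 40-stimuli-per-BCL cable protocol;
* 2D: a 5 cm (200×200) sheet, S2 coupling intervals found by scanning
  induction on that domain (PeAF2 200 ms, PeAF1 225 ms, ICaL50 300 ms),
  ~1.1 s of simulated reentry. The 15 cm experiment configs under
  `configs/` reproduce the full-size runs (hours each on one core).

## What the generator emulates — and what it does not

All "data" here are generated by the model itself: the lognormal
parameter populations stand in for cell-to-cell variability in channel
expression, and the remodeling recipe for disease. Passing tests
therefore validate the *computational chain* — equations, integrators,
estimators — not the biology: real atria add spatial heterogeneity,
fibrosis, anisotropic fiber fields and autonomic effects that this
isotropic monodomain sheet deliberately omits. The synthetic fixtures
(piecewise-linear AP surrogates, half-sine exchanger beats, analytic
vortex fields) have closed-form answers and exercise each measurement
stage without any simulation.

## Known limitations and open edges

* **Slow intracellular Na⁺** dominates long-horizon behavior of the CRN
  model: APD at a new rate keeps creeping for many minutes of simulated
  time. The control sensitivity *ranking* (G_K1⁻ > I_NaK⁺ > G_CaL⁺ >
  G_Kr⁻, NCX ≈ 0) only emerges at full Na⁺ equilibration (~1000 s per
  trial); at 250 s the I_NaK coefficient is still small or negative.
  At affordable population sizes the G_CaL, G_Kr and I_pCa coefficient
  magnitudes (0.18–0.28) overlap within sampling error, so the exact
  top-4 membership is not a stable desk-scale assertion; the sign
  structure (G_K1 strongly negative; NCX near zero in control and
  clearly negative in PeAF) is.
* The control adaptation slope saturates near 0.07 under every 250-s
  protocol variant we constructed (fresh-start, staircase, pre-adapted
  start); see the restitution/adaptation tables for the measured values.
* A 5 cm sheet cannot contain the ICaL50 spiral (wavelength ≈ 12.7 cm),
  so its multi-wavelet breakup is demonstrable only at full size; the
  desk-scale stability contrast uses PeAF1 (rotor + daughter wavelets)
  vs PeAF2 (single stable rotor).
* S_max for ICaL70 converges to ≈ 0.61–0.65 here (flat short-DI curve,
  maximal slope at mid-DI); ICaL50 gives ≈ 1.31 with alternans onset at
  BCL ≈ 210 ms, preserving the steep-vs-flat contrast that predicts
  breakup vs stability.
* Headline 2D classifications were checked insensitive to the embedding
  delay τ ∈ {10, 20} ms; τ and V* are configuration parameters.
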