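# Methods

## Model family and assumptions

The package simulates four deterministic, well-mixed ODE models of
synthetic transcriptional circuits in a single cell. Concentrations and
time are nondimensionalized; promoter responses are normalized squared
Hill functions (exponent fixed at 2, reflecting the dimerizing regulators
the designs are built from — exposing the exponent is deliberately
deferred). Ligand–receptor binding is not modelled dynamically: the
complex concentration entering an activating transfer function is the
instantaneous mass-action product X·x with unit association constant.
This is the simplest closure consistent with the circuit equations (it
vanishes whenever either factor does) and is accurate when binding
equilibrates fast compared with expression dynamics.

Two degradation classes create the time-scale separation that all four
designs rely on: tagged proteins turn over at λ, untagged ones at γ, with
λ ≫ γ. `CircuitParams` enforces λ ≥ γ as a hard constraint and warns when
λ/γ < 10, where memory persistence between pulses degrades but sweeps
near the boundary should still run.

Default parameters are the canonical operating points used throughout the
docs and fixtures:

| circuit | α | β | γ | λ | μ | ρ | K_out |
|---|---|---|---|---|---|---|---|
| habituation | 1.5 | 5 | 0.01 | 1 | 1 | – | – |
| sensitization | 1.5 | 5 | 0.01 | 1 | 1 | 1.75 | – |
| hybrid | 1.5 | 10 | 0.01 | 1 | 1 | 1.75 | 1.5 |
| msl | 1 | 1 | 0.01 | – | 1 | – | – |

All rates are inverse nondimensional time; α, β, μ, ρ are maximal
expression rates (promoter × RBS strength), γ and λ degradation–dilution
rates, K_out the half-activation of the hybrid output's repressor curve.

## Stimulation protocols

Inputs are piecewise-constant rectangular pulse trains. Pulse windows are
half-open `[onset, onset + width)` so x(t) is single-valued at edges. The
input amplitude defaults to 1: the receptor complex saturates its
transfer function at the canonical operating points for amplitudes of
order one or larger, so results are insensitive to the exact value; it is
configurable for regimes where that is not true. In the massed–spaced
protocol the `gap` is the input-free delay between consecutive pulses, so
onset-to-onset spacing is T/N + gap; with N = 1 the gap is irrelevant.

Each simulation starts from the circuit's closed-form no-input steady
state and runs to a default horizon of one full period past the last
onset plus a settling margin — ten fast lifetimes (10/λ) for the
tagged-output circuits, five slow lifetimes (5/γ) for the slow-turnover
chain — so the final-interval peak and tail are always captured. The
open-ended final scoring interval is truncated at this horizon.

The periodic-train fixtures use 10 pulses; this is a package choice (the
number of pulses only rescales how far habituation or sensitization has
progressed by the last peak). The hybrid fixture uses 20 pulses because
its sensitization-to-habituation turnover at the canonical operating
point occurs near pulse 13; a 10-pulse train would show only the rising
phase.

## Numerical scheme

Between input discontinuities the state is advanced with a classical
fixed-step 4th-order Runge–Kutta scheme; integration is restarted exactly
at every pulse edge, so no step ever straddles a discontinuity and the
formal order is preserved. The default step bound is
min(0.01, dur_on/100), giving global errors around 1e-8 at unit fast
rates; halving the step changes fixture trajectories by < 1e-6 of each
species' amplitude (asserted in the test suite). The scheme is
deterministic and bit-reproducible for a given step size — there is no
randomness anywhere in the tool, which is why nothing accepts a seed.

Dense output is produced by cubic interpolation of the accepted steps
within each smooth segment, sampled every dur_on/10 with all pulse edges
included. Peak extraction works directly on these samples without
sub-sample refinement; the interpolation error (∝ step⁴) is far below
every tolerance used downstream, and keeping the metrics solver-agnostic
was preferred over peak polishing. Tiny negative excursions (> −1e-9) are
clipped to zero; anything larger aborts the run with an error naming the
offending time, as does a non-finite state.

## Learning metrics

Peaks are the maxima of the output G over stimulus intervals
`[t_i, t_{i+1})` (final interval to the horizon), ties broken earliest.
Fold changes are log2 ratios of peaks: last/first for the single
behaviours; for the hybrid, highest/first (sensitization phase, ≥ 0 by
construction) and last/highest (habituation phase, ≤ 0). The hybrid ratio
orientations are a package convention chosen so that each phase's sign
and magnitude match the single-behaviour metrics. The massed–spaced score
compares global output maxima of two runs with identical parameters and
total on-time. Degenerate cases are explicit: a zero reference peak
raises an error, a zero final peak yields −inf with a flag — never a
silent sentinel.

## Impulsive approximation layer

When Δτ_on ≪ Δτ_off and the memory stays far from saturation
(I ≪ α/γ), each pulse acts as an instantaneous memory increment
w = αΔτ_on followed by exponential decay. The `theory` module implements
this delta-train model and its consequences: the per-cycle increment
ΔI = (I₀ + w)e^(−γΔτ_off) − I₀, the critical relaxation gap
γ⁻¹log(1 + w/I₀) where ΔI changes sign, and the periodic envelope
w·e^(−γτ)/(1 − e^(−γΔτ)) reached in the many-pulse limit. At the
canonical habituation operating point with an on/off ratio of 0.1 the
delta-train memory tracks the integrated circuit to within 0.5% at pulse
onsets; the test suite asserts 5% to leave headroom across regimes.

The massed–spaced analysis uses a further simplification: input pulses
saturate the receptor and output is produced in an all-or-nothing fashion
while the memory A exceeds a normalized threshold of 1 (unit step with
H(0) = 1; the threshold is fixed, not a parameter). Post-pulse memory
levels, production windows, and the output trajectory then have closed
forms, including peak outputs for one massed pulse,
(β/γ)(1 − 1/(αΔτ_on)), and for the budget split in two,
(β/γ)(1 − 2e^(−γΔτ_off)/(αΔτ_on(1 + e^(−γΔτ_off)))). The two-pulse
formula assumes each half-budget pulse sustains production across the
full gap (log(αΔτ_on/N) ≥ γΔτ_off); outside that region the function
refuses with an error rather than extrapolating a formula whose
derivation no longer holds. Within it, any split into N ≥ 2 spaced pulses
yields at least the massed peak — checked numerically for N up to 6 in
the test suite rather than proven algebraically.

Two indexing conventions coexist deliberately: the delta-train memory
places pulse k at t = kΔτ (k = 1..N, first pulse after one period),
while the step-gated massed–spaced model places pulse k at t = kΔτ_off
(k = 0..N−1, first pulse at t = 0). Each matches the construction it
approximates; the approximation Δτ ≈ Δτ_off is confined to this module
and never enters the exact simulator.

## Parameter-space sweeps

`sweep_fc` simulates every cell of a 2-D parameter grid from rest and
scores it; default grids are α ∈ [0.1, 10] and γ ∈ [1e-4, 1], log-spaced,
41×41 (a reconstruction of sensible ranges, not canonical values), and
cells with an undefined fold change are serialized as nulls with a reason
code. `sweep_msl` sweeps pulse count and inter-pulse delay against a
single shared massed reference; all runs in one sweep share a common
step and sample resolution (set by the narrowest pulse) so peak
comparisons carry no sampling bias, and the N = 1 row is identically
zero. `threshold_mask` turns a grid into a boolean learning/non-learning
phase map, with the comparison direction set by the metric (≤ for
habituation-like scores, ≥ otherwise).

## What the tests do and do not show

The test suite pins: exact algebraic identities (transfer-function
values, fold-change arithmetic, closed-form peaks), equivalences between
closed forms and independent reference integrations (to 1e-6), solver
convergence and analytic-subsystem oracles (1e-6/1e-8), and the
qualitative learning regimes of the canonical fixtures. Problem sizes are
kept modest — 10–20 pulse trains, sweep grids of a few cells, 40–100
randomized protocols per property — which is ample for these smooth ODE
systems. Passing tests certify the mathematics of the models, not
biology: the models omit stochastic gene expression, promoter leak,
resource competition, growth-rate coupling beyond the lumped dilution
rates, and receptor-binding dynamics, so quantitative agreement with a
wet-lab realization is not implied.

## Known limitations

* Fixed-step RK4 is not suited to genuinely stiff parameter regimes
  (rates differing by many orders beyond the λ/γ separation); the step
  bound, not an error estimator, controls accuracy.
* Peak values are sample maxima; with the default sampling of ten points
  per pulse width the induced error is negligible for the smooth outputs
  here, but sharply resonant outputs would warrant finer sampling.
* The closed-form massed–spaced layer is valid only under its stated
  assumptions (saturating pulses, step-gated output, Δτ ≈ Δτ_off); it is
  an analysis tool, not a substitute for the full simulation.
* Fold changes compare peaks only; richer habituation criteria
  (spontaneous recovery, dishabituation) are out of scope.
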