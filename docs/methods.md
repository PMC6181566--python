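# Methods

## Model and assumptions

The package implements a mass-action model of N synapses competing for
neurotransmitter receptors from a shared dendritic pool. Each synapse i has
s_i receptor slots, w_i of which are occupied (w_i ≤ s_i); p receptors
diffuse freely in the pool. Binding (rate α per receptor per empty slot),
unbinding (β per bound receptor), externalization (γ receptors/min) and
internalization (δ per pooled receptor) give the coupled ODEs

    dw_i/dt = −β w_i + α p (s_i − w_i)
    dp/dt   = −δ p + γ + Σ β w_i − Σ α p (s_i − w_i).

Assumptions worth keeping in mind:

* **Well-mixed pool.** All synapses see the same pool concentration; there
  is no spatial structure along the dendrite. Multiplicative scaling is a
  direct consequence of this homogeneity and would weaken if receptor
  density varied along the branch.
* **Separation of timescales.** Slot exchange (1/β ≈ 43 s at default
  parameters) is fast against surface turnover (1/δ ≈ 14 min). The analytic
  fast equilibrium and the reduced R-dynamics both lean on this; the full
  ODE integrator does not and is used to validate them.
* **Real-valued states in the deterministic model.** Slot counts,
  occupancies and the pool are treated as continuous; the Gillespie module
  is the integer-valued counterpart.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| β | unbinding from slots | 60/43 ≈ 1.395 | min⁻¹ |
| δ | internalization | 1/14 ≈ 0.0714 | min⁻¹ |
| φ | relative pool size p∞/W∞ | 2.67 | — |
| F | target filling fraction | one of 0.5 / 0.7 / 0.9 | — |
| α | binding to slots | β/(φS(1−F)) (calibrated) | min⁻¹ |
| γ | externalization | δφFS (calibrated) | min⁻¹ |

β and δ derive from measured dwell times (PSD residence ≈ 30 s half-life,
surface residence ≈ 10 min half-life; mean lifetime = half-life/ln 2). φ
reflects the measured ~72%/28% split of surface receptors between the
extrasynaptic membrane and synapses in mature hippocampal cultures. F is
not known experimentally and is explored over {0.5, 0.7, 0.9}. The
canonical time unit is the minute throughout; constructors accept
`(value, unit)` conversions via `params.per_minute`/`params.minutes`.
An alternative calibration holds α fixed (0.0093 min⁻¹, the value giving
F = 0.7 at φ = 2.67 with S = 188) and sets γ = δ(Sφ − β/α) to reach a pool
target; the filling fraction then co-varies as F = 1 − β/(αφS).

## Numerical choices

* **Quadratic root.** The fast equilibrium W\* is the '−' root of
  W² − W(S+R+ρ) + RS = 0. It is evaluated as 2RS/(b + √(b²−4RS)) with
  b = S+R+ρ, which is exact algebra but avoids the catastrophic
  cancellation of the textbook form near R = S, ρ → 0 — precisely the
  region where the sensitivity analysis matters. The '+' root exceeds
  min(S, R) and is exposed only for verification.
* **Sensitivity at the singular point.** dF\*/dρ at ρ = 0 equals
  (1/2S)(1 − (R+S)/|R−S|); the absolute value makes the slope negative on
  both sides of R = S. At R = S, ρ = 0 the derivative diverges and the
  function returns `-inf` explicitly rather than raising or silently
  overflowing.
* **Integrator.** Forward Euler is the reference integrator, with default
  dt = 0.005 min (0.3 s) — at least ~10× below the fastest relaxation time
  1/(β+αp) under default parameters — and sampling every 0.05 min. A
  dt-ladder test confirms first-order convergence. Steps that overshoot the
  bounds 0 ≤ w_i ≤ s_i or p ≥ 0 by more than a 10⁻⁶ relative tolerance
  raise an error advising a smaller dt; smaller excursions are clipped.
* **Events and waveforms.** Instantaneous perturbations are applied
  atomically at the nearest step of the time grid. Slot-shrinking events or
  waveforms that would strand receptors (w_i > s_i) return the excess to
  the pool, conserving receptor number; the published protocols never
  shrink slots below occupancy, so this is an extension convention.
* **Reduced dynamics.** dR/dt = γ + δF\*(R)S − δR is integrated with Euler
  (dt = 0.01 min default) using the stable root; R crosses S during
  accumulation runs, the worst-conditioned region for the naive formula.

## Stochastic simulation

The integer model is simulated with the direct Gillespie method over the
2N+2 channels (bind/unbind per synapse, externalize, internalize).
Conventions:

* runs start at the rounded deterministic fixed point (w_i = round(F s_i),
  p = round(γ/δ)) and a 2 min burn-in is discarded before statistics — the
  reference results concern steady-state fluctuations and the original
  initialization is not otherwise constrained;
* states are sampled on a fixed 1 s grid by carrying the piecewise-constant
  state forward, which is unbiased for time averages and much finer than
  needed relative to the ~0.4 min relaxation time (the sampling interval
  for the published CV analysis is not stated; 1 s is this package's
  declared convention);
* one named NumPy generator per run, seeded explicitly; identical seeds
  give bit-identical runs. Experiment-level seeding uses
  `SeedSequence.spawn`, so a single integer reproduces a whole experiment.
* ensemble means are validated against the Euler ODE solution via
  z-scores of the run-averaged trajectories (`validate_against_ode`).

## Fluctuation analysis

Per-synapse CVs (100·sd/mean of the sampled w_i, post burn-in) are averaged
across runs per synapse and then fit as CV = a(Fs)^b by **unweighted** OLS
on (log₁₀ Fs, log₁₀ CV) — a linear fit in double-log space with no
weighting, matching the stated aggregation (averages over 10 simulations
before fitting). Synapses with zero mean occupancy are flagged NaN and
excluded; at the default configurations every synapse has positive mean
(the smallest is the 1-slot synapse at F = 0.5, mean 0.5). The
independent-slot binomial oracle CV = 100·√((1−F)/(F s)) anchors the
expected scale (a → 100√(1−F)) and exponent (−½) in the large-pool limit.

## Plasticity protocols

* **Pool step** (3 synapses, 40/60/80 slots, F = 0.9, φ = 2.67): pool
  doubled or zeroed at t = 2 min. All relative changes coincide across
  synapses (multiplicative scaling); the peak matches the analytic fast
  equilibrium at the stepped R, then decays back with timescale ~1/δ.
* **Slot step** (4 synapses, 20/40/60/80 slots, F = 0.5, φ = 2.67): slots
  of synapses 1 and 3 doubled at t = 2 min. The analytic peak
  heterosynaptic change is (F\*−F)/F with F\* evaluated at the enlarged
  slot total and unchanged R; for the default setup this is −6.2%. The ODE
  trough is slightly shallower (−5.6%) because the fast redistribution
  (τ ≈ 0.4 min) competes with the already-starting slow recovery — the
  analytic value is an instantaneous-redistribution idealization.
* **LTP waveforms**: stimulated synapses' α ramps linearly 1×→4× over 17 s
  and back over 2 min (CaMKII activation time course); spine volume rises
  sigmoidally 1×→5× over 2 min and decays exponentially (τ = 5 min) to a
  sustained 2×; slot counts scale as volume^(2/3) (surface-area scaling).
  The "sigmoidal" rise is implemented as a logistic with midpoint at half
  the rise window and steepness spanning 1%–99% of the amplitude across
  the window, then pinned so the endpoints (1× and 5×) are met exactly —
  the shape is named in the source literature but not its formula, and
  pinning keeps the waveform continuous with an exact 5^(2/3) peak slot
  factor. The α ramp and the volume rise start simultaneously at the
  onset (t = 2 min); the per-synapse slot counts for the LTP figure are
  not published, so the slot-step configuration (20/40/60/80, synapses 2
  and 3 stimulated) is reused as the closest in-package convention.

## Synthetic slot distributions

`lognormal_slot_sampler` draws s_i from a lognormal with mean 1.0 and
standard deviation 0.2 **of the variate itself** (underlying normal
parameters solved from these), then rescales to exactly 100 slots per
synapse on average. This emulates the heavy-tailed spread of synaptic
weights used to illustrate multiplicative scaling. It does not emulate
spatial correlations between neighboring synapses, slot-count dynamics, or
discreteness (analytic operations accept non-integer slots); conclusions
from these fixtures concern the scaling behavior, not the biological
weight distribution per se.

## Problem sizes

The test suite and acceptance script run entirely at desk scale: ODE runs
of 10²–10⁴ steps, and the CV experiment at its published size (two filling
fractions × 10 Gillespie runs × 30 simulated minutes ≈ 3·10⁵ reaction
events), a few seconds end to end. The receptor-accumulation example uses
S = 10⁴ slots as published.

## Known limitations

* The reduced R-dynamics needs ≈ 3 h of simulated time to come within ±1
  receptor of R∞ from distant initial conditions (relaxation constant
  ≈ 14.5 min including the quasi-steady correction δ(1−dW\*/dR)); over 2 h
  residuals of several receptors in ~33 000 remain.
* No spatial diffusion, receptor subtypes, slot production/degradation
  kinetics, or homeostatic control of the rates; rates are constant except
  where a protocol drives them.
* Stability of the fixed points is assumed (and observed numerically), not
  proven; no Jacobian/eigenvalue analysis is provided.
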