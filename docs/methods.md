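# Methods

This note records the scientific and numerical choices behind `levotap`:
the model equations and their assumptions, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Kinetic model

Amounts `(depot, A1, A2)` evolve linearly: first-order oral absorption
(`ka`), a central compartment (plasma, `V1`) and a peripheral compartment
(`V2`), with transfer and elimination written in the clearance convention
(`k12`, `k21`, `ketot` in l/min; flux = clearance × source concentration).
Only the three clearances are estimated; `V1 = V2 = 30 l` and
`ka = 0.035 min⁻¹` are fixed prototypical values chosen so that a 100 mg
oral dose peaks near 1–1.5 mg/l at 30–50 min and decays with a terminal
half-life of roughly 40–100 min over the plausible clearance range — the
shape of the clinical single-dose LD test.  Benserazide, food effects and
repeated dosing are out of scope.

Two solvers: `simulate_plasma` integrates with LSODA (rtol 1e-8,
atol 1e-10) and optionally returns the full state so mass conservation can
be checked; `plasma_closed_form` diagonalizes the 3×3 rate matrix and
evaluates the exact tri-exponential.  The two agree to 1e-6 relative and
cross-check each other; fits use the closed form because it is exact and
two orders of magnitude cheaper.

## Effect site, delay, and Hill law

The effect compartment is the classical unit-gain link model
`c3' = ke3 (c1 − c3)`, `c3(0) = 0` after overnight washout.  No mass is
withdrawn from plasma; any true plasma-to-brain gain is absorbed into the
fitted `Dc50`, so the effect-site volume drops out of the model entirely.
A consequence worth noting: when `ke3` exceeds the terminal plasma decay
rate the effect site simply tracks plasma, and when it is slower it acts
as a reservoir that outlives the plasma transient — this is what separates
sustained from fluctuating responders below.

Integration uses an exact exponential update on a 1-minute internal grid
for piecewise-linear input (an IIR filter; series expansion of the
coefficients below `ke3·h < 1e-4`, where the direct expression cancels
catastrophically).  The pure delay is linear interpolation of that dense
grid, zero before the delayed signal exists.  The Hill law is evaluated as
a logistic in log-concentration, immune to overflow at extreme Hill
coefficients.

## Network model and its calibration

Each of two action channels chains sensory cortex, motor cortex, striatal
Go and NoGo, GPe, GPi/SNr and thalamus; one cholinergic unit is shared.
Units are first-order filters (τ = 10 ms) of a logistic `σ(a(u−u0))` with
a = 4, u0 = 0.5, so activities live in (0, 1).  Design choices where the
architecture was genuinely open:

- the dopaminergic input excites only the *winning* channel's Go unit,
  implemented by scaling the Go excitation with the channel's share of
  motor-cortex activity;
- the cholinergic unit is tonically active, suppressed by dopamine, and
  excites all NoGo units, so rising dopamine disinhibits action twice
  (directly and through acetylcholine);
- the tapping protocol registers a tap when the *cued* channel's motor
  unit crosses the threshold (0.84 of saturation), keeps the stimulus on
  for the 90 ms inter-movement lag, then switches the cue; a 2 s timeout
  charges failed selections.  Frequency is 60000 over the mean inter-tap
  interval with the first two cycles discarded.

The quantitative gains were calibrated by derivative-free search against
five anchors: (i) the steady-state curve is monotone on D ∈ [0, 5];
(ii) its plateau exceeds 220 taps/min; (iii) with the legacy timing
(τ = 15 ms, lag = 115 ms) the plateau sits within 10% of 180 taps/min;
(iv) the zero-dopamine floor stays below 100 taps/min; and (v) the rise is
spread over D ≈ 0.25–3 so that clinically plausible basal tones land on a
graded part of the curve.  Two dynamical facts shaped the result.  First,
selection latency is governed by a near-critical thalamo-cortical loop:
only weak dopamine path gains (small `alpha_go`, `beta_nogo`, `k_ch_d`)
spread the latency ramp over a wide dopamine range instead of producing an
all-or-nothing cliff.  Second, the baseline frequency is *U-shaped* in the
Go weights — below ≈0.9 a stronger Go synapse mainly prolongs the previous
channel's self-sustained activity and slows the alternation — so the
plastic weights are initialized at 0.9 and operate on the rising branch
[0.9, 1.5], where more skill means faster tapping.  The calibration is a
fixed point: the default synapses are themselves produced by the trained
preset (below), so gains and presets were iterated to convergence, and
`calibrate_network`/`check_calibration` can re-derive and re-verify the
shipped configuration.

The estimator never runs the millisecond network inside the fit: the
steady-state dose–response curve (26 nodes on D ∈ [0, 5]) is precomputed
once per synapse set and interpolated with a monotone cubic (PCHIP).  The
smooth interpolant matters: a piecewise-linear curve seeds the cost
surface with kink-induced local minima that measurably bias recovery.
Quasi-static coupling is justified by the timescale gap (minutes vs tens
of milliseconds).

## Plasticity

The update is threshold-Hebb, `Δw = γ·pre·(post − θ)` with the
motor-cortex activity as `pre`, the striatal unit as `post`, and θ = 0.35
chosen inside the dopamine-modulated window of the calibrated striatal
activities (Go tops out near 0.85, the NoGo dip response near 0.6; the
textbook θ = 0.5 would sit above the whole Go range and collapse the
weights).  Credit goes to the performed action: a reward updates the
chosen channel's Go synapse, a punishment the chosen (or, on timeout, the
cued) channel's NoGo synapse.  Rewards transiently multiply the current
dopaminergic input by 2 for 300 ms and their learning rate scales with the
burst size (γ·D_phasic/3), expressing that phasic bursts *enhance* Go
plasticity — rewards earned at a low drug level barely teach.  Punishments
null the input for 300 ms; the dip always disinhibits NoGo fully, so their
rate is fixed (γ_NoGo = 0.16).  Stimulus noise (SD 0.8) makes a naive
network err on roughly a third of the epochs.

Skill presets (60/80/100/150/200 epochs) train a naive weight set under a
gentler standard protocol (noise 0.45, γ = 0.002, γ_NoGo = 0.02, fixed
seed) at a healthy dopaminergic tone of 1.5.  The gentle rates keep all
presets within the calibrated operating neighbourhood: their tapping rate
at fixed dopamine increases strictly with the training depth, while their
dose–response curves stay close enough that re-matching the basal tone
`D0` reproduces a fitted trajectory within a few percent — the basis of
the skill-robustness analysis.  The level-100 preset is the shipped
"moderate-skill PD" default.

## Estimation

Stage 1 minimizes the plasma SSE with Nelder–Mead from the single guess
(1.5, 1.5, 3) l/min, in log-coordinates (positivity by construction;
xatol = fatol = 1e-8, ≤2000 iterations).

Stage 2 minimizes the weighted tapping cost (SSE + 10·max abs error) over
`(log ke3, √T, log D0, log Dmax, log Dc50, log ND)`.  Ten restarts draw
five parameters log-uniformly (ke3 ∈ [0.002, 0.2] min⁻¹,
Dmax ∈ [0.2, 5], Dc50 ∈ [0.1, 3] mg/l, ND ∈ [1, 15]; T uniform on
[0, 60] min); `D0` always starts at the inverse-curve image of the
pre-dose tapping rate.

The cost surface has two unpleasant features, and the fitter addresses
both explicitly.  It is *multimodal* — restarts are refined by seeded
basin hops (perturbation scales cycling 0.2–2.0), optional warm-started
profile continuations along the two nearly flat ridges (ke3 against the
delay; Dc50 against Dmax), and deterministic coordinate walks.  And it is
*non-smooth*: the max-abs term creases the surface along every
active-residual switch, producing steep V-shaped valleys on which both
simplex and line-search methods stall far from the optimum.  The fitter
therefore interleaves descents on the smooth pure-SSE companion surface,
accepting each candidate only if it improves the full cost.  On
noise-free synthetic patients this recovers all six parameters to machine
precision; every stage is seeded and deterministic.  `n_hops`,
`axis_rounds` and `ke3_profile` trade depth for speed (the cohort
pipeline uses light settings, recovery studies the full recipe).

Identifiability limits worth knowing: when the response saturates the
Hill law, `Dmax` and `Dc50` are constrained mainly through their ratio;
for very steep responses `ND` is identified one-sidedly (any sufficiently
large value fits); for fast-washout patients `ke3` trades against `T`.
Group-level conclusions (below) are robust to all three.

## Synthetic cohorts

The generator emulates the clinical single-dose protocol: 100 mg oral LD,
plasma sampled pre-dose, every 15 min to 90 min, then half-hourly to
3 h (10 samples); tapping on the same grid extended to 210 and 240 min
(12 samples).  Observation noise is multiplicative on plasma (CV 8%) and
additive on tapping (SD 7 taps/min), clipped at zero.

Archetype parameter intervals (log-uniform draws) were set so that the
*noisy* generator reproduces its own clinical definitions — onset =
+15% over the pre-dose baseline, fluctuating = return below that level
within the 4-h window — in ≥90% of draws per group:

| parameter | shared | stable | fluctuating |
|---|---|---|---|
| k12, k21 (l/min) | 0.3–0.8, 0.3–1.0 | | |
| ketot (l/min) | 0.4–0.7 | | |
| T (min) | 5–30 | | |
| D0 | 0.3–0.8 | | |
| Dmax | 1.0–2.0 | | |
| ke3 (min⁻¹) | | 0.004–0.01 | 0.05–0.15 |
| Dc50 (mg/l) | | 0.3–0.6 | 0.55–1.0 |
| ND | | 1.5–4 | 6–12 |

The mechanistic split mirrors the two-parameter story the estimation is
meant to uncover: stable responders hold drug in a slow effect-site
reservoir (`ke3` below the plasma decay rate) and respond gradually
(low `ND`); fluctuating responders track the plasma tail and shut off
sharply once it falls below their half-effect concentration (`ke3` and
`ND` high, `Dc50` above the 4-h plasma tail).  Baselines come out at
~110–150 taps/min and peaks up to ~230, with onset near 30 min and
wearing-off near 140 min.

What the generator does **not** emulate: demographic covariates,
inter-day variability, dyskinesia, outliers/missing samples, and any
correlation structure between parameters.  Passing recovery and cohort
tests on these cohorts therefore demonstrates that the estimation
machinery works when the model is true and the noise is as assumed — not
that the model fits any particular clinical data set.

## Problem sizes used by the test suite

The shipped tests run the recovery study on 5 noise-free patients
(10 restarts, 80 hops), the cohort comparison on four 13 + 13 cohorts
with fast fit settings (median tapping R² ≈ 0.97), the training-timing
experiment on 20 seeded sessions per time point, and the skill-robustness
analysis on one patient per archetype across all five presets.  These
sizes were chosen as the smallest that exercise each claim convincingly;
all of them scale up by changing one argument.

## Known limitations

- The hyperdirect/STN pathway, spiking dynamics, more than two action
  channels and kinematic finger mechanics are not modelled.
- All network parameters except the plastic cortico-striatal weights are
  population-level constants; differences between patients are expressed
  purely through the nine kinetic/dynamic parameters.
- The reward/punishment asymmetry is partly architectural (the
  moderate-skill Go weights sit near their ceiling, so rewards saturate);
  the dopamine-scaled reward learning rate encodes the burst-size
  dependence explicitly rather than emerging from striatal activity.
- The calibration operates the selection loop near criticality to obtain
  clinically slow latencies from 10 ms units; curve floors are therefore
  sensitive to synaptic weights, which is why the skill presets span a
  deliberately narrow weight range.
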