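# Methods

## Model

The package models the core transcription-factor circuit of the
erythroid/myeloid lineage decision: GATA-1, GATA-2 and PU.1, each
autoregulating positively, with GATA-2 activating GATA-1 and repressing
PU.1, and GATA-1/PU.1 mutually antagonistic. Transcription rates are
Shea–Ackers occupancy ratios (rational functions of the state whose
denominator terms correspond to promoter configurations), basal
expression is zero, and degradation is first order. Time is in hours
throughout: the degradation rates come from measured protein half-lives
via `k = ln 2 / t½` (GATA-1: 1 h → 0.6931/h, GATA-2: 0.5 h → 1.3863/h,
PU.1: 2.4 h → 0.2888/h), and all window times are read in the same unit.

The GATA switch — GATA-1 displacing GATA-2 from shared chromatin
sites — is modelled as a transient extra GATA-2 degradation rate
`k2*(t)`, equal to a constant on a closed window `[t_on, t_off]` and zero
outside, with a coupled GATA-1 source term `μ k2* y`. The availability
factor `μ` is the package's central control parameter: `μ = 0` encodes a
GATA-2 knockdown with GATA-1 absent, `μ ≈ 1` a full GATA switch. Three
window presets ship with the package: `deterministic` (k2\* = 6 on
[500, 1500] h), `validation` (k2\* = 20, same window) and `stochastic`
(k2\* = 25 on [50, 200] h).

Zero basal expression makes each coordinate plane invariant: a gene at
exactly zero stays at zero. This matters in three places below (the
knockdown schedule, perturbation validation of on-axis states, and
extinction in the stochastic model).

## Steady states and stability

The origin and the two committed states have closed forms; their
stability reduces to seven strict inequalities on the rate constants
(three for instability of the origin, two pairs of non-invadability
conditions for the committed states). These are implemented as signed
margins (`stability_margins`) and cross-checked in the test suite against
a Jacobian-eigenvalue oracle on random unconstrained parameter sets; the
Jacobian is analytic. A margin band of 1e−9 excludes boundary cases
where a strict inequality and a numerically computed eigenvalue sign can
legitimately disagree. Closed-form coordinates that fall below zero
(synthesis under the degradation threshold) are reported as
non-physical, not raised as errors, so bifurcation scans can cross
existence boundaries.

The interior (primed) state has no closed form. `find_primed_state` runs
a hybrid-Powell root finder from random initial guesses drawn
log-uniformly between 1e−2 and the largest attractor coordinate,
deduplicates roots at 1e−6 relative distance, keeps only strictly
positive roots, and returns the most interior one (largest minimum
coordinate), preferring stable roots and stopping early when a stable
one is found. The early stop matters because the reference set also has
a spurious near-axis saddle at (5e−4, 4e−3, 241) that a naive "first
positive root" rule would sometimes return. Absence of a primed root is
a value (`None`), not an error, because the staged penalty needs it as a
signal.

## ODE integration

`simulate_ode` splits the time span at the window boundaries so the
`k2*` discontinuity always falls on a segment edge. Each segment is
solved with the analytic Jacobian through a fallback chain — LSODA,
then BDF, then Radau — with each attempt bounded by a budget of 1e5
right-hand-side evaluations. The chain exists because LSODA is fastest
on typical segments but can stall without erroring when GATA-2 collapses
to a boundary layer inside the window for extreme parameter sets (the GA
generates such sets routinely); the implicit methods with the analytic
Jacobian handle those. Default tolerances are rtol 1e−8 / atol 1e−10;
the switching and validation stages of the GA use rtol 1e−6 / atol 1e−8
since they only classify endpoints. Recorded states are clipped at zero
(the flow preserves the positive octant; excursions are round-off).
Endpoint classification uses relative Euclidean distance with the
reference norm floored at 1, so distance to the origin is well defined.

Perturbation-return validation multiplies each coordinate by
`1 + strength·u`, `u ~ U(−1, 1)`, relaxes for 200 h and requires return
to within 1e−3 relative distance. Coordinates that are exactly zero get
an absolute kick `strength·|u|·0.01` instead: a multiplicative
perturbation of zero is no perturbation, and the unstable origin must be
able to fail the check. The 0.01 concentration-unit scale was chosen
below the measured width of the committed states' off-axis basin (for
the reference set, simultaneous GATA-1/GATA-2 kicks of ≈2–5e−3 units
already escape the myeloid basin — a genuinely thin basin that the
stochastic model also probes) and far above nothing, so that linear
stability, not basin geometry, decides the outcome.

## Deterministic switching scenarios

The three reference scenarios start at the primed state: a GATA switch
(μ = 1, k2\* = 6 on [500, 1500]) commits to the erythroid attractor; a
GATA-2 knockdown (μ = 0) commits to the myeloid attractor; intermediate
availability (μ = 0.32, k2\* = 6) fails to switch and returns to the
primed state when the window closes. The knockdown scenario runs under
the stronger `validation` window (k2\* = 20): at k2\* = 6 with μ = 0 the
in-window system has a stable fixed point at (3.40, 1.82, 4.38) —
GATA-2 is reduced but not eliminated, PU.1 never takes over, and the
trajectory returns to the primed state regardless of window length, so
myeloid commitment under the weak window is dynamically impossible for
this parameter set. All three scenarios reproduce their attractors to
better than 1% relative distance, and halving the integration tolerances
changes no endpoint classification.

## Parameter inference

Thirteen rate constants are fixed before inference: the normalization
`a3 = b2 = c2 = 1`, the data-anchored binding terms (a4 = 1.6,
b4 = 942.1939, c5 = 170), the shared-binding-site equalities `b6 = a7`
(= 53) and `c7 = c6` (= 1700), and the three degradation rates. The ten
free constants (a1, a2, a5, a6, b1, b3, b5, c1, c3, c4) are encoded as a
unit-cube genome. The mapping enforces every stability inequality by
construction: synthesis rates are `(threshold / r) · k` with slack
`r ∈ (0,1)` and scale `k = 1000`, and the invasion coefficients solve
their inequality with slack `1/r`. The direct-sample parameters a2, a5
and c4 are scaled by `k` as well: the published estimate pins all three
at order `k` (856, 399, 522), and an unscaled variant was verified to
make the feasible (switching) region practically unreachable — in 300
random genomes none reached the robustness stage, versus 14% reaching
the switching stage with the scaling.

Candidates are scored by the staged penalty; all stages run at desk
scale: primed search with 30 restarts, validation with 3 perturbation
trials per state, switching under the `validation` window with a 1%
endpoint tolerance, and a robustness stage of `n` σ = 0.5 perturbed sets
sharing one `U_jk` sample matrix across candidates so scores are
comparable. A set whose trajectories cannot be integrated even by the
fallback chain fails the stage that needed the integration — an
unintegrable candidate is a worthless candidate, and this keeps the GA
total-time bounded.

The GA itself is a standard real-coded minimizer operating purely in
genome space (mutation never touches mapped rate constants): tournament
selection of size 3, uniform crossover with probability 0.8, Gaussian
mutation with sd 0.1 clipped to (1e−6, 1 − 1e−6), elitism of 1, and a
per-genome evaluation cache. The desk-scale defaults are population 50,
10 generations and 50 robustness sets (a run takes ~15 s and reliably
reaches penalty < 2, usually < 0.2); the study-scale configuration is
population 1000, 100 generations, 1000 robustness sets. Ten genome
slots cover the ten free constants; one published accounting lists
eleven unknowns, but the constraint bookkeeping yields ten, and the
genome follows the bookkeeping.

## Robustness and bifurcation

Robustness perturbs all 23 constants multiplicatively,
`a_jk = a_j (1 + σ (U_jk − 0.5))`, `U ~ U(0,1)` (non-negative for
σ ≤ 2), and reports the fraction of sets that keep tristability,
operationalized as: both closed-form committed states physical and
stable by the inequalities, plus a strictly positive, eigenvalue-stable
primed root. The primed search under perturbation warm-starts from the
unperturbed primed state and falls back to 20 random restarts. With a
shared sample matrix the fraction is a deterministic function of the
parameters. For the reference set the retention fraction is ≈0.5–0.6 at
σ = 0.5 (n = 100) and consistent within ≈0.1 for σ between 0.4 and 1,
matching the σ-independence property of the inference design; at n = 100
the binomial noise alone is ±0.05 per fraction, so the 0.1 band is about
two standard errors.

Bifurcation scans re-evaluate the same tristability predicate on a
41-point grid from 0 to twice the estimate of one constant. The scans
reproduce the expected asymmetry: tristability survives raising GATA-1
or PU.1 synthesis (a1 to ≥2×, c1 up to 2×) or lowering GATA-2 synthesis
(b1 down to ≈0.2×), but is lost in the opposite directions, with a sharp
b1 threshold; it is insensitive to the GATA-2→GATA-1 rate a2 at every
positive grid value. At a2 = 0 exactly, the x = 0 plane is invariant and
no interior state exists — a structural boundary case of the zero-basal
assumption, not a robustness failure.

## Stochastic model

The tau-leap simulator draws independent Poisson counts for seven
channels per step of length τ: three synthesis channels (the occupancy
ratios evaluated on concentrations `counts/ω`, multiplied back by ω),
three degradation channels — GATA-2's carries the combined mean
`(k2 + k2*(t)) Y τ` during the window — and the GATA-switch transfer
`μ k2* Y τ` into GATA-1. Counts are clamped at zero after each leap;
independent Poisson draws can overshoot the available molecules, and
clamping (rather than redrawing) keeps the update in the stated
independent-channel form. Clamp events are counted and are below 0.1%
of channel updates for the reference set at the default τ.

Defaults: τ = 0.01 h (the ensemble-mean trajectory at ω = 100 tracks
the ODE within ~1% time-averaged relative deviation, and halving τ moves
lineage fractions by less than binomial noise), read-out 300 h after the
window closes (the ensemble has visibly settled well before that), and
initial condition the deterministic primed state scaled by ω and
rounded.

The copy-number scale ω defaults to **1000 molecules per concentration
unit**. The choice is constrained from two sides. At ω = 1 the primed
state holds 4/13/1 molecules; with zero basal synthesis, zero is
absorbing per gene, PU.1 goes extinct almost surely and every run drifts
to the erythroid axis — no multimodality is possible. At very large ω
the ensemble collapses onto the deterministic outcome and the mixed
window disappears. Around ω = 10³ (which is also the right order for
nuclear concentrations read as nM: 1 nM in a ~1.7 pL nucleus is ≈10³
molecules) the model reproduces the full commitment-window structure:
μ ≤ 0.05 all-myeloid, μ ≈ 0.17 all-primed, μ = 0.28 split across all
three lineages, μ = 1.5 ≈97% erythroid. The deterministic μ thresholds
(myeloid below ≈0.11, primed 0.12–0.28, erythroid above ≈0.32) bracket
the stochastic mixing windows; the commitment decision happens inside
the switch window, where the deciding species pass through near-zero
copy numbers even at large ω.

Ensembles are stepped in lock-step (vectorized across runs) from one
dedicated RNG stream per ensemble, so a μ-sweep is reproducible from its
seed and independent of sweep order; single trajectories use a substream
derived from (seed, run_index) so any individual run can be reproduced
in isolation. Endpoints are classified by nearest attractor in
Euclidean distance on `log1p` coordinates (relative across the orders of
magnitude separating the lineages), with a deterministic
erythroid > myeloid > primed tie-break; classifications are stable under
±5% endpoint jitter.

## What the synthetic conditions do and do not show

All tests run on the packaged reference estimate and on parameter sets
generated by the constrained sampler — there is no external data. The
study conditions (window presets, σ = 0.5, k = 1000, 200-run sweeps)
are fixed by the inference design, not tuned per test. Passing tests
therefore demonstrate internal consistency of the model, the inference
machinery and the simulators under these conditions; they do not
validate the biological parameter values themselves, the nM reading of
the concentration unit, or the model's simplifications (no mRNA stage,
no basal expression, no extrinsic noise, deterministic window timing).
Problem sizes in the test suite are desk-scale by design: 1000-set
sampler and oracle checks, 100-set robustness ensembles, 200-run
lineage sweeps, and the 50 × 10 GA; the study-scale GA (1000 × 100 ×
1000) is exposed through `GAConfig` but not exercised by the suite.

## Known limitations

- The staged penalty is piecewise-flat (4/3/2), so the GA's progress
  through the early stages is selection-driven random search; it works
  because the constrained sampler already lands ~10% of genomes at the
  switching stage, but a shaped penalty would converge faster.
- `find_primed_state` is a multi-start local method; it cannot prove
  absence of an interior root, and the robustness predicate inherits
  this (warm-starting keeps false negatives rare in practice).
- The independent-Poisson leap is first-order in τ and requires the
  clamp; an exact SSA cross-check is not included.
- The μ-window boundaries depend on ω and τ; only the window structure,
  not exact boundary values, is asserted.
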