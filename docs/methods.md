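# Methods

## 1. The paired-panel statistics

The unit of analysis is a paired pre/post panel: `n` athletes × `k`
markers, two measurements each.  Per marker the pipeline is

1. **Normality gate.** Shapiro–Wilk on the paired differences at
   α = 0.05.  The gate is applied to the differences, not to pre and
   post separately, because the paired tests operate on differences.  A
   constant difference vector is classified non-normal with a warning
   (W is undefined there).
2. **Test.** Paired *t* (df = n − 1) if the gate passes, otherwise the
   Wilcoxon signed-rank test.  Zero differences are dropped (classic
   Wilcoxon; a flag switches to the Pratt treatment).  For n ≤ 25 after
   zero removal the two-sided p is exact under the sign-flip null,
   computed by a dynamic program over doubled midranks — exactly
   equivalent to enumerating all 2^n sign assignments, including tied
   magnitudes — which covers the study-sized n = 22 with an exact null.
   Larger n uses the tie- and continuity-corrected normal
   approximation.  The reported statistic is min(W+, W−) and the
   two-sided p is 2·min(P(W+ ≤ w), P(W+ ≥ w)) capped at 1.
3. **Multiplicity.** Benjamini–Hochberg step-up q-values across the
   *secondary* markers only; the a-priori primary outcome (the CD4/CD8
   ratio in the motivating design) is excluded from the family and
   keeps q = p.  The family size k defaults to the number of secondary
   markers actually analyzed and is never hard-coded; it may be set
   larger than the p-vector when the nominal family includes tests not
   present.
4. **Effect size.** Cohen's d_av = mean change divided by the average
   of the two time-point SDs.  The public value uses the summary-table
   sign convention (pre − post, so a decline is positive); a companion
   accessor returns the change-signed value.  Magnitude bands are
   left-closed: |d| = 0.2 is "small", 2.0 is "very large".

**Design formula.** N ≈ ((z_{α/2} + z_β)/d)² + 3.  At d = 0.8,
α = 0.05, power 0.80 this gives 15.26 → 16 participants.  A published
value of "≈19" for these inputs corresponds to d ≈ 0.7 with the
two-decimal quantiles (1.96, 0.84); the function accepts explicit
quantiles so both conventions are reproducible, and evaluates the
formula faithfully rather than reproducing the inconsistent figure.

**Known table inconsistencies.** Two printed effect sizes (total
leukocytes 2.64; IgM 2.95) are not derivable from their own printed
moments under d_av, pooled-SD d, or d_z; the implementation returns the
formula values (2.16 and 0.28) and the tests document the mismatch
rather than reproduce it.  Three post-training leukocyte SDs are
printed equal to their means ("0.37 ± 0.37"), a presumed typographical
slip; the synthetic presets substitute the pre-training SDs for those
rows and carry an `sd_post_imputed` flag.

## 2. The synthetic cohort generator

`MarkerSpec` holds target marginal moments and an intra-subject
correlation (default 0.85; the motivating design assumes r > 0.8).
Dependence is a Gaussian copula on latent normals.  Marginals are
truncated normal for cell counts and immunoglobulins (negative draws
are rejected and resampled; for the preset moments the truncated mass
is negligible, so sample moments converge to the specs within 1% at
n = 10^5) and moment-matched lognormal for cytokines, whose
physiological distributions are right-skewed.  For the lognormal the
correlation is imposed on the latent scale.

The CD4 and CD8 subsets are drawn *jointly* (within-time-point
cross-correlation 0.5 by default) and the per-athlete CD4/CD8 ratio is
computed from them, so the ratio is an emergent quantity rather than an
independently drawn marker; the cohort-level ratio means (≈1.35 pre,
<1.0 post) act as a calibration check of that construction, not as
generator inputs.

What the generator deliberately does **not** emulate: measurement
error distinct from biological variation, athlete-level covariates
(sex, age, training history), dropout or missingness, and any
between-marker dependence beyond the CD4–CD8 pair.  Tests that pass on
these panels therefore certify the *pipeline arithmetic* under the
assumed moment structure, not robustness to real-world artefacts.

**Training load.** The 28-day schedule (22 training days; three Sunday
rests, two pre-test rest days and the post-test sampling day carry no
load) is converted to per-tick stress: each training day fires, at its
first tick, a lactate pulse with amplitude ~ Normal(session BLa mean,
SD) clipped at zero, and a glucose-drain pulse of amplitude
zone-weight × `stress_drain_scale`; both decay geometrically with a
3-tick half-life.  Zone weights default to Moderate 0.5, Heavy/Mixed
1.0, Severe 2.0, Extreme 3.0.  Whether the week-1 Sunday
"active recovery/massage" slot counts as load is not knowable from the
schedule alone; it defaults to rest, with a flag to include it as an
easy Moderate session.

## 3. The agent-based model

**Entities.** CD4 and CD8 T cells and APCs (state: energy, activation
naive/effector/exhausted, position), pathogens (position, virulence),
and a 2-D torus of glucose-bearing patches with one global
systemic-lactate scalar.  Lactate is global rather than per-patch
because the quantity it mirrors (blood lactate) is systemic; a
per-patch field is a documented extension point.

**Tick cycle.** (1) movement: every non-exhausted agent steps to a
uniform random Moore neighbour, immune agents paying `move_cost`;
(2) metabolic: immune agents consume patch glucose up to demand plus a
small refill (`refill_rate`, capped at `energy_max`), with pro-rata
rationing when a patch cannot cover its occupants — an order-free rule
chosen over randomized sequential consumption so that no agent-index
artefacts can arise; the stress series then injects lactate and drains
every patch, lactate decays by 20%/tick (≈3-tick half-life), patches
regenerate `glucose_regen` up to `glucose_init`; (3) immune: APCs
detecting a pathogen within the Chebyshev radius become antigen-loaded,
naive T cells co-located with a loaded APC activate to effector, every
non-exhausted T cell chooses an action through the decision layer, and
pathogens in range of attackers die with probability
1 − (1−0.5)^{CD8 attackers} (1−0.25)^{CD4 attackers}; co-located
pathogens damage immune agents with a small probability;
(4) state update: effectors whose decision was proliferate — and that
clear the energy floor, the glucose feasibility and the *strict*
lactate bound — spawn a daughter with probability `proliferation_prob`
scaled by the clonal-expansion intensity; agents at zero energy die;
effectors accumulating `exhaustion_ticks` = 30 ticks under suppressive
lactate become exhausted and are removed after a 10-tick grace;
effectors quiet for 25 ticks at low lactate revert to naive; pathogens
replicate at 5%/tick × virulence up to a 150-agent cap.

Population-level immunosuppression is not scripted anywhere: it
emerges from the arithmetic of glucose supply vs demand.  The one
deliberate asymmetry is metabolic — CD4 demand 0.30 vs CD8 0.20 energy
units/tick, modelling the helper compartment as the more glycolytic
population — and it, not any explicit kill-the-CD4 rule, produces the
ratio inversion under sustained substrate scarcity.

**Decision layer.** Candidate actions {proliferate, rest, attack,
migrate} with intensity in [0,1] are scored on two minimization
objectives: f1 = −(expected pathogens killed) and f2 = energy cost.
Attack is credited with k·kill_weight immediate kills; proliferation is
credited with its daughter's expected contribution over a
`proliferation_horizon` of 3 attack-ticks — without that forward term
the proliferate action would be Pareto-dominated by rest in every
context and could never be selected, contradicting the intended
behaviour near infection clusters.  Feasibility is Eq.-(2)-style:
g = demand − local glucose ≤ 0 for every action, plus a strict
lactate − threshold < 0 constraint on proliferation only (the boundary
is closed *against* proliferation: lactate exactly at 7.0 already
blocks it, while the glucose boundary g = 0 remains feasible).
Selection among the feasible non-dominated set is by equal-weight
scalarization with seeded tie-breaking — reproducible, and since
positive-weight scalar minimizers are automatically non-dominated, the
engine's vectorized chooser can skip explicit front construction; a
test pins the two code paths to pointwise agreement.

**Clonal expansion (NNIA reduction).** A bounded archive (size 20) of
non-dominated (decision, objective) pairs is maintained across ticks
from sampled agent contexts; each tick a clone budget (10) is allocated
proportionally to crowding isolation (nearest-neighbour distance in
objective space, largest-remainder rounding) and clone intensities are
Gaussian-mutated (σ = 0.1, clipped to [0,1]).  The mean intensity of
proliferate-type clones scales the engine's spawn probability and
biases the proliferate score, so expansion pressure adapts to the
archive's current trade-off surface.  The published optimizer's
recombination and active-population machinery is deliberately reduced
to this archive + proportional cloning + mutation core; the reduction
is a modelling choice, not an approximation claim.

**Calibration.** The motivating model description names the entities,
the tick cycle, the suppression logic and the constraint equations but
no rate constants; every numeric default here is therefore a
calibration chosen once so that the three validation patterns emerge,
and labelled as such.  Load-bearing choices: `glucose_regen` 0.25 per
patch/tick sits *below* CD4 upkeep (0.30 + 0.10 move) and *above* CD8's
net need, so sustained drains starve helpers first; `attack_cost` 0.4
sits above `glucose_regen`, so attacking becomes infeasible exactly on
drained patches (this is what sustains the pathogen load under
stress); `suppression_threshold` 7.0 mirrors the severe-domain
criterion BLa > 7.0 mmol/L; initial populations are the cohort T0
means × 0.1 (81 CD4, 61 CD8, ratio 1.33); 280 ticks = 10 ticks/day ×
28 days.  Initial energies are drawn uniform on [0.5, 1]×`energy_init`
so starvation deaths stagger instead of arriving as a cliff.

## 4. Pattern-oriented validation

The three qualitative patterns are operationalized as pure functions
of traces (so constructed oracle traces can test them without the
simulator):

- **Non-linear decay**: terminal total immune count below initial AND
  a single-exponential least-squares fit beating the linear fit by
  ≥ 2 AIC (both fits have two parameters, so the margin is purely
  goodness of fit).  Chosen over curvature tests for robustness on
  short noisy traces.
- **Ratio inversion**: median CD4/CD8 over the final 10% of ticks
  below 1.0 from an initial ratio above 1.0; a zero CD8 count in the
  window is an undefined ratio and fails with a diagnostic.
- **Resolution failure**: terminal pathogen load above 10% of the
  inoculum under stress while the control's is at or below it.

A configuration is valid when each pattern passes in ≥ 80% of seeds
(ψ = 0.8).  With the shipped defaults all three pass 20/20 high-stress
seeds and 0/20 control seeds.  The high-stress regime is deliberately
past the tipping point — the helper compartment typically collapses
entirely — because the validation targets are structural patterns, not
quantitative trajectories; no numeric curve is fit to empirical data.
The tipping-point sweep reduces each stress multiplier to the median
terminal immune count over seeds and reports the grid interval of
steepest decline plus a sharpness index (steepest slope / response
range); on the default grid {0, 0.5, 1, 2, 4} the critical multiplier
falls between 0.5 and 1.

## 5. Numerical and testing choices

- One seeded PCG64 generator per simulation run; identical config +
  seed reproduces traces byte-for-byte.  The documented default seed
  for randomized batteries is 20220202.
- Wilcoxon exactness threshold n = 25; the exact branch's DP is
  verified against full 2^n enumeration for n ≤ 8.
- BH-FDR is verified against both a brute-force min-over-tails double
  loop and statsmodels.
- The generator/analyzer loop-closure test compares the *mean* pipeline
  d_av over 16 replicate panels of n = 10,000 to the preset-implied
  value at ±0.05: for the largest effects (d ≈ 7) the single-panel
  sampling SD of d̂_av is ≈ 0.04, the same order as the tolerance, so a
  single draw cannot certify convergence; the replicate mean (MC error
  ≈ 0.012) can.
- Simulation problem sizes in tests and the acceptance script — 33×33
  grid, ~160 immune agents, 280 ticks, 20-seed batteries, a 5-point
  sweep — were chosen so the whole validation battery completes in
  about a minute on one CPU while leaving the pattern outcomes far
  from their pass thresholds.

## 6. Known limitations

- The ABM is a qualitative heuristic, not a predictive model: rate
  constants are calibrated to patterns, tick duration has no fixed
  physical unit beyond the 10-ticks/day convention, and terminal
  population sizes should not be read as cell concentrations.
- B cells and NK cells are not model entities (only CD4, CD8, APCs and
  pathogens are described in the motivating model); cytokines are
  empirical markers, not simulated fields.
- No plasma-volume correction is applied anywhere — the motivating
  analysis did not perform one — so concentration declines conflate
  true modulation with hemodilution by design.
- The statistics module implements the paired design only; no
  mixed-effects or longitudinal extensions.
- The printed q-values of the motivating tables (uniformly ".0012")
  require the raw per-athlete data and are not reproducible from
  summary moments; the pipeline computes q-values from actual panels
  instead.
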