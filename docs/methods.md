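# Methods

`tpafish` implements an instrumental texture-analysis pipeline for fish
fillets: texture profile analysis (TPA) by double compression with a
ball probe, attribute extraction from the force–time curve, removal of
the fillet-thickness contribution by regression residuals,
two-treatment cohort statistics on per-fish means, and prediction of
descriptive-panel sensory intensities from the instrumental
attributes.  Because no raw traces from such studies are publicly
deposited, the package carries its own calibrated curve generator; this
note records the models, the defaults and why, and what the synthetic
data can and cannot show.

## The double-compression test and its attributes

A ball probe approaches at 3 mm/s, registers contact when force
exceeds a 5 g trigger, compresses the sample to 50% of its local
height at 1 mm/s, withdraws, pauses 5 s, and compresses a second time
to the same absolute depth.  Eight anchor points on the force–time
curve bound four work areas (trapezoidal integrals of force over time,
N·s) and two travel distances (mm):

| attribute | formula | meaning |
|---|---|---|
| hardness‑1, hardness‑2 | peak force, cycle 1 / 2 | resistance to compression (N) |
| hardness‑1b | Area 1 (cycle‑1 compression work) | work-based hardness (N·s) |
| cohesiveness | Area 4 / Area 1 | second-bite work relative to first |
| resilience | 100 · Area 2 / Area 1 | elastic recovery of work (%) |
| springiness | 100 · Distance 2 / Distance 1 | height recovery (%) |
| adhesiveness | Area 3 (≤ 0) | probe hold-back on withdrawal (N·s) |
| chewiness‑1 / ‑1b / ‑2 | hardness variant · cohesiveness · springiness/100 | composite chew effort |
| thickness‑1 / ‑2 | 2 · Distance 1 / 2 · Distance 2 | local height before / after first bite (mm) |

At 50% strain the probe travels half the local height, so twice the
travel is the height itself; `thickness_2 = thickness_1 ×
springiness/100` holds exactly by construction of the formulas.

Numerical choices in the extractor:

- Areas integrate force over **time**; at the constant 1 mm/s test
  speed this equals work over distance numerically.  Area 1 starts at
  the trigger crossing, not at geometric contact.
- Trigger crossings and zero crossings are located by linear
  interpolation between bracketing samples; cycle peaks take the
  earliest index on ties.
- Anchor *location* uses a 5-sample median filter and a 3-sample
  debounce on threshold crossings so noise cannot spawn spurious
  cycles; all *reported* values integrate the raw samples.
- The adhesion region is recognized only when smoothed force dips
  below minus one trigger force; otherwise it collapses
  (a4 = a5, Area 3 = 0).
- A decompression limb that never returns to zero falls back to the
  end of the above-trigger run; distance‑2 exceeding distance‑1 warns
  but does not fail (it can happen on swollen samples).

## The curve generator

The generator is an *attribute-level emulator*, not a constitutive
model of cooked muscle.  During a compression limb the force at
normalized depth `x = d/d_max` is

    F(x) = S · (x^m + c·x) / (1 + c)

with peak force `S`, exponent `m`, and a linear toe weight
`c = 0.05`.  The toe exists because a 5 g trigger on a pure power law
with a realistic exponent would fire ~40% into the stroke; with the
toe, contact registers within ~0.05 mm, as a real load cell does.
The exponent default `m = 12` is set by the published work/peak ratio:
mean normalized force ≈ hardness‑1b / (hardness‑1 · d₁) ≈ 0.096 at
d₁ ≈ 7.9 mm, which inverts to m ≈ 12 given the toe.

The remaining geometry is closed-form: the second compression reaches
the same absolute probe depth but starts at the recovered surface, so
springiness equals the recovery fraction; withdrawal force decays over
`decompression_fraction · d₁` of travel (so resilience equals that
fraction); the second-cycle exponent `m₂` is solved per test point
from the drawn cohesiveness via
`cohesiveness = f₂ · rf · g(m₂)/g(m₁)` where `g` is the mean
normalized force and `f₂` the second/first peak ratio; adhesiveness is
the area `−2·A·τ/π` of a half-sine dip (default A = 0.9 N, τ = 2 s,
giving ≈ −1.15 N·s).  Gaussian noise (default SD 0.02 N ≈ 2 g) is
added to force only; displacement is crosshead-driven and exact.  The
tiny trigger offset is inverted when mapping drawn attribute values to
fillet parameters, so measured attributes are unbiased for their
targets.

Because every piece has a closed form, `simulate_curve` returns exact
ground truth with each trace; traces are sampled on grids aligned to
the motion-segment boundaries so the true peak and zero instants are
present in the data (noise-free extraction then agrees with ground
truth to ≲0.01%, and the 0.5% round-trip tolerance in the tests leaves
room for realistic noise).

## Cohort generation

`simulate_cohort` draws per-fish latent attribute values around
group-level targets whose defaults are the published two-treatment
summary (60 phosphate-treated IQF fish vs 34 fresh-frozen fish, 8
points per fillet; see `tpafish.reference`).  Within-fish
point-to-point jitter (thickness 0.8 mm, hardness 6% relative,
springiness 1.5 points, …) represents fillet taper and tissue
heterogeneity; between-fish SDs are deflated by the within-fish
variance divided by the number of points so the SD *of fish means*
converges to the published values.  Per-fish thickness and hardness
are drawn with correlation 0.5 (thicker fillets read harder), which is
what gives the cohort-fitted residual lines slopes of the right sign
and order.  Hardness‑2 tracks hardness‑1 with a 2% relative wobble in
the peak ratio, keeping the two peaks highly but not perfectly
correlated.  All randomness derives from one `SeedSequence`, so equal
seeds give identical cohorts.

Sensory scores are generated per fish from the fish-mean TPA profile
through a linear link plus Gaussian noise (SD 0.7 intensity units),
clipped to the 0–15 spectrum scale.  Default link coefficients are
single-predictor (e.g. firmness ← 0.01·hardness‑1,
flaky ← −0.0124·hardness‑1) with intercepts solved so the implied
group means match the published sensory summary.

What the generator does **not** emulate: cooking heat transfer,
within-fillet spatial structure beyond independent jitter, non-Gaussian
tails, panelist effects, or the full covariance of the twelve
attributes (only the thickness–hardness and peak–peak correlations are
imposed; the rest emerge from the shared parameters).  Passing tests
therefore demonstrate correctness of the *pipeline arithmetic and
statistics* under realistic magnitudes, not biological fidelity of any
individual trace.

## Residualization

Residual attributes subtract a straight line in thickness‑2:
`residual = value − (slope·t₂ + intercept)`.  Eight published lines
are shipped as fixed constants (five instrumental, three sensory);
cohort-specific lines are fitted by OLS on per-fish means (per-point
fitting is available by passing the per-point table deliberately).
Residual hardness‑1 has no published line and is computed by fitting
only.  Thickness‑2 is always the covariate: it is the better predictor
of the work attributes because the first compression flattens
variation in the initial surface.

A known inconsistency, recorded rather than resolved: applying the
published chewiness‑1b line to the published group means does not
reproduce the published residual chewiness‑1b means beyond rounding
(−2.30 vs −3.713 and +4.14 vs +6.552); that line was evidently fitted
on a different granularity or subset.  It is excluded from the
cross-check suite; all other line/mean combinations are consistent.

## Cohort statistics

Repeated measures are averaged per fish (unweighted, missing points
omitted); the treatment comparison is a one-way fixed-effects ANOVA on
fish means, which for two groups is exactly the pooled two-sample
t test (F = t²).  An unbalanced mixed model on the same fish means
reduces to this once each fish contributes a single aggregated
observation, so the simplification costs nothing here.  Summary-table
SDs are across fish.  Tests are two-sided at α = 0.05 with no
multiple-testing correction, and no covariates (side, pond) are used.

## Sensory prediction

Published equations are stored verbatim (coefficients, RMSE, R², R)
for both treatments — ten fresh-frozen models and nine IQF models plus
an explicit "no model" marker for IQF moisture retention — and are
evaluated without refitting, so cross-checks against the published
group means are pure arithmetic.

The stepwise procedure is forward-only with entry p < 0.05: at each
step the candidate with the smallest partial-F p-value enters if it
qualifies.  Phase 2 augments the candidate pool with the squares and
pairwise cross products of the phase-1 survivors only, keeping the
phase-1 terms.  Ties on p are broken by larger SSE reduction, then
alphabetically.  Candidates whose entry would make the design
rank-deficient are skipped.  The default candidate pool is the union
of the twelve attributes and the available residuals; fits are
per-treatment (pooling the two products roughly halves R²).  RMSE uses
the regression convention √(SSE/(n−p−1)); R = √R² (undefined when an
unfitted equation yields R² < 0 off its own sample).  Fitting uses
per-fish means, matching the ANOVA granularity.

A second recorded inconsistency: the published IQF springiness
equation evaluated at the published mean of its single predictor gives
1.22, far from the published sensory springiness mean of 3.09,
violating the OLS mean identity; it is excluded from the cross-check
suite.

## Problem sizes and tolerances in the test suite

Cross-check arithmetic is exact (tolerances are set by the rounding of
the printed inputs: ±0.02 at O(1) scale, ±0.002 for the two
three-decimal small-magnitude targets, ±0.2 where a steep slope
amplifies thickness rounding).  Moment-convergence checks use 500 fish
per group; the treatment-separation experiment uses 1000 seeded
replicates at the study's group sizes; stepwise null-rate experiments
use 300–400 replicates of n = 80–100 with 8–10 candidates, sized to
put the binomial standard error well inside the asserted bands.
Integration oracles run at 2×10⁵–4×10⁵ samples where trapezoidal error
is below 10⁻⁶ relative.
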