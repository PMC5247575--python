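# Methods

## Choice model and synthetic study

Each female line `i` carries a latent quality `q_i ~ N(0, σ_q²)` expressed
through two cue channels, visual `v_i = q_i + ε_v` and chemical
`c_i = q_i + ε_c` (channel noise sd 0.3 by default).  The channels are
deliberately redundant readings of the same quality: blocking one removes
signal but preserves the ranking carried by the other, which is what lets
single-modality-impaired choosers keep sorting lines correctly.

A two-female trial under sensory condition `s` proceeds in two steps:

1. **Detection.** The trial yields a mating with probability
   `π_mate = floor + (base − floor)·w_s`, where `w_s` is the summed weight
   of the unblocked channels (1 for intact, 0 for both blocked).  With
   both channels blocked only the floor (default 0.02) remains, emulating
   the collapse of mating when neither sight nor chemosensation is
   available.
2. **Choice.** Conditional on mating, line `i` is chosen over `j` with
   probability `logistic(β·(S_i − S_j))` where
   `S_i = w_v v_i + w_c c_i + noise + w_r r_i` is the per-trial perceived
   score: a Bradley–Terry model on perceived-attractiveness differences.
   The female receptivity latent `r_i` enters *additively* with weight
   `w_r` — mate outcome is treated as a sum of male assessment and female
   willingness.  Whether the two interact multiplicatively instead is
   untested; the additive form is the simplest model in which both sexes'
   behaviour contributes, and nothing downstream depends on the
   distinction at the effect sizes simulated.

Female traits load on the same latent quality through correlated
standard-normal latents: the receptivity score loads +0.8 (more
attractive lines mate faster), the two repellent hydrocarbon peaks load
−0.8, log offspring mean loads +0.6, and body mass loads 0 (mass varies
among lines but carries no attractiveness signal).  Linear maps take the
latents to natural units (courtship-to-mating line mean
`60 − 20·latent` minutes clipped at 2; peak-9 relative abundance
`0.15 + 0.04·latent`; offspring mean `exp(3.4 + 0.5·latent)` ≈ 30).
Because the maps are linear, the configured loadings are the population
correlations, which the generator tests verify by Monte Carlo.

Defaults mirror the emulated design: 10 lines, all 45 pairwise
combinations, 14 replicate trials per pair, 20 receptivity observations
per line with a 200-minute right-censoring window, 10% structural
zero-offspring vials on a negative binomial with size 2, and 10% of
proximity trials below the 50 s analysis filter.  An `outlier_line`
option forces one line's quality to the bottom of the panel and its
offspring mean to the top, decoupling productivity from attractiveness.

Individual courtship-to-mating times are gamma-distributed around the
line mean with coefficient of variation 0.35 (shape `1/cv²`): positive,
mildly right-skewed durations whose line-mean estimator is unbiased and
near-normal at n = 20, so 2-standard-error intervals achieve close to
nominal coverage.  A more skewed family (e.g. lognormal at cv 0.5) would
push the coverage of such intervals below 93% at this sample size.

Per-individual hydrocarbon profiles place the two repellent peaks among
27 background peaks and renormalize each individual to sum to one
(relative abundance = peak area over total analysed area).  Each line
receives independent multiplicative variation on the background peaks;
without it, renormalization alone would make every background peak a
mirror image of the repellent signal and the abundance screen would flag
the entire profile.

### What the generator does not emulate

Courtship ethograms, video frames, circadian hydrocarbon dynamics,
colour-marking and colour balancing (experimental controls with no
statistical content downstream), male individual identity across trials,
and block structure.  Passing tests therefore demonstrate that the
analysis chain recovers the structures this generative model produces —
linear latent quality, redundant channels, line-level trait loadings —
not that real trial data satisfy those assumptions.

## Network construction

Preference `p(i,j)` is the fraction of (i,j) matings won by `i`; trials
with no mating within the observation window are excluded from
preferences but retained for mating rates.  An edge points from the line
with `p > ½`; exact ½ is a tie (no arrow), and pairs with no matings at
all are ties flagged "no data".  Copeland scores are out-degrees over
resolved edges with competition ranking (tied scores share a rank).
Pair proportions are aligned across choosers by a canonical
lexicographic pair order, so the same quantity — preference for the
alphabetically first line — is correlated between choosers; pairs
undefined in either network are dropped pairwise-complete and the count
logged.

## Permutation inference

All randomization tests use the add-one convention
`p = (n_exceed + 1)/(n_perm + 1)`, which floors at 1/100,001 for the
100,000-replicate transitivity test, and draw replicates from numpy's
Philox counter-based generator keyed by the caller's seed, so identical
`(seed, n_perm)` give identical results.

**Transitivity.**  Each replicate re-orients every resolved edge with
probability ½ each way; ties stay ties.  Tie-containing triads are
excluded from both the numerator and denominator of `t_tri` — the
standard dominance-hierarchy convention — and because ties are fixed the
resolved-triad denominator is constant across replicates, so the
"replicate ≥ observed" comparison reduces to an exact integer comparison
of transitive-triad counts with no floating-point tie-breaking.  The
triad census itself is delegated to the directed triadic census
(030T/030C types); an independent brute-force triple classifier serves
as the test oracle.

**Trait correlations.**  The permutation unit is the line: the
line-to-trait assignment is shuffled and every pairwise difference
recomputed, respecting the dependence of the 45 pair statistics on 10
underlying measurements.  Exceedance is two-sided by default
(`|r_perm| ≥ |r_obs|`); a sidedness flag exposes the directional
variants.  Pearson `r` makes the p-value exactly invariant to affine
trait transformations.  For individual-level receptivity differences
(antisymmetric per-pair statistics rather than per-line values), the
line permutation maps pair `(i,j)` to `(σi, σj)` and negates the stored
difference when the image pair is stored in the opposite canonical
order.

**Discreteness and calibration.**  `t_tri` takes few distinct values on
small networks, so the reported permutation p is conservative
(super-uniform) rather than uniform.  The test suite therefore
calibrates with *randomized* p-values — ties between replicate and
observed statistics broken by a uniform draw — which are exactly
Uniform(0,1) under the null for any discrete statistic; the reported
conservative p is separately checked never to exceed its nominal
rejection rate.  Randomized p-values are a diagnostic device only; the
pipeline always reports the conservative p.

## Receptivity score and correction

The receptivity score is `max(line-mean time) − line-mean time`: the
slowest line scores 0, higher is more receptive.  Line means use
uncensored individuals only; the 200-minute substitution for non-maters
applies only in the individual-level randomization, where censored
females enter at the maximum.  Random pairing between lines is without
replacement with excess individuals dropped, seeded.

The correction regresses per-pair preference on the pairwise
receptivity-score difference by ordinary least squares on the proportion
scale and re-orients each pair by the sign of its residual (exactly zero
residuals become ties, which the binary re-assignment rule leaves
undefined).  A logit-scale option is exposed (off by default): when the
underlying choice rule is logistic in the receptivity difference, the
linear-scale fit leaves systematic curvature in the residuals and the
corrected network retains some of the mediated signal, whereas the
log-odds fit removes it entirely.  The simulation contrast in the test
suite uses the logit option for exactly this reason.  The corrected
preference stored is `0.5 + residual` (clipped to [0,1]), so a
zero-slope fit reproduces the original network identically.

## Proximity assays

Dwell time credits each inter-frame interval (0.5 s at 2 fps) to a
female whose 3 mm circle contains the frame's position (boundary
inclusive).  Female positions closer than two radii are rejected at
load — with females embedded 10–15 mm apart the circles cannot overlap,
and the assertion makes the both-credited branch unreachable for valid
geometry.  Trials with total proximity under 50 s are removed and
logged.  Signed-rank tests against ½ use the exact null for n ≤ 25
(falling back to a tie-safe method when zeros or tied magnitudes
preclude the standard table) and the normal approximation with tie
correction above.  Replicates are pooled only when a two-sided rank-sum
test finds no difference at α = 0.05.  Fisher's combination uses the
one-tailed p-values, null "≤50% of time near the previously more
attractive line", with two-sided p-values reported alongside.

## Offspring model

The zero-inflated negative binomial has an intercept-only inflation
component (logit link) and an NB2 count component (log link) with female
line and male line as fixed effects — the minimal reading of
"zero-inflated negative binomial with line effects", and the one that
makes the line-effect likelihood-ratio test carry `n_lines − 1` degrees
of freedom.  Fitting is quasi-Newton (BFGS, falling back to Nelder–Mead)
from Poisson-regression starts with a moment-based inflation start;
non-convergence triggers up to four seeded jittered restarts before an
explicit error — never a silent bad fit.  The fitted log-likelihood is
asserted to be at least the start-value likelihood.  A fixed-dispersion
GLM variant (`inflation="none"`, `alpha_fixed`) recovers the Poisson
limit and anchors the count component against an independent oracle.

The companion receptivity LRT is a Gaussian fixed-effects model on
log-transformed courtship-to-mating times (uncensored observations; the
response transform is not dictated by the design, so a raw-scale option
is exposed).

Outlier screening uses externally studentized residuals from an OLS of
line-mean productivity on each candidate trait, two-sided t tails
multiplied by the number of lines and capped at 1, flagging at adjusted
p < 0.05.

## Numerical and design choices

- p-values never equal 0: the add-one convention bounds them below by
  `1/(n_perm + 1)`.
- One-way ANOVA is computed from sums of squares; complete separation
  (zero within-group variance, nonzero between) reports an infinite F
  and p = 0 rather than an exception.
- Geometric-mean (standardized major axis) regression:
  `slope = sign(r)·sd(y)/sd(x)` through the means; used for display
  fits, not inference.
- The hydrocarbon screen correlates each peak's line-mean relative
  abundance with the Copeland attractiveness score (higher = more
  attractive), so repellent peaks appear with negative `r`; `|r| > 0.5`
  selects.  Constant peaks are excluded with a note.  The screen's
  detection property is stated for the repellent *channel*: at loading
  0.8 with 10 lines, sample-correlation noise means each individual peak
  clears the threshold in only ~85–90% of studies while at least one of
  the two does in ~98%.
- CSV dialect: UTF-8, comma-separated, header row, "." decimal, missing
  values as empty fields.  Every filtering decision (dropped pairs,
  filtered proximity trials, excluded lines) is logged at INFO with
  counts.
- The run report embeds a schema version, a config hash (excluding the
  output directory), and every seed; reruns with the same config are
  byte-identical apart from where they are written.

## Problem sizes in tests

The library defaults are the analysis conventions (100,000 direction
randomizations, 10,000 label permutations).  The test suite exercises the
same code at sizes chosen for a single-CPU run: 10,000 random
tournaments for the null-mean and null-variance checks, 500 simulated
pipelines (6 lines × 6 replicates, 199–300 permutation replicates) for
the uniformity calibrations, 50 high-signal studies (steepness 20,
perception noise 0.25, cue noise 0.05, 20 replicates per pair) for
latent-quality rank recovery, 25 fits at 200 females per line for ZINB
parameter recovery, and 25–40 runs for the correction and
outlier-exclusion contrasts.  Exhaustive enumerations (all tournaments
on ≤5 lines, all sign patterns for n ≤ 12 signed-rank tests, all group
assignments for small rank-sum tests) are complete, not sampled.

## Known limitations

- The generator's latent quality is one-dimensional; it cannot produce
  genuinely intransitive preference structures (context-dependent or
  multi-attribute choice), so the analysis chain's behaviour under true
  intransitivity is exercised only through hand-built cyclic networks.
- The receptivity correction is a statistical residualization, not a
  causal mediation analysis; with correlated non-behavioural traits it
  will remove their shared variance too.
- Line-permutation inference treats lines as exchangeable units; with 10
  lines the permutation p-value granularity (10! relabelings, sampled)
  is ample, but panels below ~6 lines leave the test underpowered.
- The zero-inflation component is intercept-only; line-dependent
  inflation would be absorbed into the count component's line effects.
- Longer-chain (whole-network order-model) transitivity diagnostics are
  out of scope; the triad census and its randomization null are the
  implemented instruments.
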