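# Methods

## The population model

Every scenario describes a population on a (between-groups × within-cells)
grid.  Within-participant responses are jointly normal with unit SD in
every cell and a compound-symmetric correlation matrix (a single
correlation r for all pairs of within cells; a full matrix may be given
for custom designs).  Between-groups are independent samples.  Because
cell SDs are fixed at 1, every cell-mean difference is a standardized
effect, and designs are parameterized by a single effect size d with a
target power (default .80) at α = .05.

Effect-size convention for repeated measures: the catalog's d is **d_z**,
the difference-score effect (mean of the paired differences over their
SD), because d_z is what determines paired-test power.  Raw within-cell
mean differences are therefore d_z·√(2(1−r)); at the default r = .5 this
scale is exactly 1, so d_z = d_av there.  The construction makes the power
of every within-participant contrast invariant to r (at r = .9 the raw
difference shrinks to d·√0.2 ≈ .45·d while the difference-score SD shrinks
by the same factor), which is why minimal-N runs at r = .5 and r = .9
agree.  Between-group shifts are raw d on the cell scale: the power of a
between-groups effect in a split-plot design *does* depend on r (participant
means have variance (1+r)/2), and the catalog reproduces the published
spread (75/group at r = .5 vs 95/group at r = .9 for the split-plot
between effect; 80 vs 100 for the ANCOVA gain design, whose raw gain is
d_z·√(2(1−r))).

## Success criteria (pattern power)

A study "succeeds" when *every* clause of its criterion holds on the same
simulated dataset.  Clauses are: omnibus ANOVA effects (two-tailed α),
pairwise contrasts (one-tailed in the expected direction, at a per-test
Bonferroni α = family α / number of corrected post-hocs), expected-null
contrasts (the same one-tailed p must be **non**-significant at the same
per-test α), TOST equivalence verdicts, and Bayes-factor bounds (BF10
above a bound for expected effects, below a bound for expected nulls).
Conventions worth stating:

* "One-tailed Bonferroni-corrected at family α = .05 over two tests"
  means one-tailed p < .025, i.e. two-tailed p < .10/2 — the two notations
  are the same test.
* Three-level "similar" designs (population pattern I = II > III) require
  the two real differences to be significant *and* the equal pair to be
  non-significant (one-tailed p ≥ .05/3); the Bayesian version requires
  BF10 > 10 for the real differences and BF10 < 3 for the equal pair.
  Requiring the null outcome is what makes the recovered pattern match
  the population pattern, exactly as in the 2×2 one-cell-only interaction
  criterion.
* A degenerate replicate (zero variance somewhere) never counts as a
  success.

## Frequentist machinery

All tests are exact classical procedures, vectorized over a leading
replication axis: pooled-variance t tests (the designs are balanced and
homoscedastic by construction, so Welch's correction would only cost
power), the t-based Pearson test, fixed-effects one-way F, one-way RM
ANOVA with the subject-by-treatment error term, and 2×2 RM / split-plot
ANOVAs by orthogonal-contrast decomposition — each single-df effect is an
exact paired or independent t squared, verified against a general
mixed-ANOVA implementation in the tests.  No sphericity correction is
applied: all within factors have two levels except the three-level
design, where compound symmetry holds by construction.  The ANCOVA is the
common-slope model (group + pretest, no interaction), F(1, N−3) for the
group effect.  TOST declares equivalence when both one-sided tests reject
at α.

## Bayesian machinery

The t-test Bayes factor is the JZS default: Cauchy prior with scale
rscale = √2/2 on the standardized effect, computed by adaptive quadrature
of the one-dimensional integral over the relative prior variance
g ~ InverseGamma(1/2, rscale²/2) on a log axis (relative error < 1e-6;
cross-checked against an independent brute-force trapezoid oracle and
against pingouin).  ANOVA Bayes factors put independent g-priors on the
projected sum-to-zero effects — fixed effects at scale .5, the
participant random effect at scale 1, the conventional defaults — and
integrate on fixed log-g grids (1-D for between designs, 2-D for
repeated measures); for two groups this is *exactly* the two-sample JZS
BF with rscale √2/2, which the tests assert.  The correlation BF uses a
stretched-beta prior on ρ of width κ = 1/3 (the conventional "medium"
width; it also calibrates the BF10 > 10 design target for ρ = .2 to 80%
at 370 pairs, where κ = 1 would give ~76%) and integrates the exact
sampling density of r, again cross-checked against an independent
implementation.

In Monte-Carlo recipes, Bayes-factor requirements on single-df effects
are evaluated by inverting the BF once per sample size: BF10 is strictly
increasing in |t|, so "BF10 > 10" is "|t| > t*(n)", which turns a
quadrature per replicate into one root-find per design point.  Split-plot
and ANCOVA single-df effects use the JZS t BF with the effective n of the
corresponding t statistic.  Multi-df omnibus requirements (three-level
designs) evaluate the g-prior ANOVA BF per replicate on the grid.  Only
the t-test prior scale is canonical; the ANOVA and correlation scales are
exposed as parameters, and the Bayesian reference cells are validated
structurally (Bayesian N ≥ frequentist N per design; N nonincreasing in
d; the two-group prior equivalence) rather than digit-by-digit.

## Analytic power and p-value bands

Paired and two-sample power come from the exact noncentral t
(ncp = d√n and d√(n/2), two-tailed including the opposite-direction
region); correlations use the Fisher z approximation with variance
1/(n−3) (the convention that yields 194 pairs for ρ = .2 — the exact
t-based test crosses 80% at ≈193, so simulated minima can undershoot the
Fisher-z value by a pair or two); TOST power uses the standard
two-one-sided noncentral-t expression, with the classic large-sample z
approximation available as `method="z"` (the z convention is the one
behind the published 215-pairs value; the noncentral-t value is 216,
power .7989 at 215).  The p-value band distribution (bands at .001, .01,
.05, .10, split by direction) is computed from the same noncentral t.
Published versions of the d = .4 band columns follow a normal
approximation — e.g. .761 for p < .001 at N = 100 where the exact
noncentral t gives .726 — while the d = 0 column and the headline
power figures agree exactly.

## Monte-Carlo engine and minimal-N search

`mc_power` draws whole studies in vectorized batches (Cholesky transform
of standard normals; 2,000-replicate chunks bound memory) and reports the
success fraction with its binomial SE.  Default replications: 10,000 for
frequentist scenarios, 2,000 for Bayesian ones.  `find_min_n` brackets
the target by doubling, narrows by bisection, then scans grid candidates
using **common random numbers** — the same base draws sliced to each
candidate n — so the estimated power curve is monotone across candidates
and the bracketing invariant (estimate ≥ target at the returned n, below
target one step lower, on the same streams) holds exactly.  The decision
at the bracket is re-taken once with doubled replications so that a
near-boundary grid point is not misclassified by noise.  The final grid
step is 1 below n = 50, 5 up to 600 and 10 beyond: conjunction power
moves by well under the Monte-Carlo SE per participant at the reference
sample sizes, so a finer grid would report noise; the step can be
overridden.

Seeding: a root seed plus stable per-phase tags feed
`numpy.random.SeedSequence`, so every estimate and search is bit
reproducible; `sample_dataset` additionally accepts a replicate index so
any single replicate can be regenerated in isolation.

## Reliability

ICC1 and ICC2 come from the one-way random-effects decomposition.
Balanced complete data use the closed-form ANOVA estimator
(MSB − MSW)/(MSB + (k−1)·MSW); data with missing observations fall back
on REML variance components (statsmodels MixedLM) with k set to the
harmonic mean of per-participant counts — on balanced data the two
estimators agree to 1e-6.  ICC2 is the Spearman–Brown step-up of ICC1 by
k.  Negative between-participant variance estimates are truncated at zero
with a warning, but the untruncated ICC1 is reported alongside (genuinely
negative condition correlations occur in real data, e.g. between extreme
raters' positive and negative valence ratings).  `icc_by_condition`
returns per-condition and pooled reports side by side: a large
between-condition gap inflates the pooled ICC while range restriction
deflates the condition-wise ones, and negatively correlated conditions
hurt the pooled estimate, so both views are informative.

## What the simulations do and do not show

The generator draws exactly the idealized populations the reference
numbers assume: normal responses, perfectly balanced cells, homoscedastic
unit variances, compound-symmetric correlations, no missing data and no
participant or item heterogeneity beyond the modeled correlation.
Passing tests therefore validate the *machinery and the reference
numbers under those assumptions*; real data are messier, so the tabled
Ns are minima, and unbalanced designs (roughly 20% extra for a 2:1
imbalance), non-normal noise and unreliable measures all push the
requirement upward.  Multiple observations per condition enter only
through the reliability module's algebra, not as an explicit trial-level
simulation.

## Known divergences from published reference values

These are cases where the exact computation and a published (simulated,
sometimes rounded-up) value differ by a grid step or two; the package
always reports its own computed number:

* paired TOST at bounds ±.2: exact 216 vs published 215 (z convention);
* 90%-power paired minimum: exact 68; the step-5 search returns 70,
  matching the published value;
* between-groups d = .5 minimum: exact 64/group (128 total) vs printed
  130;
* three-level ordered within design: text 290 vs table 300; high-reps
  estimate of the true minimum ≈295;
* ANCOVA (r = .5): exact ≈75–76/group vs printed 80 — the step-5 search
  returns either, both within one step;
* 2×2 interaction-with-post-hocs: true minimum ≈103–104 vs printed 110
  (the ×4 rule of thumb relative to the main effect's 27);
* Bayesian paired null design (BF10 < 1/3): step-5 grid gives 55
  (P = .807; P(50) = .795) vs published 60;
* split-plot within main effect: 2 × 27 = 54 total vs the printed 55.

## Problem sizes used in the shipped checks

Monte-Carlo reference checks run at 10,000 replications (frequentist)
and 1,000–2,000 (Bayesian conjunctions); the Bayesian null design uses
40,000 in the reproduction script because adjacent grid points differ by
only ~.01 in success probability.  The analytic-vs-simulation agreement
property runs at 100,000 replications with a unit grid step.  The full
test suite completes in under two minutes on one CPU; the reproduction
script in a few seconds.
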