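# powerref

Reference sample sizes and simulation-based power analysis for the designs
psychologists actually run.

A typical published effect in psychology is around d = .4, and at that
effect size even a plain two-condition repeated-measures comparison needs
over 50 participants for 80% power — far more than much of current
practice.  Worse, the familiar closed-form power calculators answer the
wrong question for factorial designs: they give the power of the omnibus
F test, while a study only "works" when the *whole expected pattern* shows
up — the omnibus test **and** the directional Bonferroni-corrected
post-hocs **and** non-significance where the population is null.  That
conjunction ("pattern power") can require several times more participants
than the omnibus test alone, and in general it has no closed form.

`powerref` makes those numbers reproducible:

* a **scenario catalog** of population designs in standardized units
  (every cell has SD 1, so cell-mean differences are Cohen's d): two- and
  three-level between/within designs, Pearson correlations, 2×2
  repeated-measures and split-plot factorials with cross-over,
  one-cell-only and attenuated interactions, pre/post ANCOVA, plus TOST
  and Bayes-factor null designs.  Repeated-measures effects are
  parameterized as d_z (the difference-score effect that drives power),
  so results are invariant to the within-participant correlation r;
* **frequentist tests** (pooled t, Pearson r, one-way/RM/split-plot/2×2
  ANOVAs by exact orthogonal-contrast decomposition, common-slope ANCOVA,
  TOST) and **default-Bayes tests** (JZS t-test Bayes factor with Cauchy
  scale √2/2, g-prior ANOVA BFs, stretched-beta correlation BF), all
  vectorized over simulation replicates;
* a **power engine**: exact noncentral-t / Fisher-z power and minimal N
  where a closed form exists, Monte-Carlo conjunction power everywhere
  else, and a minimal-N search that reuses common random numbers across
  candidate sample sizes so the estimated power curve is monotone;
* the **effect-size algebra** (d_z = d_av/√(2(1−r_XY)), d = t/√N, the
  design-specific η²_p → d conversions, f = d/2, the 100 + 100·k
  regression rule) and the **reliability toolkit** (one-way
  random-effects ICC1/ICC2, Spearman–Brown prophecy and its inverse,
  condition-wise vs dataset-wide reliability).

## Worked example

How many participants does a 2×2 repeated-measures study need when factor
A has an effect of d_z = .4 at one level of B and none at the other, and
success means: interaction p < .05, one-tailed Bonferroni-corrected
post-hoc significant where the effect is, and non-significant where it is
not?

```python
>>> import powerref as pr
>>> pr.analytic_min_n(0.4, 0.8, kind="paired").n          # plain paired test
52
>>> sc = pr.build_scenario("rm2x2_interaction_null_cell", d=0.4)
>>> est = pr.mc_power(sc, n=110, reps=10_000, seed=0)
>>> round(est.estimate, 3), round(est.se, 4)
(0.828, 0.0038)
>>> found = pr.find_min_n(sc, target_power=0.8, reps=10_000, seed=0, step=5)
>>> found.n, round(found.estimate, 4)
(105, 0.8102)
```

So the interaction pattern needs roughly four times the 27 participants
the 2×2 main effect needs — about 105–110 — because the interaction
contrast is only half as large as its constituent simple effect and three
outcomes must line up at once.

The in-package toy datasets reproduce the textbook effect-size and
reliability arithmetic:

```python
>>> from powerref.datasets import priming_example, repeated_measures_example_long
>>> d = priming_example()
>>> res = pr.paired_t(d["Unrelated"], d["Related"])
>>> print(f"t = {float(res.statistic):.2f}, dz = {res.effect['dz']:.2f}, "
...       f"dav = {res.effect['dav']:.2f}")
t = 3.04, dz = 0.96, dav = 0.31
>>> rep = pr.icc(repeated_measures_example_long())
>>> print(f"ICC1 = {rep.icc1:.2f}, ICC2 = {rep.icc2:.2f}")
ICC1 = 0.39, ICC2 = 0.72
>>> pr.required_observations(rep.icc2, current_k=4, r_desired=0.8)
6
```

The same 10-participant priming dataset gives d_z = .96 but d_av = .31:
the near-.95 correlation between conditions makes difference scores far
more stable than the raw condition means — which is exactly why power
calculators ask for the correlation of repeated measures, and why
averaging more observations per condition (raising reliability, here from
ICC2 = .72 to .80 with 6 repetitions instead of 4) is often cheaper than
recruiting more participants.

There is also a CLI:

```
powerref scenarios
powerref min-n -s splitplot_crossover --d 0.4 --reps 10000 --seed 0
powerref table --id 8 --column d=0.4 --rows within_2_levels,correlation --out t8.csv
powerref icc observations.csv
```

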