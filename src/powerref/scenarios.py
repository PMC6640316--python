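"""Declarative catalog of population designs and study success criteria.

A *scenario* bundles three things:

* a :class:`PopulationDesign` — the population the study samples from,
  written in standardized units (every cell has SD 1, so all mean
  differences are Cohen's d values);
* a :class:`SuccessCriterion` — the conjunction of test outcomes that must
  hold for a simulated study to count as "successful" (an omnibus test,
  directional Bonferroni-corrected post-hocs, expected-null comparisons,
  Bayes-factor bounds, or an equivalence verdict);
* an analysis recipe name that tells the power engine which statistical
  machinery to run on each simulated dataset.

The catalog covers the standard reference designs: one- and three-level
between-groups and repeated-measures comparisons, Pearson correlations,
2x2 repeated-measures and split-plot factorials with the three canonical
interaction shapes (cross-over, effect-in-one-cell-only, attenuated
effect), the pre/post ANCOVA comparison, and TOST / Bayes-factor null
designs.  Every scenario is parameterized by the standardized effect size
``d`` and the within-participant correlation ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "PopulationDesign",
    "TestRequirement",
    "SuccessCriterion",
    "Scenario",
    "build_scenario",
    "list_scenarios",
    "scenario_from_config",
]


def _dz_scale(r: float) -> float:
    """Raw within-cell mean difference per unit of dz.

    The catalog's effect size for repeated-measures contrasts is dz (the
    difference-score effect, which is what drives power), so raw cell-mean
    differences are dz * sqrt(2(1-r)).  At the default r = .5 the scale is
    exactly 1; holding dz fixed makes every within-participant contrast's
    power invariant to r, which is why r = .5 and r = .9 runs give the same
    sample sizes.
    """
    return float(np.sqrt(2.0 * (1.0 - r)))


def _compound_symmetric(k: int, r: float) -> np.ndarray:
    m = np.full((k, k), float(r))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass(frozen=True)
class PopulationDesign:
    """Cell-level description of the population a study samples from.

    Cells are laid out on a (groups x within-cells) grid: ``cell_means``
    has shape ``(n_groups, n_within)``.  A pure between-groups design has
    one within column; a pure repeated-measures design has one group row.
    Within-participant cells are jointly normal with unit SD and the given
    correlation matrix (compound symmetry unless a full matrix is passed),
    so every cell mean is a Cohen's d relative to a zero baseline.
    """

    name: str
    between_factors: tuple[tuple[str, int], ...]
    within_factors: tuple[tuple[str, int], ...]
    cell_means: np.ndarray
    within_correlation: np.ndarray
    group_labels: tuple[str, ...] = ()
    within_labels: tuple[str, ...] = ()

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.cell_means, dtype=float))
        object.__setattr__(self, "cell_means", means)
        corr = np.atleast_2d(np.asarray(self.within_correlation, dtype=float))
        object.__setattr__(self, "within_correlation", corr)
        g, k = means.shape
        if corr.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {corr.shape} does not match "
                f"{k} within-participant cells"
            )
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        if not self.group_labels:
            object.__setattr__(
                self, "group_labels", tuple(f"g{i + 1}" for i in range(g))
            )
        if not self.within_labels:
            object.__setattr__(
                self, "within_labels", tuple(f"c{j + 1}" for j in range(k))
            )
        if len(self.group_labels) != g or len(self.within_labels) != k:
            raise ValueError("labels do not match the cell grid")

    @property
    def n_groups(self) -> int:
        return self.cell_means.shape[0]

    @property
    def n_within(self) -> int:
        return self.cell_means.shape[1]

    @property
    def cell_mean_map(self) -> dict[str, float]:
        """Map from cell label to standardized mean."""
        out = {}
        for i, gl in enumerate(self.group_labels):
            for j, wl in enumerate(self.within_labels):
                label = f"{gl}:{wl}" if self.n_groups > 1 and self.n_within > 1 \
                    else (gl if self.n_within == 1 else wl)
                out[label] = float(self.cell_means[i, j])
        return out

    def cholesky(self) -> np.ndarray:
        """Cholesky factor of the within-cell correlation matrix.

        A tiny jitter is added for exactly singular matrices (|r| = 1 is
        rejected upstream, but PSD-but-singular custom matrices are legal).
        """
        try:
            return np.linalg.cholesky(self.within_correlation)
        except np.linalg.LinAlgError:
            k = self.n_within
            return np.linalg.cholesky(self.within_correlation + 1e-12 * np.eye(k))


@dataclass(frozen=True)
class TestRequirement:
    """One clause of a success criterion.

    ``test`` is one of ``omnibus`` (an ANOVA effect named by ``effect``),
    ``contrast`` (a pairwise comparison of two cells, referenced by
    (group index, within index) pairs), ``correlation`` or ``equivalence``.
    ``threshold`` is a per-test alpha for frequentist clauses (already
    Bonferroni-divided where a family correction applies) or a Bayes-factor
    bound for Bayesian clauses.  ``polarity`` says whether the clause must
    pass (significance / BF10 above the bound) or must fail (expected null:
    non-significance / BF10 below the bound).  ``direction`` is the expected
    sign of (first cell - second cell) for one-tailed contrasts.
    """

    test: str
    effect: str | None = None
    cells: tuple[tuple[int, int], tuple[int, int]] | None = None
    tails: int = 2
    mode: str = "frequentist"
    threshold: float = 0.05
    polarity: str = "must_pass"
    direction: int = 1

    def __post_init__(self):
        if self.test not in ("omnibus", "contrast", "correlation", "equivalence"):
            raise ValueError(f"unknown test kind {self.test!r}")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.mode not in ("frequentist", "bayesian"):
            raise ValueError("mode must be frequentist or bayesian")
        if self.polarity not in ("must_pass", "must_fail"):
            raise ValueError("polarity must be must_pass or must_fail")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class SuccessCriterion:
    """Conjunction of test requirements defining a 'successful' study.

    A criterion with a single two-tailed must-pass requirement degenerates
    to ordinary power.  Per-test alphas already embody any Bonferroni
    correction: a family alpha of .05 spread over three directional
    post-hocs is stored as three clauses at .05/3 each.
    """

    requirements: tuple[TestRequirement, ...]

    def __post_init__(self):
        if not self.requirements:
            raise ValueError("a success criterion needs at least one requirement")

    def __len__(self) -> int:
        return len(self.requirements)


@dataclass(frozen=True)
class Scenario:
    """A (design, criterion, analysis recipe) triple from the catalog."""

    name: str
    design: PopulationDesign
    criterion: SuccessCriterion
    analysis: str
    d: float
    r: float
    mode: str
    doc: str = ""
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# catalog builders
# --------------------------------------------------------------------------

def _freq(test, *, effect=None, cells=None, tails=2, alpha=0.05,
          polarity="must_pass", direction=1) -> TestRequirement:
    return TestRequirement(test=test, effect=effect, cells=cells, tails=tails,
                           mode="frequentist", threshold=alpha,
                           polarity=polarity, direction=direction)


def _bayes(test, *, effect=None, cells=None, bound=10.0,
           polarity="must_pass", direction=1) -> TestRequirement:
    return TestRequirement(test=test, effect=effect, cells=cells, tails=2,
                           mode="bayesian", threshold=bound,
                           polarity=polarity, direction=direction)


def _design_between(name, means, d_unused=None) -> PopulationDesign:
    means = np.asarray(means, float).reshape(-1, 1)
    return PopulationDesign(
        name=name,
        between_factors=(("group", means.shape[0]),),
        within_factors=(),
        cell_means=means,
        within_correlation=np.eye(1),
    )


def _design_within(name, means, r) -> PopulationDesign:
    means = np.asarray(means, float).reshape(1, -1)
    k = means.shape[1]
    return PopulationDesign(
        name=name,
        between_factors=(),
        within_factors=(("condition", k),),
        cell_means=means,
        within_correlation=_compound_symmetric(k, r),
    )


def _design_splitplot(name, g1_means, g2_means, r) -> PopulationDesign:
    means = np.asarray([g1_means, g2_means], float)
    return PopulationDesign(
        name=name,
        between_factors=(("group", 2),),
        within_factors=(("condition", means.shape[1]),),
        cell_means=means,
        within_correlation=_compound_symmetric(means.shape[1], r),
    )


def _design_rm2x2(name, means, r) -> PopulationDesign:
    means = np.asarray(means, float).reshape(1, 4)
    return PopulationDesign(
        name=name,
        between_factors=(),
        within_factors=(("A", 2), ("B", 2)),
        cell_means=means,
        within_correlation=_compound_symmetric(4, r),
        within_labels=("A1B1", "A1B2", "A2B1", "A2B2"),
    )


def _check_r(name, r, needs_within):
    if needs_within:
        if not -1 < r < 1:
            raise ValueError(f"within correlation must lie in (-1, 1), got {r}")
    return r


class _Entry:
    def __init__(self, builder: Callable, doc: str, has_within: bool):
        self.builder = builder
        self.doc = doc
        self.has_within = has_within


_CATALOG: dict[str, _Entry] = {}


def _register(name, doc, has_within=True):
    def deco(fn):
        _CATALOG[name] = _Entry(fn, doc, has_within)
        return fn
    return deco


def _pair_reqs_between(pairs, null_pairs, mode, alpha, bf, bf_null):
    """Directional Bonferroni post-hoc battery over independent-group pairs."""
    n_tests = len(pairs) + len(null_pairs)
    per_alpha = alpha / n_tests
    reqs = []
    for (i, j) in pairs:  # cell i expected LOWER than cell j
        if mode == "frequentist":
            reqs.append(_freq("contrast", cells=((j, 0), (i, 0)), tails=1,
                              alpha=per_alpha))
        else:
            reqs.append(_bayes("contrast", cells=((j, 0), (i, 0)), bound=bf))
    for (i, j) in null_pairs:
        if mode == "frequentist":
            reqs.append(_freq("contrast", cells=((j, 0), (i, 0)), tails=1,
                              alpha=per_alpha, polarity="must_fail"))
        else:
            reqs.append(_bayes("contrast", cells=((j, 0), (i, 0)), bound=bf_null,
                               polarity="must_fail"))
    return reqs


def _pair_reqs_within(pairs, null_pairs, mode, alpha, bf, bf_null):
    n_tests = len(pairs) + len(null_pairs)
    per_alpha = alpha / n_tests
    reqs = []
    for (i, j) in pairs:
        if mode == "frequentist":
            reqs.append(_freq("contrast", cells=((0, j), (0, i)), tails=1,
                              alpha=per_alpha))
        else:
            reqs.append(_bayes("contrast", cells=((0, j), (0, i)), bound=bf))
    for (i, j) in null_pairs:
        if mode == "frequentist":
            reqs.append(_freq("contrast", cells=((0, j), (0, i)), tails=1,
                              alpha=per_alpha, polarity="must_fail"))
        else:
            reqs.append(_bayes("contrast", cells=((0, j), (0, i)), bound=bf_null,
                               polarity="must_fail"))
    return reqs


@_register("t_between",
           "Two independent groups differing by d; two-tailed t test.",
           has_within=False)
def _t_between(d, r, mode, alpha, bf, bf_null):
    design = _design_between("t_between", [0.0, d])
    if mode == "frequentist":
        reqs = [_freq("contrast", cells=((1, 0), (0, 0)), tails=2, alpha=alpha)]
    else:
        reqs = [_bayes("contrast", cells=((1, 0), (0, 0)), bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "independent_t"


@_register("t_within",
           "One group, two correlated conditions differing by dz = d; "
           "two-tailed paired t test.")
def _t_within(d, r, mode, alpha, bf, bf_null):
    design = _design_within("t_within", [0.0, d * _dz_scale(r)], r)
    if mode == "frequentist":
        reqs = [_freq("contrast", cells=((0, 1), (0, 0)), tails=2, alpha=alpha)]
    else:
        reqs = [_bayes("contrast", cells=((0, 1), (0, 0)), bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "paired_t"


@_register("correlation",
           "Bivariate normal pairs with rho = d/2; two-tailed Pearson test.")
def _correlation(d, r, mode, alpha, bf, bf_null):
    rho = d / 2.0
    design = PopulationDesign(
        name="correlation", between_factors=(), within_factors=(("var", 2),),
        cell_means=np.zeros((1, 2)),
        within_correlation=_compound_symmetric(2, rho),
        within_labels=("X", "Y"),
    )
    if mode == "frequentist":
        reqs = [_freq("correlation", tails=2, alpha=alpha)]
    else:
        reqs = [_bayes("correlation", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "correlation"


@_register("t_between_null",
           "Two identical groups; success is a TOST equivalence verdict at "
           "bounds +/-0.2 (frequentist) or BF10 below the null bound (Bayesian).",
           has_within=False)
def _t_between_null(d, r, mode, alpha, bf, bf_null):
    design = _design_between("t_between_null", [0.0, 0.0])
    if mode == "frequentist":
        reqs = [_freq("equivalence", alpha=alpha)]
        return design, SuccessCriterion(tuple(reqs)), "tost_independent"
    reqs = [_bayes("contrast", cells=((1, 0), (0, 0)), bound=bf_null,
                   polarity="must_fail")]
    return design, SuccessCriterion(tuple(reqs)), "independent_t"


@_register("t_within_null",
           "One group, two equal conditions; TOST at +/-0.2 or BF10 below "
           "the null bound.")
def _t_within_null(d, r, mode, alpha, bf, bf_null):
    design = _design_within("t_within_null", [0.0, 0.0], r)
    if mode == "frequentist":
        reqs = [_freq("equivalence", alpha=alpha)]
        return design, SuccessCriterion(tuple(reqs)), "tost_paired"
    reqs = [_bayes("contrast", cells=((0, 1), (0, 0)), bound=bf_null,
                   polarity="must_fail")]
    return design, SuccessCriterion(tuple(reqs)), "paired_t"


@_register("correlation_null",
           "Uncorrelated pairs; TOST at rho +/-0.1 or BF10 below the null "
           "bound.")
def _correlation_null(d, r, mode, alpha, bf, bf_null):
    design = PopulationDesign(
        name="correlation_null", between_factors=(),
        within_factors=(("var", 2),), cell_means=np.zeros((1, 2)),
        within_correlation=np.eye(2), within_labels=("X", "Y"),
    )
    if mode == "frequentist":
        reqs = [_freq("equivalence", alpha=alpha)]
        return design, SuccessCriterion(tuple(reqs)), "tost_correlation"
    reqs = [_bayes("correlation", bound=bf_null, polarity="must_fail")]
    return design, SuccessCriterion(tuple(reqs)), "correlation"


@_register("three_between_similar",
           "Three independent groups, new condition level with one of the "
           "extremes (means d, d, 0): omnibus plus directional Bonferroni "
           "post-hocs, with the equal pair expected null.",
           has_within=False)
def _three_between_similar(d, r, mode, alpha, bf, bf_null):
    design = _design_between("three_between_similar", [d, d, 0.0])
    reqs = []
    if mode == "frequentist":
        reqs.append(_freq("omnibus", effect="group", alpha=alpha))
    else:
        reqs.append(_bayes("omnibus", effect="group", bound=bf))
    # pairs as (lower cell, higher cell); equal pair (1, 0) expected null
    reqs += _pair_reqs_between([(2, 0), (2, 1)], [(1, 0)], mode, alpha, bf, bf_null)
    return design, SuccessCriterion(tuple(reqs)), "oneway_between"


@_register("three_between_ordered",
           "Three independent groups, new condition midway (means 0, d/2, d): "
           "omnibus plus three directional Bonferroni post-hocs.",
           has_within=False)
def _three_between_ordered(d, r, mode, alpha, bf, bf_null):
    design = _design_between("three_between_ordered", [0.0, d / 2.0, d])
    reqs = []
    if mode == "frequentist":
        reqs.append(_freq("omnibus", effect="group", alpha=alpha))
    else:
        reqs.append(_bayes("omnibus", effect="group", bound=bf))
    reqs += _pair_reqs_between([(0, 1), (1, 2), (0, 2)], [], mode, alpha, bf, bf_null)
    return design, SuccessCriterion(tuple(reqs)), "oneway_between"


@_register("three_within_similar",
           "Three repeated-measures levels with means d, d, 0: omnibus RM "
           "ANOVA plus directional Bonferroni post-hocs, equal pair expected "
           "null.")
def _three_within_similar(d, r, mode, alpha, bf, bf_null):
    s = _dz_scale(r)
    design = _design_within("three_within_similar", [d * s, d * s, 0.0], r)
    reqs = []
    if mode == "frequentist":
        reqs.append(_freq("omnibus", effect="condition", alpha=alpha))
    else:
        reqs.append(_bayes("omnibus", effect="condition", bound=bf))
    reqs += _pair_reqs_within([(2, 0), (2, 1)], [(1, 0)], mode, alpha, bf, bf_null)
    return design, SuccessCriterion(tuple(reqs)), "rm_oneway"


@_register("three_within_ordered",
           "Three repeated-measures levels with means 0, d/2, d: omnibus RM "
           "ANOVA plus three directional Bonferroni post-hocs.")
def _three_within_ordered(d, r, mode, alpha, bf, bf_null):
    s = _dz_scale(r)
    design = _design_within("three_within_ordered",
                            [0.0, d * s / 2.0, d * s], r)
    reqs = []
    if mode == "frequentist":
        reqs.append(_freq("omnibus", effect="condition", alpha=alpha))
    else:
        reqs.append(_bayes("omnibus", effect="condition", bound=bf))
    reqs += _pair_reqs_within([(0, 1), (1, 2), (0, 2)], [], mode, alpha, bf, bf_null)
    return design, SuccessCriterion(tuple(reqs)), "rm_oneway"


@_register("rm2x2_main",
           "2x2 repeated measures; factor A shifts both B cells by d, factor "
           "B null, no interaction; main effect of A tested.")
def _rm2x2_main(d, r, mode, alpha, bf, bf_null):
    s = _dz_scale(r)
    design = _design_rm2x2("rm2x2_main", [d * s, d * s, 0.0, 0.0], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="A", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="A", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "rm_2x2"


@_register("rm2x2_crossover",
           "2x2 repeated measures, fully crossed interaction (A effect +d at "
           "B1, -d at B2, no main effects); interaction tested.")
def _rm2x2_crossover(d, r, mode, alpha, bf, bf_null):
    h = d * _dz_scale(r) / 2.0
    design = _design_rm2x2("rm2x2_crossover", [h, -h, -h, h], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="AxB", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="AxB", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "rm_2x2"


@_register("rm2x2_interaction_null_cell",
           "2x2 repeated measures, A effect d at B1 and 0 at B2: interaction "
           "significant, directional post-hoc significant at B1 and expected "
           "null at B2 (per-test alpha = family alpha / 2, one-tailed).")
def _rm2x2_null_cell(d, r, mode, alpha, bf, bf_null):
    design = _design_rm2x2("rm2x2_interaction_null_cell",
                           [d * _dz_scale(r), 0.0, 0.0, 0.0], r)
    reqs = []
    if mode == "frequentist":
        a2 = alpha / 2.0
        reqs.append(_freq("omnibus", effect="AxB", alpha=alpha))
        reqs.append(_freq("contrast", cells=((0, 0), (0, 2)), tails=1, alpha=a2))
        reqs.append(_freq("contrast", cells=((0, 1), (0, 3)), tails=1, alpha=a2,
                          polarity="must_fail"))
    else:
        reqs.append(_bayes("omnibus", effect="AxB", bound=bf))
        reqs.append(_bayes("contrast", cells=((0, 0), (0, 2)), bound=bf))
        reqs.append(_bayes("contrast", cells=((0, 1), (0, 3)), bound=bf_null,
                           polarity="must_fail"))
    return design, SuccessCriterion(tuple(reqs)), "rm_2x2"


@_register("rm2x2_interaction_attenuated",
           "2x2 repeated measures, strong A effect 2d at B1 attenuated to d "
           "at B2: interaction significant plus both directional post-hocs.")
def _rm2x2_attenuated(d, r, mode, alpha, bf, bf_null):
    s = _dz_scale(r)
    design = _design_rm2x2("rm2x2_interaction_attenuated",
                           [2.0 * d * s, d * s, 0.0, 0.0], r)
    reqs = []
    if mode == "frequentist":
        a2 = alpha / 2.0
        reqs.append(_freq("omnibus", effect="AxB", alpha=alpha))
        reqs.append(_freq("contrast", cells=((0, 0), (0, 2)), tails=1, alpha=a2))
        reqs.append(_freq("contrast", cells=((0, 1), (0, 3)), tails=1, alpha=a2))
    else:
        reqs.append(_bayes("omnibus", effect="AxB", bound=bf))
        reqs.append(_bayes("contrast", cells=((0, 0), (0, 2)), bound=bf))
        reqs.append(_bayes("contrast", cells=((0, 1), (0, 3)), bound=bf))
    return design, SuccessCriterion(tuple(reqs)), "rm_2x2"


@_register("splitplot_main_within",
           "Split-plot (2 groups x 2 conditions), within effect d in both "
           "groups, no group effect; repeated-measures main effect tested.")
def _sp_main_within(d, r, mode, alpha, bf, bf_null):
    ds = d * _dz_scale(r)
    design = _design_splitplot("splitplot_main_within", [0.0, ds], [0.0, ds], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="within", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="within", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "splitplot_2x2"


@_register("splitplot_main_within_mixed",
           "Split-plot with a counterbalancing group crossing the within "
           "effect (2d in one group, 0 in the other; average d); "
           "repeated-measures main effect tested.")
def _sp_main_within_mixed(d, r, mode, alpha, bf, bf_null):
    design = _design_splitplot("splitplot_main_within_mixed",
                               [0.0, 2.0 * d * _dz_scale(r)], [0.0, 0.0], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="within", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="within", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "splitplot_2x2"


@_register("splitplot_main_between",
           "Split-plot, second group shifted by d in both conditions; "
           "between-groups main effect tested (power depends on r).")
def _sp_main_between(d, r, mode, alpha, bf, bf_null):
    design = _design_splitplot("splitplot_main_between", [0.0, 0.0], [d, d], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="between", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="between", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "splitplot_2x2"


@_register("splitplot_crossover",
           "Split-plot cross-over interaction (within effect +d in group 1, "
           "-d in group 2): interaction plus both directional post-hocs "
           "(per-test alpha = family alpha / 2, one-tailed).")
def _sp_crossover(d, r, mode, alpha, bf, bf_null):
    ds = d * _dz_scale(r)
    design = _design_splitplot("splitplot_crossover", [0.0, ds], [0.0, -ds], r)
    reqs = []
    if mode == "frequentist":
        a2 = alpha / 2.0
        reqs.append(_freq("omnibus", effect="interaction", alpha=alpha))
        reqs.append(_freq("contrast", cells=((0, 1), (0, 0)), tails=1, alpha=a2))
        reqs.append(_freq("contrast", cells=((1, 0), (1, 1)), tails=1, alpha=a2))
    else:
        reqs.append(_bayes("omnibus", effect="interaction", bound=bf))
        reqs.append(_bayes("contrast", cells=((0, 1), (0, 0)), bound=bf))
        reqs.append(_bayes("contrast", cells=((1, 0), (1, 1)), bound=bf))
    return design, SuccessCriterion(tuple(reqs)), "splitplot_2x2"


@_register("splitplot_crossover_omnibus",
           "Split-plot cross-over interaction, omnibus interaction test only.")
def _sp_crossover_omnibus(d, r, mode, alpha, bf, bf_null):
    ds = d * _dz_scale(r)
    design = _design_splitplot("splitplot_crossover_omnibus",
                               [0.0, ds], [0.0, -ds], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="interaction", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="interaction", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "splitplot_2x2"


@_register("splitplot_interaction_null_cell",
           "Split-plot, within effect d in group 1 and 0 in group 2: "
           "interaction significant, directional post-hoc significant in "
           "group 1, expected null in group 2.")
def _sp_null_cell(d, r, mode, alpha, bf, bf_null):
    design = _design_splitplot("splitplot_interaction_null_cell",
                               [0.0, d * _dz_scale(r)], [0.0, 0.0], r)
    reqs = []
    if mode == "frequentist":
        a2 = alpha / 2.0
        reqs.append(_freq("omnibus", effect="interaction", alpha=alpha))
        reqs.append(_freq("contrast", cells=((0, 1), (0, 0)), tails=1, alpha=a2))
        reqs.append(_freq("contrast", cells=((1, 1), (1, 0)), tails=1, alpha=a2,
                          polarity="must_fail"))
    else:
        reqs.append(_bayes("omnibus", effect="interaction", bound=bf))
        reqs.append(_bayes("contrast", cells=((0, 1), (0, 0)), bound=bf))
        reqs.append(_bayes("contrast", cells=((1, 1), (1, 0)), bound=bf_null,
                           polarity="must_fail"))
    return design, SuccessCriterion(tuple(reqs)), "splitplot_2x2"


@_register("ancova",
           "Pre/post design: group 2 gains dz = d between measurements "
           "(raw gain d*sqrt(2(1-r))), group 1 stable; one-way ANCOVA on "
           "the posttest with pretest covariate, group effect tested.")
def _ancova(d, r, mode, alpha, bf, bf_null):
    gain = d * np.sqrt(2.0 * (1.0 - r))
    design = _design_splitplot("ancova", [0.0, 0.0], [0.0, gain], r)
    if mode == "frequentist":
        reqs = [_freq("omnibus", effect="group", alpha=alpha)]
    else:
        reqs = [_bayes("omnibus", effect="group", bound=bf)]
    return design, SuccessCriterion(tuple(reqs)), "ancova"


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def build_scenario(name: str, d: float = 0.4, r: float = 0.5, *,
                   mode: str = "frequentist", alpha: float = 0.05,
                   bf: float = 10.0, bf_null: float = 3.0,
                   tost_bound: float | None = None) -> Scenario:
    """Instantiate a catalog scenario.

    Parameters
    ----------
    name : str
        Catalog identifier (see :func:`list_scenarios`).
    d : float
        Standardized effect size (>= 0).  For the correlation scenario the
        population correlation is ``d / 2``.
    r : float
        Common correlation between within-participant cells (compound
        symmetry), in (-1, 1).  Ignored by pure between-groups designs.
    mode : {"frequentist", "bayesian"}
        Whether requirements are alpha-based or Bayes-factor-based.
    alpha : float
        Family alpha for frequentist criteria; directional post-hoc
        batteries divide it per test (Bonferroni).
    bf : float
        BF10 bound a must-pass Bayesian requirement has to exceed.
    bf_null : float
        BF10 bound an expected-null Bayesian requirement has to stay below
        (e.g. 3 for "moderate" null evidence, 1/3 or 1/10 for stand-alone
        null designs depending on convention).
    tost_bound : float, optional
        Equivalence half-width for the frequentist null scenarios; defaults
        to 0.2 on the d scale and 0.1 on the correlation scale.
    """
    if name not in _CATALOG:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(sorted(_CATALOG))}")
    if d < 0:
        raise ValueError("d must be >= 0")
    entry = _CATALOG[name]
    _check_r(name, r, entry.has_within)
    if mode not in ("frequentist", "bayesian"):
        raise ValueError("mode must be frequentist or bayesian")
    design, criterion, analysis = entry.builder(d, r, mode, alpha, bf, bf_null)
    if tost_bound is None:
        tost_bound = 0.1 if name.startswith("correlation") else 0.2
    return Scenario(name=name, design=design, criterion=criterion,
                    analysis=analysis, d=d, r=r, mode=mode, doc=entry.doc,
                    params={"alpha": alpha, "bf": bf, "bf_null": bf_null,
                            "tost_bound": float(tost_bound)})


def list_scenarios() -> dict[str, str]:
    """Catalog listing: scenario identifier -> one-line documentation."""
    return {name: entry.doc for name, entry in sorted(_CATALOG.items())}


def scenario_from_config(config: dict) -> Scenario:
    """Build a scenario from a structured config mapping.

    Two forms are accepted.  A catalog reference::

        {"scenario": "t_within", "d": 0.4, "r": 0.5, "mode": "frequentist"}

    or an explicit custom design::

        {"design": {"groups": 1,
                    "cells": [[0.0, 0.4]],
                    "correlation": 0.5},
         "criterion": [{"test": "contrast", "cells": [[0, 1], [0, 0]],
                        "tails": 2, "alpha": 0.05}],
         "analysis": "paired_t"}

    ``correlation`` may be a scalar (compound symmetry) or a full matrix.
    """
    if "scenario" in config:
        kwargs = {k: config[k] for k in
                  ("d", "r", "mode", "alpha", "bf", "bf_null") if k in config}
        return build_scenario(config["scenario"], **kwargs)
    if "design" not in config or "criterion" not in config:
        raise ValueError("config needs either 'scenario' or 'design'+'criterion'")
    dcfg = config["design"]
    cells = np.atleast_2d(np.asarray(dcfg["cells"], float))
    corr = dcfg.get("correlation", 0.5)
    k = cells.shape[1]
    corr = _compound_symmetric(k, corr) if np.ndim(corr) == 0 else np.asarray(corr)
    design = PopulationDesign(
        name=str(dcfg.get("name", "custom")),
        between_factors=(("group", cells.shape[0]),) if cells.shape[0] > 1 else (),
        within_factors=(("condition", k),) if k > 1 else (),
        cell_means=cells, within_correlation=corr,
    )
    reqs = []
    for rc in config["criterion"]:
        mode = rc.get("mode", "frequentist")
        threshold = rc.get("alpha" if mode == "frequentist" else "bf",
                           rc.get("threshold", 0.05 if mode == "frequentist" else 10.0))
        cells_idx = rc.get("cells")
        if cells_idx is not None:
            cells_idx = tuple(tuple(int(v) for v in pair) for pair in cells_idx)
        reqs.append(TestRequirement(
            test=rc["test"], effect=rc.get("effect"), cells=cells_idx,
            tails=int(rc.get("tails", 2)), mode=mode, threshold=float(threshold),
            polarity=rc.get("polarity", "must_pass"),
            direction=int(rc.get("direction", 1)),
        ))
    return Scenario(name=design.name, design=design,
                    criterion=SuccessCriterion(tuple(reqs)),
                    analysis=config["analysis"],
                    d=float(config.get("d", float("nan"))),
                    r=float(dcfg.get("correlation", 0.5))
                    if np.ndim(dcfg.get("correlation", 0.5)) == 0 else float("nan"),
                    mode=config.get("mode", "frequentist"))
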