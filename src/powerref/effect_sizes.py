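"""Effect-size algebra for paired and between-group comparisons.

Two standardized effect sizes coexist for repeated measures: dz (mean of
the difference scores over their SD — the quantity that drives paired-test
power) and dav (mean difference over the average condition SD — the
quantity comparable across between- and within-designs).  They are linked
through the correlation between conditions:

    dz = dav / sqrt(2 * (1 - r))

so dz = dav exactly at r = .5.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "dz_from_scores", "dav_from_scores", "dz_from_dav", "dav_from_dz",
    "d_from_t_paired", "d_from_eta2p", "f_from_d", "regression_rule_n",
]


def dz_from_scores(x, y) -> float:
    """dz: mean of the paired differences divided by their SD.

    Returns inf (flagged by the caller as degenerate) when the differences
    have zero variance but a nonzero mean.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return math.inf if d.mean() != 0 else 0.0
    return float(d.mean() / sd)


def dav_from_scores(x, y) -> float:
    """dav: mean difference over the arithmetic mean of the two SDs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    s = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    if s == 0:
        raise ValueError("zero variance in both conditions")
    return float((x.mean() - y.mean()) / s)


def dz_from_dav(dav: float, r: float) -> float:
    """dz = dav / sqrt(2(1 - r)); requires -1 < r < 1."""
    if not -1 < r < 1:
        raise ValueError("correlation must lie strictly in (-1, 1)")
    return dav / math.sqrt(2.0 * (1.0 - r))


def dav_from_dz(dz: float, r: float) -> float:
    """Inverse of :func:`dz_from_dav`: dav = dz * sqrt(2(1 - r))."""
    if not -1 < r < 1:
        raise ValueError("correlation must lie strictly in (-1, 1)")
    return dz * math.sqrt(2.0 * (1.0 - r))


def d_from_t_paired(t: float, n: int) -> float:
    """dz = t / sqrt(n) for a paired t statistic on n pairs."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    return t / math.sqrt(n)


def d_from_eta2p(eta2p: float, design: str) -> float:
    """Convert partial eta squared to d.

    ``design`` must be given explicitly: "between" uses
    d = 2*sqrt(eta2p/(1-eta2p)); "within" drops the factor 2 (paired
    observations are not independent, and the between formula would
    overestimate d by a factor of two).
    """
    if not 0 <= eta2p < 1:
        raise ValueError("eta2p must lie in [0, 1)")
    if design not in ("between", "within"):
        raise ValueError("design must be 'between' or 'within' (no default)")
    root = math.sqrt(eta2p / (1.0 - eta2p))
    return 2.0 * root if design == "between" else root


def f_from_d(d: float) -> float:
    """Cohen's f = d/2 for a two-group between contrast."""
    if d < 0:
        raise ValueError("d must be >= 0")
    return d / 2.0


def regression_rule_n(k_predictors: int) -> int:
    """Rule-of-thumb sample size for multiple regression: 100 + 100*k.

    Assumes predictor-criterion and predictor intercorrelations around .2
    and interest in the individual predictors.
    """
    if k_predictors < 1:
        raise ValueError("need at least 1 predictor")
    return 100 + 100 * int(k_predictors)
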