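"""Reliability of a dependent variable: intraclass correlations and the
Spearman-Brown prophecy.

ICC1 is the single-observation reliability from a one-way random-effects
decomposition (between-participant variance over total variance); ICC2 is
the reliability of the mean of k observations, which equals the
Spearman-Brown step-up of ICC1.  Balanced complete data use the closed-form
ANOVA estimator; data with missing observations fall back on REML variance
components (statsmodels MixedLM) with k set to the harmonic mean of the
per-participant counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityReport", "icc", "icc_by_condition",
    "spearman_brown", "required_multiplier", "required_observations",
]


@dataclass(frozen=True)
class ReliabilityReport:
    """Variance components and the two intraclass correlations."""

    icc1: float
    icc2: float
    k: float
    var_between: float
    var_within: float
    n_participants: int
    n_observations: int
    method: str
    icc1_untruncated: float

    def __repr__(self):
        return (f"ReliabilityReport(icc1={self.icc1:.3f}, "
                f"icc2={self.icc2:.3f}, k={self.k:.2f}, "
                f"method={self.method!r})")


def spearman_brown(r_indiv: float, n_multiplier: float) -> float:
    """Reliability of the average of n parallel observations.

    r_av = n*r / (1 + (n-1)*r); ``n_multiplier`` may be fractional.
    """
    if not -1 < r_indiv < 1:
        raise ValueError("r must lie strictly in (-1, 1)")
    if n_multiplier <= 0:
        raise ValueError("n must be positive")
    return n_multiplier * r_indiv / (1.0 + (n_multiplier - 1.0) * r_indiv)


def required_multiplier(r_observed: float, r_desired: float) -> float:
    """How many times more observations are needed to reach ``r_desired``.

    n = r_des*(1 - r_obs) / (r_obs*(1 - r_des)).  A value <= 1 simply
    documents that fewer observations would suffice.
    """
    if not 0 < r_observed < 1 or not 0 < r_desired < 1:
        raise ValueError("reliabilities must lie strictly in (0, 1)")
    return (r_desired * (1.0 - r_observed)) / (r_observed * (1.0 - r_desired))


def required_observations(r_observed: float, current_k: float,
                          r_desired: float = 0.8, safe: bool = False) -> int:
    """Observations per participant needed for the target reliability.

    Multiplies :func:`required_multiplier` (applied to the average-measure
    reliability ``r_observed``) by the current number of observations.
    Rounds to the nearest integer; ``safe=True`` takes the ceiling instead.
    """
    raw = required_multiplier(r_observed, r_desired) * current_k
    return int(np.ceil(raw)) if safe else int(round(raw))


def _check_long(long: pd.DataFrame) -> pd.DataFrame:
    need = {"Participant", "Response"}
    if not need.issubset(long.columns):
        raise ValueError("long table needs Participant and Response columns")
    df = long.dropna(subset=["Response"]).copy()
    counts = df.groupby("Participant")["Response"].size()
    if len(counts) < 2:
        raise ValueError("need at least 2 participants")
    if counts.max() < 2:
        raise ValueError("need at least 2 observations for some participant")
    return df


def _anova_icc(df: pd.DataFrame) -> tuple[float, float, float, int]:
    """Closed-form one-way ANOVA variance components (balanced data)."""
    g = df.groupby("Participant")["Response"]
    k = float(g.size().iloc[0])
    n = g.ngroups
    grand = df["Response"].mean()
    msb = k * ((g.mean() - grand) ** 2).sum() / (n - 1)
    msw = ((df["Response"] - g.transform("mean")) ** 2).sum() / (n * (k - 1))
    var_b = (msb - msw) / k
    return var_b, msw, k, n


def _reml_icc(df: pd.DataFrame) -> tuple[float, float, float, int]:
    """REML variance components tolerating missing observations."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("Response ~ 1", df,
                          groups=df["Participant"]).fit(reml=True)
    var_b = float(fit.cov_re.iloc[0, 0])
    var_w = float(fit.scale)
    counts = df.groupby("Participant")["Response"].size()
    k = len(counts) / (1.0 / counts).sum()  # harmonic mean
    return var_b, var_w, float(k), len(counts)


def icc(long: pd.DataFrame) -> ReliabilityReport:
    """One-way random-effects intraclass correlations from long data.

    Expects columns Participant and Response (rows with missing responses
    are dropped, matching the long-format convention where absent cells are
    simply left out).  ICC1 = var_between / (var_between + var_within);
    ICC2 steps ICC1 up by the (possibly fractional) number of observations
    per participant.  A negative between-participant variance estimate is
    truncated at zero with a warning; the untruncated ICC1 is reported
    alongside because genuinely negative condition correlations do occur.
    """
    df = _check_long(long)
    counts = df.groupby("Participant")["Response"].size()
    balanced = counts.nunique() == 1
    if balanced:
        var_b, var_w, k, n = _anova_icc(df)
        method = "anova"
    else:
        var_b, var_w, k, n = _reml_icc(df)
        method = "reml"
    if var_w == 0 and var_b == 0:
        raise ValueError("all responses identical: ICC undefined")
    icc1_raw = var_b / (var_b + var_w)
    if var_b < 0:
        warnings.warn("negative between-participant variance truncated at 0",
                      stacklevel=2)
        var_b = 0.0
    icc1 = var_b / (var_b + var_w) if (var_b + var_w) > 0 else 1.0
    icc2 = spearman_brown(icc1, k) if -1 < icc1 < 1 else icc1
    return ReliabilityReport(icc1=icc1, icc2=icc2, k=k, var_between=var_b,
                             var_within=var_w, n_participants=n,
                             n_observations=len(df), method=method,
                             icc1_untruncated=icc1_raw)


def icc_by_condition(long: pd.DataFrame):
    """Condition-wise and dataset-wide reliability, side by side.

    Requires a Condition column assigning each observation to a design
    condition.  Returns ``(per_condition, overall)`` where
    ``per_condition`` maps condition label to a :class:`ReliabilityReport`
    and ``overall`` is the report for the pooled dataset.  Conditions where
    no participant has two observations are skipped with a warning.  Both
    views are informative: a large group difference inflates the pooled
    ICC while range restriction deflates the within-condition ICCs, and
    negatively correlated conditions hurt the pooled estimate.
    """
    if "Condition" not in long.columns:
        raise ValueError("icc_by_condition needs a Condition column")
    per = {}
    for cond, sub in long.groupby("Condition", sort=False):
        try:
            per[cond] = icc(sub)
        except ValueError as exc:
            warnings.warn(f"condition {cond!r} skipped: {exc}", stacklevel=2)
    overall = icc(long)
    return per, overall
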