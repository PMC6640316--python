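"""Frequentist tests used by the simulation recipes.

All functions broadcast over leading axes: the last axis is always the
participant axis, so a ``(reps, n)`` array yields vectorized results for
``reps`` simulated studies at once.  Results carry the statistic, degrees
of freedom, two-tailed p, the one-tailed p in the expected direction, and
the relevant effect sizes.

Equal-variance (pooled) t statistics are used throughout: the simulated
designs are balanced and homoscedastic by construction.  The 2x2
repeated-measures and split-plot ANOVAs are computed by orthogonal-contrast
decomposition (each single-df effect is an exact paired/independent t
squared), which is both exact for balanced data and fast enough for
Monte-Carlo use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestResult", "paired_t", "independent_t", "pearson_test",
    "oneway_anova_between", "rm_anova_oneway", "rm_anova_2x2",
    "splitplot_anova_2x2", "ancova_posttest", "tost", "posthoc_battery",
]


@dataclass
class TestResult:
    """Outcome of one statistical test (scalar or vectorized)."""

    test: str
    statistic: np.ndarray | float
    df: tuple
    p_two: np.ndarray | float
    p_one: np.ndarray | float | None = None
    effect: dict = field(default_factory=dict)
    degenerate: np.ndarray | bool = False
    extra: dict = field(default_factory=dict)

    def passed(self, alpha: float, tails: int = 2):
        p = self.p_one if tails == 1 else self.p_two
        return (p < alpha) & ~np.asarray(self.degenerate, bool)


def _one_tailed(t, p_two, direction):
    """One-tailed p in the expected direction from t and the two-tailed p."""
    t = np.asarray(t, float)
    match = np.sign(t) * direction >= 0
    return np.where(match, np.asarray(p_two) / 2.0, 1.0 - np.asarray(p_two) / 2.0)


def paired_t(x, y, direction: int = 1) -> TestResult:
    """Student t test on paired differences ``x - y``.

    ``direction=+1`` means the mean difference is expected positive.  Also
    reports dz (difference-score effect size) and dav (mean-SD effect
    size).  Zero-variance differences give a degenerate flagged result
    instead of raising, so Monte-Carlo loops can count them.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    md = d.mean(-1)
    sd = d.std(-1, ddof=1)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, np.nan, sd)
    t = md / (sd_safe / np.sqrt(n))
    t = np.where(degenerate & (md == 0), 0.0, t)
    p2 = 2.0 * stats.t.sf(np.abs(t), n - 1)
    dz = np.where(degenerate & (md == 0), 0.0, md / sd_safe)
    dav = md / ((x.std(-1, ddof=1) + y.std(-1, ddof=1)) / 2.0)
    return TestResult("paired_t", t, (n - 1,), p2,
                      _one_tailed(t, p2, direction),
                      effect={"dz": dz, "dav": dav},
                      degenerate=degenerate)


def independent_t(g1, g2, direction: int = 1) -> TestResult:
    """Pooled-variance two-sample t test (``direction=+1``: g1 > g2)."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    n1, n2 = g1.shape[-1], g2.shape[-1]
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    v1 = g1.var(-1, ddof=1)
    v2 = g2.var(-1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    degenerate = sp2 == 0
    sp2 = np.where(degenerate, np.nan, sp2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (g1.mean(-1) - g2.mean(-1)) / se
    p2 = 2.0 * stats.t.sf(np.abs(t), df)
    d = (g1.mean(-1) - g2.mean(-1)) / np.sqrt(sp2)
    return TestResult("independent_t", t, (df,), p2,
                      _one_tailed(t, p2, direction),
                      effect={"d": d}, degenerate=degenerate)


def pearson_test(x, y, direction: int = 1) -> TestResult:
    """Pearson correlation with its t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.shape[-1]
    if n < 4:
        raise ValueError("need at least 4 pairs")
    xc = x - x.mean(-1, keepdims=True)
    yc = y - y.mean(-1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(-1) * (yc ** 2).sum(-1))
    degenerate = denom == 0
    r = (xc * yc).sum(-1) / np.where(degenerate, np.nan, denom)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p2 = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return TestResult("pearson", t, (n - 2,), p2,
                      _one_tailed(t, p2, direction),
                      effect={"r": r}, degenerate=degenerate)


def oneway_anova_between(groups) -> TestResult:
    """Fixed-effects one-way ANOVA over independent groups (balanced)."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = groups[0].shape[-1]
    if any(g.shape[-1] != n for g in groups):
        raise ValueError("groups must be balanced")
    if n < 2:
        raise ValueError("need at least 2 observations per group")
    means = np.stack([g.mean(-1) for g in groups])
    vars_ = np.stack([g.var(-1, ddof=1) for g in groups])
    grand = means.mean(0)
    msb = n * ((means - grand) ** 2).sum(0) / (k - 1)
    msw = vars_.mean(0)
    degenerate = msw == 0
    F = msb / np.where(degenerate, np.nan, msw)
    df = (k - 1, k * (n - 1))
    p = stats.f.sf(F, *df)
    ss_eff = msb * (k - 1)
    ss_err = msw * df[1]
    return TestResult("oneway_between", F, df, p,
                      effect={"eta2p": ss_eff / (ss_eff + ss_err)},
                      degenerate=degenerate)


def rm_anova_oneway(wide) -> TestResult:
    """One-way repeated-measures ANOVA.

    ``wide`` has shape (..., n, k): n participants by k conditions.  The
    treatment effect is tested against the subject-by-treatment error term;
    partial eta squared is reported.  No sphericity correction is applied
    (the simulated designs are compound-symmetric by construction).
    """
    X = np.asarray(wide, float)
    n, k = X.shape[-2], X.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 participants")
    grand = X.mean((-1, -2), keepdims=True)
    ss_subj = k * ((X.mean(-1) - grand[..., 0]) ** 2).sum(-1)
    ss_treat = n * ((X.mean(-2) - grand[..., 0, :]) ** 2).sum(-1)
    ss_tot = ((X - grand) ** 2).sum((-1, -2))
    ss_err = ss_tot - ss_subj - ss_treat
    df = (k - 1, (n - 1) * (k - 1))
    degenerate = ss_err == 0
    F = (ss_treat / df[0]) / np.where(degenerate, np.nan, ss_err / df[1])
    F = np.where(degenerate & (ss_treat == 0), 0.0, F)
    p = stats.f.sf(F, *df)
    return TestResult("rm_oneway", F, df, p,
                      effect={"eta2p": ss_treat / (ss_treat + ss_err)},
                      degenerate=degenerate)


def _contrast_t(X, weights, direction=1):
    """Paired t on a per-participant linear contrast of within cells."""
    c = np.tensordot(X, np.asarray(weights, float), axes=([-1], [0]))
    n = c.shape[-1]
    m = c.mean(-1)
    s = c.std(-1, ddof=1)
    degenerate = s == 0
    t = m / (np.where(degenerate, np.nan, s) / np.sqrt(n))
    t = np.where(degenerate & (m == 0), 0.0, t)
    p2 = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return TestResult("contrast", t, (n - 1,), p2, _one_tailed(t, p2, direction),
                      effect={"dz": np.where(degenerate & (m == 0), 0.0,
                                             m / np.where(degenerate, np.nan, s))},
                      degenerate=degenerate)


def rm_anova_2x2(wide) -> dict[str, TestResult]:
    """2x2 within-participants ANOVA by orthogonal contrasts.

    ``wide`` has shape (..., n, 4) with cells ordered A1B1, A1B2, A2B1,
    A2B2.  Each effect (A, B, AxB) is its contrast's paired t squared,
    tested against its own subject-interaction error term with (1, n-1)
    degrees of freedom — exact for balanced data.
    """
    X = np.asarray(wide, float)
    if X.shape[-1] != 4:
        raise ValueError("expected 4 within cells (A1B1, A1B2, A2B1, A2B2)")
    out = {}
    for label, w in (("A", (0.5, 0.5, -0.5, -0.5)),
                     ("B", (0.5, -0.5, 0.5, -0.5)),
                     ("AxB", (0.5, -0.5, -0.5, 0.5))):
        tres = _contrast_t(X, w)
        n = X.shape[-2]
        F = np.asarray(tres.statistic) ** 2
        out[label] = TestResult(f"rm2x2_{label}", F, (1, n - 1), tres.p_two,
                                tres.p_one,
                                effect={"eta2p": F / (F + (n - 1)),
                                        "dz": tres.effect["dz"]},
                                degenerate=tres.degenerate)
    return out


def splitplot_anova_2x2(g1, g2) -> dict[str, TestResult]:
    """Split-plot ANOVA: 2 groups x 2 within conditions.

    ``g1``/``g2`` have shape (..., n, 2).  The between effect is an
    independent t on participant means; the within and interaction effects
    are tests on participant difference scores with the error pooled over
    groups.  All three F values equal the corresponding t squared.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape[-1] != 2 or g2.shape[-1] != 2:
        raise ValueError("expected 2 within cells per group")
    n1, n2 = g1.shape[-2], g2.shape[-2]
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 participants per group")
    out = {}

    s1, s2 = g1.mean(-1), g2.mean(-1)
    tb = independent_t(s1, s2)
    out["between"] = TestResult("splitplot_between",
                                np.asarray(tb.statistic) ** 2,
                                (1, n1 + n2 - 2), tb.p_two, tb.p_one,
                                effect=tb.effect, degenerate=tb.degenerate)

    w1 = g1[..., 1] - g1[..., 0]
    w2 = g2[..., 1] - g2[..., 0]
    df = n1 + n2 - 2
    mse = ((n1 - 1) * w1.var(-1, ddof=1) + (n2 - 1) * w2.var(-1, ddof=1)) / df
    degenerate = mse == 0
    mse = np.where(degenerate, np.nan, mse)
    m1, m2 = w1.mean(-1), w2.mean(-1)

    tw = ((m1 + m2) / 2.0) / np.sqrt(mse / 4.0 * (1.0 / n1 + 1.0 / n2))
    tw = np.where(degenerate & (m1 + m2 == 0), 0.0, tw)
    p2w = 2.0 * stats.t.sf(np.abs(tw), df)
    out["within"] = TestResult("splitplot_within", tw ** 2, (1, df), p2w,
                               _one_tailed(tw, p2w, 1), degenerate=degenerate)

    ti = (m1 - m2) / np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
    ti = np.where(degenerate & (m1 == m2), 0.0, ti)
    p2i = 2.0 * stats.t.sf(np.abs(ti), df)
    out["interaction"] = TestResult("splitplot_interaction", ti ** 2, (1, df),
                                    p2i, _one_tailed(ti, p2i, 1),
                                    degenerate=degenerate)
    return out


def ancova_posttest(pre, post, group) -> TestResult:
    """One-way ANCOVA: group effect on the posttest adjusted for the pretest.

    Common-slope model (no group-by-pretest interaction); the group effect
    has (1, N-3) degrees of freedom.  ``group`` is a binary indicator of
    length N; arrays broadcast over leading axes.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    group = np.asarray(group, float)
    N = pre.shape[-1]
    if np.ptp(group) == 0:
        raise ValueError("need two groups")
    if pre.std() == 0:
        raise ValueError("pretest has zero variance")
    xc = pre - pre.mean(-1, keepdims=True)
    yc = post - post.mean(-1, keepdims=True)
    gc = group - group.mean(-1, keepdims=True)
    Sgg = (gc ** 2).sum(-1)
    Sgx = (gc * xc).sum(-1)
    Sxx = (xc ** 2).sum(-1)
    Sgy = (gc * yc).sum(-1)
    Sxy = (xc * yc).sum(-1)
    det = Sgg * Sxx - Sgx ** 2
    bg = (Sxx * Sgy - Sgx * Sxy) / det
    bx = (Sgg * Sxy - Sgx * Sgy) / det
    sse = (yc ** 2).sum(-1) - bg * Sgy - bx * Sxy
    df = N - 3
    mse = sse / df
    degenerate = mse <= 0
    t = bg / np.sqrt(np.where(degenerate, np.nan, mse) * Sxx / det)
    p2 = 2.0 * stats.t.sf(np.abs(t), df)
    return TestResult("ancova_group", t ** 2, (1, df), p2,
                      _one_tailed(t, p2, 1), degenerate=degenerate,
                      extra={"slope": bx, "group_coef": bg})


def tost(context: str, *, x=None, y=None, g1=None, g2=None,
         bounds: float = 0.2, alpha: float = 0.05) -> TestResult:
    """Two one-sided tests equivalence procedure.

    ``context`` is ``"paired"`` (standardized bounds on dz), ``"independent"``
    (bounds on d), or ``"correlation"`` (bounds on rho, Fisher-z tests).
    Equivalence is declared iff both one-sided tests reject at ``alpha``.
    ``bounds`` is the symmetric equivalence half-width (> 0).
    """
    if bounds <= 0:
        raise ValueError("equivalence bounds must straddle zero (bounds > 0)")
    if context == "paired":
        d = np.asarray(x, float) - np.asarray(y, float)
        n = d.shape[-1]
        se = d.std(-1, ddof=1) / np.sqrt(n)
        est = d.mean(-1) / d.std(-1, ddof=1)          # dz scale
        t_low = (d.mean(-1) + bounds * d.std(-1, ddof=1)) / se
        t_upp = (d.mean(-1) - bounds * d.std(-1, ddof=1)) / se
        df = n - 1
    elif context == "independent":
        g1 = np.asarray(g1, float)
        g2 = np.asarray(g2, float)
        n1, n2 = g1.shape[-1], g2.shape[-1]
        df = n1 + n2 - 2
        sp = np.sqrt(((n1 - 1) * g1.var(-1, ddof=1)
                      + (n2 - 1) * g2.var(-1, ddof=1)) / df)
        se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
        diff = g1.mean(-1) - g2.mean(-1)
        est = diff / sp
        t_low = (diff + bounds * sp) / se
        t_upp = (diff - bounds * sp) / se
    elif context == "correlation":
        res = pearson_test(x, y)
        r = res.effect["r"]
        n = np.asarray(x, float).shape[-1]
        se = 1.0 / np.sqrt(n - 3)
        z = np.arctanh(r)
        est = r
        z_low = (z - np.arctanh(-bounds)) / se
        z_upp = (z - np.arctanh(bounds)) / se
        p_low = stats.norm.sf(z_low)
        p_upp = stats.norm.cdf(z_upp)
        p = np.maximum(p_low, p_upp)
        return TestResult("tost_correlation", np.maximum(np.abs(z_low),
                                                         np.abs(z_upp)),
                          (np.inf,), p, p,
                          effect={"r": est},
                          extra={"equivalent": p < alpha,
                                 "p_lower": p_low, "p_upper": p_upp,
                                 "bounds": bounds})
    else:
        raise ValueError("context must be paired, independent or correlation")
    p_low = stats.t.sf(t_low, df)
    p_upp = stats.t.cdf(t_upp, df)
    p = np.maximum(p_low, p_upp)
    return TestResult(f"tost_{context}", np.where(np.abs(t_low) < np.abs(t_upp),
                                                  t_low, t_upp),
                      (df,), p, p, effect={"d": est},
                      extra={"equivalent": p < alpha, "p_lower": p_low,
                             "p_upper": p_upp, "bounds": bounds})


def posthoc_battery(dataset, contrasts, family_alpha: float = 0.05,
                    tails: int = 1):
    """Bonferroni-corrected battery of pairwise cell contrasts.

    ``dataset`` is a :class:`powerref.datagen.Dataset`; each contrast is a
    pair of (group index, within index) cell references, first cell
    expected larger.  Per-test alpha is ``family_alpha / len(contrasts)``.
    Returns a list of ``(TestResult, per_test_alpha, passed)`` triples.
    """
    if not contrasts:
        raise ValueError("empty contrast list")
    per_alpha = family_alpha / len(contrasts)
    out = []
    for (gi, wi), (gj, wj) in contrasts:
        data = dataset.data
        if gi == gj:
            res = paired_t(data[gi, :, wi], data[gj, :, wj])
        else:
            res = independent_t(data[gi, :, wi], data[gj, :, wj])
        out.append((res, per_alpha, bool(np.all(res.passed(per_alpha, tails)))))
    return out
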