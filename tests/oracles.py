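"""Independent brute-force oracles for the statistical battery.

Everything here is written from the textbook formulas: statistics by
hand, p-values by numerical integration of hand-written densities
(never by calling the same distribution routines the implementation
uses), so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def _t_pdf(x: float, nu: float) -> float:
    logc = (
        math.lgamma((nu + 1) / 2)
        - math.lgamma(nu / 2)
        - 0.5 * math.log(nu * math.pi)
    )
    return math.exp(logc - (nu + 1) / 2 * math.log1p(x * x / nu))


def t_two_sided_p(t: float, nu: float) -> float:
    tail, _ = quad(_t_pdf, abs(t), np.inf, args=(nu,), epsabs=1e-14, epsrel=1e-12)
    return min(1.0, 2.0 * tail)


def _f_pdf(x: float, d1: float, d2: float) -> float:
    if x <= 0:
        return 0.0
    logb = math.lgamma(d1 / 2) + math.lgamma(d2 / 2) - math.lgamma((d1 + d2) / 2)
    lognum = d1 * math.log(d1 * x) + d2 * math.log(d2) - (d1 + d2) * math.log(d1 * x + d2)
    return math.exp(0.5 * lognum - logb - math.log(x))


def f_upper_tail_p(F: float, d1: float, d2: float) -> float:
    tail, _ = quad(_f_pdf, F, np.inf, args=(d1, d2), epsabs=1e-14, epsrel=1e-12)
    return tail


def _chi2_pdf(x: float, k: float) -> float:
    if x <= 0:
        return 0.0
    logp = (k / 2 - 1) * math.log(x) - x / 2 - (k / 2) * math.log(2) - math.lgamma(k / 2)
    return math.exp(logp)


def chi2_upper_tail_p(stat: float, k: float) -> float:
    tail, _ = quad(_chi2_pdf, stat, np.inf, args=(k,), epsabs=1e-14, epsrel=1e-12)
    return tail


def welch_oracle(a, b) -> tuple[float, float, float]:
    """(t, df, two-sided p) from the raw Welch-Satterthwaite formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df, t_two_sided_p(t, df)


def f_test_oracle(a, b) -> tuple[float, tuple[float, float], float]:
    """Larger-over-smaller variance ratio with two-sided p by integration."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        F, df = va / vb, (len(a) - 1, len(b) - 1)
    else:
        F, df = vb / va, (len(b) - 1, len(a) - 1)
    return F, df, min(1.0, 2.0 * f_upper_tail_p(F, *df))


def nested_anova_oracle(groups1, groups2) -> tuple[float, float, float]:
    """t derived from a balanced two-level nested ANOVA.

    ``groups*`` are lists of per-individual recording lists (all the
    same length).  The treatment mean square is tested against the
    individuals-within-treatment mean square; t = sign(diff) * sqrt(F)
    with the individuals df.
    """
    r = len(groups1[0])
    assert all(len(g) == r for g in groups1 + groups2), "oracle requires balance"
    m1 = np.array([np.mean(g) for g in groups1])
    m2 = np.array([np.mean(g) for g in groups2])
    a1, a2 = len(m1), len(m2)
    grand = (m1.sum() + m2.sum()) / (a1 + a2)
    ss_treat = r * (a1 * (m1.mean() - grand) ** 2 + a2 * (m2.mean() - grand) ** 2)
    ms_treat = ss_treat / 1.0
    ss_ind = r * (((m1 - m1.mean()) ** 2).sum() + ((m2 - m2.mean()) ** 2).sum())
    df_ind = (a1 - 1) + (a2 - 1)
    ms_ind = ss_ind / df_ind
    F = ms_treat / ms_ind
    t = math.copysign(math.sqrt(F), m1.mean() - m2.mean())
    return t, df_ind, t_two_sided_p(t, df_ind)


def chisq_oracle(observed, proportions) -> tuple[float, float, float]:
    """Direct sum((O-E)^2/E) with upper-tail p by integration."""
    obs = np.asarray(observed, float)
    props = np.asarray(proportions, float)
    props = props / props.sum()
    expected = props * obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    return stat, df, chi2_upper_tail_p(stat, df)
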