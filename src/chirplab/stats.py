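"""Statistical comparisons between treatment groups of song summaries.

The battery used to compare illumination treatments (e.g. a 12h:12h
light:dark regime against constant light):

- :func:`welch_t_test` — unequal-variance t for overall means;
- :func:`variance_f_test` — F ratio of sample variances;
- :func:`check_normality_and_transform` — Shapiro–Wilk check with a
  log → sqrt transform ladder;
- :func:`nested_t_test` — recordings nested within individuals are
  collapsed to one mean per individual before a two-sample t, so
  repeated recordings of the same animal never inflate the sample size
  (pseudoreplication immunity);
- :func:`chisq_gof` — chi-square goodness of fit of observed
  syllable-count proportions against expected ones.

All p-values are two-sided except the chi-square upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_direction: int
    method_name: str
    transform_applied: str | None = None

    def to_dict(self) -> dict[str, object]:
        return {
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "effect_direction": self.effect_direction,
            "method_name": self.method_name,
            "transform_applied": self.transform_applied,
        }


@dataclass
class NestedSample:
    """One treatment group: per-recording values nested within individuals."""

    treatment_label: str
    individuals: list[tuple[str, list[float]]]

    def __post_init__(self) -> None:
        for ind_id, values in self.individuals:
            if len(values) == 0:
                raise ValueError(f"individual {ind_id!r} has no recordings")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"individual {ind_id!r} has non-finite values")

    def individual_means(self) -> np.ndarray:
        return np.array([np.mean(v) for _, v in self.individuals])

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        value_column: str,
        individual_column: str,
        treatment_label: str = "",
    ) -> "NestedSample":
        if individual_column not in df.columns:
            raise KeyError(
                f"column {individual_column!r} not found; available: {list(df.columns)}"
            )
        if value_column not in df.columns:
            raise KeyError(
                f"column {value_column!r} not found; available: {list(df.columns)}"
            )
        groups = [
            (str(ind), sub[value_column].dropna().tolist())
            for ind, sub in df.groupby(individual_column, sort=True)
        ]
        return cls(treatment_label=treatment_label, individuals=groups)


def _direction(a: np.ndarray, b: np.ndarray) -> int:
    diff = float(np.mean(a) - np.mean(b))
    return int(np.sign(diff))


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Welch t-test (unequal variances), two-sided.

    Degenerate inputs where both groups have zero variance follow the
    convention: equal means give t = 0, p = 1; unequal means give an
    infinite statistic with p = 0, flagged in ``method_name``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(len(x) + len(y) - 2), 1.0, 0, "welch_t (degenerate)")
        sign = _direction(x, y)
        return TestResult(
            math.inf * sign, float(len(x) + len(y) - 2), 0.0, sign, "welch_t (degenerate)"
        )
    res = sst.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        effect_direction=_direction(x, y),
        method_name="welch_t",
    )


def variance_f_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """F-test for equality of variances, two-sided.

    Convention: F is the larger sample variance over the smaller (so
    F >= 1 and the result is invariant to argument order), degrees of
    freedom ordered accordingly, p = min(1, 2 * upper-tail).
    ``effect_direction`` is the sign of var(a) - var(b).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both variances are zero; F undefined")
    if vx >= vy:
        F, df = vx / vy if vy > 0 else math.inf, (len(x) - 1, len(y) - 1)
    else:
        F, df = vy / vx if vx > 0 else math.inf, (len(y) - 1, len(x) - 1)
    p = min(1.0, 2.0 * float(sst.f.sf(F, df[0], df[1]))) if math.isfinite(F) else 0.0
    return TestResult(
        statistic=float(F),
        df=(float(df[0]), float(df[1])),
        p_value=p,
        effect_direction=int(np.sign(vx - vy)),
        method_name="variance_f",
    )


def check_normality_and_transform(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, str]:
    """Shapiro–Wilk normality check with a log → sqrt transform ladder.

    Returns the (possibly transformed) values and a record of what was
    applied: ``"none"`` if the raw data pass at ``alpha``, else the
    first of ``"log"`` (strictly positive data only) or ``"sqrt"``
    (non-negative data only) whose transform passes, else ``"failed"``
    with the original values.  Constant data have no defined normality
    and are flagged ``"failed"``.  Apply the same recorded transform to
    both groups of a comparison (see :func:`apply_transform`).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("normality check needs at least 3 values")
    if np.ptp(x) == 0.0:
        return x, "failed"
    if sst.shapiro(x).pvalue >= alpha:
        return x, "none"
    if np.all(x > 0):
        logged = np.log(x)
        if np.ptp(logged) > 0 and sst.shapiro(logged).pvalue >= alpha:
            return logged, "log"
    if np.all(x >= 0):
        rooted = np.sqrt(x)
        if np.ptp(rooted) > 0 and sst.shapiro(rooted).pvalue >= alpha:
            return rooted, "sqrt"
    return x, "failed"


def apply_transform(values: Sequence[float], transform: str) -> np.ndarray:
    """Apply a transform recorded by :func:`check_normality_and_transform`."""
    x = np.asarray(values, dtype=float)
    if transform in ("none", "failed"):
        return x
    if transform == "log":
        return np.log(x)
    if transform == "sqrt":
        return np.sqrt(x)
    raise ValueError(f"unknown transform {transform!r}")


def nested_t_test(g1: NestedSample, g2: NestedSample) -> TestResult:
    """Nested (hierarchical) t-test of two treatments.

    Recordings are subsamples; individuals are the biological
    replicates.  Each individual's recordings are collapsed to one mean
    and the treatments are compared with an equal-variance two-sample t
    on those means, df = n1 + n2 - 2.  For balanced designs this equals
    the t derived from a nested ANOVA (tested against that oracle in the
    suite); duplicating recordings within an individual cannot change
    the result.
    """
    m1 = g1.individual_means()
    m2 = g2.individual_means()
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError(
            "nested t-test needs at least 2 individuals per treatment "
            "(individual-level variance is undefined otherwise)"
        )
    res = sst.ttest_ind(m1, m2, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(m1) + len(m2) - 2),
        p_value=float(res.pvalue),
        effect_direction=_direction(m1, m2),
        method_name="nested_t",
    )


def chisq_gof(
    observed: Sequence[float] | Mapping[int, float],
    expected_proportions: Sequence[float] | Mapping[int, float],
) -> TestResult:
    """Chi-square goodness of fit of observed counts vs expected proportions.

    ``statistic = sum((O_i - E_i)^2 / E_i)`` with ``E_i = p_i * sum(O)``,
    df = k - 1, upper-tail p.  Proportions are normalized to sum to 1,
    so any uniform scaling of them is irrelevant.  Non-integer counts
    are accepted (the formula is well-defined on non-negative reals,
    e.g. counts reconstructed from printed percentages).  A zero
    expected proportion is an error unless its observed count is also
    zero, in which case the cell contributes nothing.
    """
    if isinstance(observed, Mapping):
        keys = sorted(set(observed) | set(expected_proportions if isinstance(expected_proportions, Mapping) else []))
        obs = np.array([observed.get(k, 0.0) for k in keys], dtype=float)
        if isinstance(expected_proportions, Mapping):
            props = np.array([expected_proportions.get(k, 0.0) for k in keys], dtype=float)
        else:
            props = np.asarray(expected_proportions, dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
        props = np.asarray(expected_proportions, dtype=float)
    if len(obs) != len(props):
        raise ValueError("observed and expected have different lengths")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed counts sum to zero")
    psum = props.sum()
    if psum <= 0:
        raise ValueError("expected proportions sum to zero")
    props = props / psum
    if np.any((props == 0) & (obs > 0)):
        raise ValueError("zero expected proportion with nonzero observed count")
    expected = props * total
    nonzero = expected > 0
    stat = float(np.sum((obs[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]))
    df = len(obs) - 1
    p = float(sst.chi2.sf(stat, df))
    return TestResult(
        statistic=stat,
        df=float(df),
        p_value=p,
        effect_direction=0,
        method_name="chisq_gof",
    )
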