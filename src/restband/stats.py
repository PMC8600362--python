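"""Univariate group statistics: t tests, effect sizes, 2x2 mixed ANOVA.

The comparisons mirror a classic two-group (young vs older), two-eye-condition
(closed vs open) resting-EEG design:

* independent-samples Student t (pooled variance, df = n1 + n2 - 2) with
  Cohen's d_s = (m1 - m2) / s_pooled;
* paired-samples t with Cohen's d_z = mean(diff) / sd(diff) = t / sqrt(n);
* a 2x2 mixed-design (split-plot) ANOVA with one between-subjects factor and
  one repeated measure, reporting partial eta squared per effect.

No multiple-comparison correction is applied anywhere, by design.

The effect-size conversion helpers (``ds_from_t``, ``dz_from_t``,
``etasq_from_f``) operate on printed summary statistics, so published t and F
values can be turned into effect sizes without the raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "TTestResult",
    "AnovaEffect",
    "AnovaResult",
    "independent_t",
    "paired_t",
    "mixed_anova_2x2",
    "ds_from_t",
    "dz_from_t",
    "etasq_from_f",
]


@dataclass(frozen=True)
class SummaryStats:
    """Group summary (n, mean, sd) as printed in a results section."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("SummaryStats requires n >= 2")
        if self.sd < 0:
            raise ValueError("SummaryStats requires sd >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    effect: float  # d_s for independent, d_z for paired
    effect_name: str


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    eta2p: float


@dataclass(frozen=True)
class AnovaResult:
    """Effects of a 2x2 mixed design: group, condition, group x condition."""

    group: AnovaEffect
    condition: AnovaEffect
    interaction: AnovaEffect


GroupData = Union[SummaryStats, Sequence, np.ndarray]


def _as_summary(x: GroupData) -> SummaryStats:
    if isinstance(x, SummaryStats):
        return x
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("raw group data must be a 1-d array with n >= 2")
    return SummaryStats(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def independent_t(a: GroupData, b: GroupData) -> TTestResult:
    """Pooled-variance Student t between two groups, with Cohen's d_s.

    Accepts either raw value arrays or :class:`SummaryStats`; both routes
    give identical results because the Student t depends on the data only
    through (n, mean, sd).
    """
    sa, sb = _as_summary(a), _as_summary(b)
    df = sa.n + sb.n - 2
    pooled_var = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
    if pooled_var == 0.0:
        raise ZeroDivisionError("zero pooled variance: t statistic undefined")
    pooled_sd = math.sqrt(pooled_var)
    t = (sa.mean - sb.mean) / (pooled_sd * math.sqrt(1.0 / sa.n + 1.0 / sb.n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    d_s = (sa.mean - sb.mean) / pooled_sd
    return TTestResult(t=float(t), df=df, p=p, effect=float(d_s), effect_name="d_s")


def paired_t(x: Sequence, y: Sequence) -> TTestResult:
    """Paired t on x - y with Cohen's d_z = mean(diff) / sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):  # identical samples: no effect, by convention t = 0
            return TTestResult(t=0.0, df=n - 1, p=1.0, effect=0.0, effect_name="d_z")
        raise ZeroDivisionError("zero variance of paired differences: t undefined")
    t = diff.mean() / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, effect=float(diff.mean() / sd), effect_name="d_z")


def mixed_anova_2x2(
    closed: Mapping, open_: Mapping, group: Mapping
) -> AnovaResult:
    """2x2 mixed-design ANOVA (one between factor, one repeated measure).

    Parameters
    ----------
    closed, open_
        Mapping subject id -> value in the eyes-closed / eyes-open condition.
        Every subject must appear in both.
    group
        Mapping subject id -> group label (exactly two distinct labels).

    Notes
    -----
    The 2x2 split-plot decomposes exactly into two independent strata built
    from per-subject sums and differences:

    * between-subjects stratum (subject means): group main effect;
    * within-subjects stratum (condition differences): condition main effect
      and the group x condition interaction.

    With unequal group sizes the condition main effect tests the *unweighted*
    mean of the two groups' condition effects (SPSS Type-III convention).
    Partial eta squared is SS_effect / (SS_effect + SS_error) of the stratum.
    """
    subjects = sorted(closed)
    if sorted(open_) != subjects or sorted(group) != subjects:
        raise ValueError("every subject must have both conditions and a group label")
    labels = sorted(set(group.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g = np.array([group[s] == labels[1] for s in subjects])  # boolean indicator
    yc = np.array([closed[s] for s in subjects], dtype=float)
    yo = np.array([open_[s] for s in subjects], dtype=float)
    n0, n1 = int((~g).sum()), int(g.sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    N = n0 + n1
    df_den = N - 2

    # --- between-subjects stratum: subject means -------------------------
    m = (yc + yo) / 2.0
    m0, m1 = m[~g].mean(), m[g].mean()
    gm = m.mean()  # weighted grand mean
    ss_group = 2.0 * (n0 * (m0 - gm) ** 2 + n1 * (m1 - gm) ** 2)
    ss_err_between = 2.0 * (((m[~g] - m0) ** 2).sum() + ((m[g] - m1) ** 2).sum())

    # --- within-subjects stratum: condition differences ------------------
    d = yc - yo
    d0, d1 = d[~g].mean(), d[g].mean()
    ss_err_within = 0.5 * (((d[~g] - d0) ** 2).sum() + ((d[g] - d1) ** 2).sum())
    # harmonic-mean cell weight: Type III (unweighted marginal means)
    nh = 2.0 / (1.0 / n0 + 1.0 / n1)
    ss_condition = 0.5 * nh * ((d0 + d1) / 2.0) ** 2 * 2.0
    ss_interaction = 0.5 * nh * ((d0 - d1) / 2.0) ** 2 * 2.0

    def effect(ss_eff: float, ss_err: float) -> AnovaEffect:
        if ss_err == 0.0:
            F = 0.0 if ss_eff == 0.0 else math.inf
        else:
            F = (ss_eff / 1.0) / (ss_err / df_den)
        p = float(sps.f.sf(F, 1, df_den)) if math.isfinite(F) else 0.0
        denom = ss_eff + ss_err
        eta = ss_eff / denom if denom > 0 else 0.0
        return AnovaEffect(F=float(F), df_num=1, df_den=df_den, p=p, eta2p=float(eta))

    return AnovaResult(
        group=effect(ss_group, ss_err_between),
        condition=effect(ss_condition, ss_err_within),
        interaction=effect(ss_interaction, ss_err_within),
    )


def ds_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d_s from an independent-samples t: t * sqrt((n1+n2)/(n1*n2))."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be positive")
    return float(t * math.sqrt((n1 + n2) / (n1 * n2)))


def dz_from_t(t: float, n: int) -> float:
    """Cohen's d_z from a paired-samples t: t / sqrt(n)."""
    if n < 1:
        raise ValueError("sample size must be positive")
    return float(t / math.sqrt(n))


def etasq_from_f(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from F: F*df_num / (F*df_num + df_den)."""
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be positive")
    return float(F * df_num / (F * df_num + df_den))
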