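"""Technical error of measurement (TEM) and derived reliability statistics.

The TEM is the standard deviation of replicate measurements of the same
unchanged subject, pooled over subjects — the within-subject error SD,
in the units of the measurement.  For g groups of replicates with group
sizes k_i,

    TEM = sqrt( sum_i sum_j (x_ij - xbar_i)^2 / sum_i (k_i - 1) )

i.e. the square root of the one-way ANOVA within-group mean square.  For
all-pairs data (every k_i = 2) this reduces exactly to the classical
two-measurement form sqrt(sum d_i^2 / 2N), and for balanced designs to
the classical multi-rater formula; the pooled form additionally handles
the unbalanced case where each volunteer is measured by a different
number of raters.

Derived statistics:

* **relative TEM (%TEM)** = 100 * TEM / mean, a scale-free error useful
  for comparing parameters of different magnitude;
* **coefficient of reliability** R = 1 - TEM^2 / SD^2, the proportion of
  observed between-subject variance not attributable to measurement
  error (SD is the standard deviation of the observations in the
  stratum);
* an **F-comparison** of two TEMs, F = TEM_a^2 / TEM_b^2 against the F
  distribution on the two pooled-variance degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import ReplicateGroupSet, Stratum

__all__ = [
    "pooled_tem",
    "relative_tem",
    "coefficient_of_reliability",
    "compare_tem",
    "reliability_result",
    "ReliabilityResult",
    "TemComparison",
]


def pooled_tem(groups: ReplicateGroupSet) -> float:
    """Pooled technical error of measurement over replicate groups.

    Returns NaN for an empty group set (the undefined marker).  A group
    with fewer than two replicates is a caller error: the views are
    responsible for filtering incomplete groups.
    """
    if groups.n_groups == 0:
        return float("nan")
    ss = 0.0
    df = 0
    for _, values in groups.groups:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(
                f"replicate group with {v.size} value(s); every group needs k >= 2"
            )
        ss += float(np.sum((v - v.mean()) ** 2))
        df += v.size - 1
    return math.sqrt(ss / df)


def relative_tem(tem: float, grand_mean: float) -> float:
    """%TEM = 100 * TEM / mean of the measurements."""
    if not grand_mean > 0:
        raise ValueError(f"grand_mean must be positive, got {grand_mean!r}")
    return 100.0 * tem / grand_mean


def coefficient_of_reliability(tem: float, between_subject_sd: float) -> float:
    """R = 1 - TEM^2 / SD^2.

    May be negative when the measurement error exceeds the between-
    subject spread; negative values are returned as computed (with a
    warning) rather than truncated, since truncation would hide
    pathological strata.  ``between_subject_sd == 0`` yields NaN.
    """
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be non-negative")
    if between_subject_sd == 0:
        warnings.warn("zero between-subject SD: coefficient of reliability undefined")
        return float("nan")
    r = 1.0 - tem**2 / between_subject_sd**2
    if r < 0:
        warnings.warn(f"negative coefficient of reliability ({r:.4f}): error exceeds between-subject spread")
    return r


@dataclass
class TemComparison:
    """F-comparison of two pooled TEMs.

    ``f_stat = (tem_a / tem_b)^2`` referred to an F distribution on the
    pooled-variance error degrees of freedom of the two estimates
    (``sum_i (k_i - 1)`` for each group set), with a two-sided p-value.
    Under equal error variances and normal errors this pivot is exact,
    so null p-values are uniform.
    """

    f_stat: float
    p_value: float
    df1: int
    df2: int
    tem_a: float
    tem_b: float
    direction: str = ""


def compare_tem(tem_a: float, df_a: int, tem_b: float, df_b: int) -> TemComparison:
    """Compare two TEMs by their variance ratio.

    Parameters
    ----------
    tem_a, tem_b
        The two pooled TEMs (group a is the numerator).
    df_a, df_b
        Error degrees of freedom of each TEM estimate: ``sum_i (k_i - 1)``
        over that group set (``ReplicateGroupSet.error_df``).  Callers
        wanting a different df convention pass it here.
    """
    if df_a < 1 or df_b < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not (tem_a > 0) or not (tem_b > 0):
        return TemComparison(float("nan"), float("nan"), df_a, df_b, tem_a, tem_b,
                             direction="undefined: zero or invalid TEM")
    f = (tem_a / tem_b) ** 2
    dist = stats.f(df_a, df_b)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    p = min(p, 1.0)
    if tem_a < tem_b:
        direction = "a lower error than b"
    elif tem_a > tem_b:
        direction = "a higher error than b"
    else:
        direction = "equal"
    return TemComparison(f, p, int(df_a), int(df_b), tem_a, tem_b, direction)


@dataclass
class ReliabilityResult:
    """TEM-family statistics for one (parameter, stratum, mode) cell.

    The identities ``pct_tem == 100 * tem / grand_mean`` and
    ``r_coef == 1 - tem^2 / between_subject_sd^2`` hold exactly in every
    emitted result; ``icc`` is filled in by the one-way ICC estimator.
    Undefined statistics are NaN.
    """

    mode: str
    parameter: str
    stratum: Stratum
    n: int
    n_groups: int
    grand_mean: float
    between_subject_sd: float
    tem: float
    pct_tem: float
    r_coef: float
    icc: float = float("nan")

    @property
    def defined(self) -> bool:
        return self.n > 0 and not math.isnan(self.tem)


def reliability_result(groups: ReplicateGroupSet) -> ReliabilityResult:
    """Compute n, TEM, %TEM and R for one replicate group set.

    The %TEM denominator and the between-subject SD both use exactly the
    observations entering the TEM computation (all values of the group
    set), so every statistic in the result refers to the same data.
    An empty set yields a row of undefined markers rather than an error.
    """
    if groups.n_groups == 0:
        return ReliabilityResult(
            mode=groups.mode, parameter=groups.parameter, stratum=groups.stratum,
            n=0, n_groups=0, grand_mean=float("nan"), between_subject_sd=float("nan"),
            tem=float("nan"), pct_tem=float("nan"), r_coef=float("nan"),
        )
    values = groups.values()
    tem = pooled_tem(groups)
    grand_mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    pct = relative_tem(tem, grand_mean)
    if sd and not math.isnan(sd) and sd > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = coefficient_of_reliability(tem, sd)
    else:
        r = float("nan")
    return ReliabilityResult(
        mode=groups.mode, parameter=groups.parameter, stratum=groups.stratum,
        n=groups.n_obs, n_groups=groups.n_groups, grand_mean=grand_mean,
        between_subject_sd=sd, tem=tem, pct_tem=pct, r_coef=r,
    )
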