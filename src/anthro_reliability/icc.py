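"""One-way random-effects intraclass correlation for unbalanced groups.

The one-way model treats each replicate measurement of subject i as

    x_ij = mu + a_i + e_ij,   a_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2)

with no rater effect distinguishable from residual error — the right
model when each subject is rated by an arbitrary, possibly different,
set of raters.  The single-rater ICC is sigma_b^2 / (sigma_b^2 + sigma_w^2),
estimated from the one-way ANOVA mean squares with Searle's effective
group size k0 for unbalanced data:

    ICC = (MSB - MSW) / (MSB + (k0 - 1) * MSW),
    k0  = (M - sum k_i^2 / M) / (g - 1),    M = sum k_i, g = number of groups.

For balanced designs (all k_i = k) k0 = k and the estimator is the
textbook ICC(1,1).  Because missingness in a subjects-by-raters layout
only changes the group sizes under the one-way model, operating on
grouped replicates handles missing cells with no imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .records import ReplicateGroupSet

__all__ = ["AnovaComponents", "anova_components", "icc_oneway"]


@dataclass
class AnovaComponents:
    """One-way ANOVA decomposition of a replicate group set."""

    msb: float  # between-group mean square
    msw: float  # within-group mean square (= pooled TEM squared)
    k0: float   # Searle effective group size
    n_groups: int
    n_obs: int


def anova_components(groups: ReplicateGroupSet) -> AnovaComponents:
    """Between/within mean squares and Searle's k0 for possibly unbalanced groups.

    Requires at least two groups, each with k_i >= 2 (single-replicate
    groups carry no within-group information and must be filtered
    upstream).
    """
    g = groups.n_groups
    if g < 2:
        raise ValueError(f"need >= 2 replicate groups for an ANOVA decomposition, got {g}")
    sizes = groups.group_sizes()
    if (sizes < 2).any():
        raise ValueError("every replicate group needs k >= 2")
    values = groups.values()
    M = int(sizes.sum())
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for _, v in groups.groups:
        v = np.asarray(v, dtype=float)
        m = v.mean()
        ssb += v.size * (m - grand) ** 2
        ssw += float(np.sum((v - m) ** 2))
    msb = ssb / (g - 1)
    msw = ssw / (M - g)
    k0 = (M - float(np.sum(sizes.astype(float) ** 2)) / M) / (g - 1)
    return AnovaComponents(msb=msb, msw=msw, k0=k0, n_groups=g, n_obs=M)


def icc_oneway(groups: ReplicateGroupSet) -> float:
    """Single-rater one-way random-effects ICC of a replicate group set.

    May be negative (lower bound -1/(k0 - 1)); negative estimates are
    returned as computed.  All-identical data (MSB = MSW = 0) yields NaN
    with a warning.
    """
    comp = anova_components(groups)
    denom = comp.msb + (comp.k0 - 1.0) * comp.msw
    if denom == 0:
        warnings.warn("no variance at all in the replicate groups: ICC undefined")
        return float("nan")
    icc = (comp.msb - comp.msw) / denom
    if icc < 0:
        warnings.warn(f"negative ICC estimate ({icc:.4f})")
    return icc
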