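"""Bland-Altman agreement analysis for standardisation exercises.

Two constructions:

* **intra-rater** — for each (volunteer, rater) pair, the difference
  between the two rounds (round 2 minus round 1 by default) against the
  mean of the two rounds;
* **inter-rater** — for each volunteer and each of their raters, the
  difference between that rater's first measurement and the mean of all
  included first measurements of the volunteer, against that mean.
  Because each point's reference is the volunteer's own mean, the
  per-volunteer differences sum to zero and the overall bias is zero by
  construction; the spread of the limits is the informative part.

The bias is the mean difference with a t-based 95% CI; the limits of
agreement (LoA) are bias +/- ``loa_multiplier`` standard deviations of
the differences (multiplier 2 by default, the convention of field
anthropometry exercises; 1.96 is available via the argument).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .records import ReplicateGroupSet

__all__ = [
    "AgreementResult",
    "bland_altman_intra",
    "bland_altman_inter",
    "loa_coverage",
    "plot_agreement",
    "points_to_csv",
]


@dataclass
class AgreementResult:
    """Bland-Altman summary: bias, its CI, SD of differences and LoA.

    ``points`` holds (x = mean-axis value, y = difference) pairs so the
    plot and the within-limits proportion can be recomputed from the
    result alone.
    """

    mode: str
    parameter: str
    n_points: int
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa: tuple[float, float]
    loa_multiplier: float
    prop_within_loa: float
    points: np.ndarray  # shape (n, 2): columns (x, y)
    warnings: list[str] = field(default_factory=list)
    stratum_label: str = ""


def _summarise(
    x: np.ndarray,
    y: np.ndarray,
    *,
    mode: str,
    parameter: str,
    loa_multiplier: float,
) -> AgreementResult:
    n = y.size
    bias = float(y.mean())
    sd = float(y.std(ddof=1)) if n > 1 else 0.0
    warns: list[str] = []
    if sd == 0.0:
        warns.append("zero SD of differences: degenerate limits of agreement")
        ci = (bias, bias)
    else:
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci = (bias - half, bias + half)
    loa = (bias - loa_multiplier * sd, bias + loa_multiplier * sd)
    within = float(np.mean((y >= loa[0]) & (y <= loa[1])))
    return AgreementResult(
        mode=mode, parameter=parameter, n_points=n, bias=bias, bias_ci=ci,
        sd_diff=sd, loa=loa, loa_multiplier=loa_multiplier,
        prop_within_loa=within, points=np.column_stack([x, y]), warnings=warns,
    )


def bland_altman_intra(
    pairs: ReplicateGroupSet,
    *,
    sign: str = "r2-r1",
    loa_multiplier: float = 2.0,
) -> AgreementResult:
    """Bland-Altman analysis of round-1 vs round-2 measurements.

    ``sign="r2-r1"`` (default) plots round2 - round1; ``"r1-r2"`` flips
    the convention (the bias changes sign, the LoA width does not).
    Needs at least two complete pairs.
    """
    if pairs.mode != "intra":
        raise ValueError("bland_altman_intra needs an intra-rater group set")
    if sign not in ("r2-r1", "r1-r2"):
        raise ValueError("sign must be 'r2-r1' or 'r1-r2'")
    if pairs.n_groups < 2:
        raise ValueError(f"need >= 2 complete pairs, got {pairs.n_groups}")
    arr = np.array([v for _, v in pairs.groups], dtype=float)  # (n, 2)
    diffs = arr[:, 1] - arr[:, 0] if sign == "r2-r1" else arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    return _summarise(means, diffs, mode="intra", parameter=pairs.parameter,
                      loa_multiplier=loa_multiplier)


def bland_altman_inter(
    groups: ReplicateGroupSet,
    *,
    loa_multiplier: float = 2.0,
) -> AgreementResult:
    """Bland-Altman analysis of each rater's first measurement against the
    volunteer mean.

    For volunteer i with first-round measurements x_i1..x_ik, each rater
    contributes the point (xbar_i, x_ij - xbar_i).  The overall bias is
    structurally zero; the result records it (and its CI) anyway so the
    same reporting path serves both constructions.
    """
    if groups.mode != "inter":
        raise ValueError("bland_altman_inter needs an inter-rater group set")
    if groups.n_groups < 1:
        raise ValueError("empty group set")
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for _, v in groups.groups:
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            raise ValueError("every volunteer needs >= 2 raters in the inter view")
        m = v.mean()
        xs.append(np.full(v.size, m))
        ys.append(v - m)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return _summarise(x, y, mode="inter", parameter=groups.parameter,
                      loa_multiplier=loa_multiplier)


def loa_coverage(result: AgreementResult) -> float:
    """Fraction of stored points whose difference lies within the LoA."""
    if result.n_points < 1:
        raise ValueError("no points")
    y = result.points[:, 1]
    lo, hi = result.loa
    return float(np.mean((y >= lo) & (y <= hi)))


def plot_agreement(result: AgreementResult, path: str | Path | None = None, *, title: str | None = None):
    """Render the Bland-Altman scatter with bias, CI band and LoA lines.

    Returns the matplotlib figure; saves to ``path`` (PNG/SVG by
    extension) when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.points[:, 0], result.points[:, 1], s=12, alpha=0.6, edgecolors="none")
    ax.axhline(result.bias, color="tab:blue", lw=1.2, label=f"bias {result.bias:+.3f}")
    ax.axhspan(result.bias_ci[0], result.bias_ci[1], color="tab:blue", alpha=0.15)
    for lim, lab in zip(result.loa, ("lower LoA", "upper LoA")):
        ax.axhline(lim, color="tab:red", lw=1.0, ls="--", label=f"{lab} {lim:+.3f}")
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference")
    ax.set_title(title or f"{result.parameter} ({result.mode}-rater), n={result.n_points}")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def points_to_csv(result: AgreementResult, path: str | Path) -> None:
    """Dump the (x, y) points as a two-column CSV for external plotting."""
    np.savetxt(path, result.points, delimiter=",", header="mean,difference", comments="")
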