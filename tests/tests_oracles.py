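"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package:
the ANOVA decomposition goes through a least-squares fit of a cell-means
model (statsmodels OLS), the balanced single-rater ICC through pingouin,
and Searle's effective group size through a from-scratch transcription
of the formula.  None of them share code with ``anthro_reliability``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def anova_oneway_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """(between, within) mean squares via an OLS fit of group indicators."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    long = pd.DataFrame(
        {
            "g": np.repeat([f"g{i}" for i in range(len(groups))], [len(v) for v in groups]),
            "y": np.concatenate([np.asarray(v, dtype=float) for v in groups]),
        }
    )
    fit = ols("y ~ C(g)", data=long).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    msb = float(table.loc["C(g)", "sum_sq"] / table.loc["C(g)", "df"])
    msw = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    return msb, msw


def icc1_balanced_oracle(obs: np.ndarray) -> float:
    """ICC(1,1) of a balanced subjects x raters matrix, via pingouin."""
    import pingouin as pg

    n, k = obs.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "y": np.asarray(obs, dtype=float).ravel(),
        }
    )
    res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="y")
    return float(res.loc[res["Type"] == "ICC(1,1)", "ICC"].iloc[0])


def searle_k0_oracle(groups: list[list[float]]) -> float:
    """Effective group size for the unbalanced one-way model,
    k0 = (M - sum k_i^2 / M) / (g - 1), transcribed from scratch."""
    sizes = [len(v) for v in groups]
    M = sum(sizes)
    g = len(sizes)
    return (M - sum(k * k for k in sizes) / M) / (g - 1)
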