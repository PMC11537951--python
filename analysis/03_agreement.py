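"""Bland-Altman agreement analyses of the simulated exercise.

For every parameter x rater group, both constructions: round-2 minus
round-1 differences (intra-rater) and each rater's first measurement
minus the volunteer mean (inter-rater), with bias, 95% CI, 2-SD limits
of agreement and the proportion of points within the limits.  Writes a
summary table to results/ and one scatter per stratum to
results/figures/ (PNG, regenerate at will).
"""

from pathlib import Path

import pandas as pd

from anthro_reliability.agreement import plot_agreement
from anthro_reliability.pipeline import run_agreement_analyses
from anthro_reliability.records import validate
from anthro_reliability.synth import study_like_dataset

SEED = 2022
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGURES = RESULTS / "figures"


def main() -> None:
    FIGURES.mkdir(parents=True, exist_ok=True)
    df, _ = study_like_dataset(SEED)
    df, _ = validate(df)
    results = run_agreement_analyses(df)

    rows = []
    for res in results:
        rows.append(
            {
                "parameter": res.parameter, "mode": res.mode, "stratum": res.stratum_label,
                "n_points": res.n_points, "bias": res.bias,
                "bias_ci_low": res.bias_ci[0], "bias_ci_high": res.bias_ci[1],
                "sd_diff": res.sd_diff, "loa_low": res.loa[0], "loa_high": res.loa[1],
                "prop_within_loa": res.prop_within_loa,
                "bias_significant": not (res.bias_ci[0] <= 0.0 <= res.bias_ci[1]),
            }
        )
        name = f"ba_{res.parameter}_{res.mode}_{res.stratum_label.replace('/', '_')}.png"
        plot_agreement(res, FIGURES / name)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "agreement_stats.csv", index=False)
    print(f"agreement summary -> {RESULTS / 'agreement_stats.csv'}")
    print(f"{len(results)} plots -> {FIGURES}/")

    print("\nBland-Altman summary (intra-rater):")
    intra = summary[summary["mode"] == "intra"]
    print(intra[["parameter", "stratum", "n_points", "bias", "sd_diff",
                 "prop_within_loa", "bias_significant"]].round(3).to_string(index=False))
    worst = summary["prop_within_loa"].min()
    print(f"\nminimum proportion of points within the 2-SD limits: {worst:.3f}")
    n_sig = int(summary["bias_significant"].sum())
    print(f"strata with bias 95% CI excluding zero: {n_sig}/{len(summary)}")


if __name__ == "__main__":
    main()
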