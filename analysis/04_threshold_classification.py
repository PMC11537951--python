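"""Classify the simulated exercise against published acceptability cutoffs.

Applies the built-in threshold sets — %TEM < 2.0 for weight and
length/height, the beginner/experienced %TEM standards for adult
anthropometrists, and ICC/R > 0.90 ("excellent") — to every report row
and tallies pass/fail per rule.
"""

from pathlib import Path

import pandas as pd

from anthro_reliability.pipeline import AnalysisConfig, run_reliability_report
from anthro_reliability.records import validate
from anthro_reliability.synth import study_like_dataset

SEED = 2022
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    df, _ = study_like_dataset(SEED)
    df, _ = validate(df)
    config = AnalysisConfig(
        threshold_sets=("carsley2019", "perini_beginner", "perini_experienced", "icc_excellent")
    )
    report = run_reliability_report(df, config)
    cls = report.classifications
    cls.to_csv(RESULTS / "threshold_classifications.csv", index=False)
    print(f"classification table -> {RESULTS / 'threshold_classifications.csv'}")

    tally = (
        cls.groupby(["threshold_set", "rule", "passed"]).size().unstack(fill_value=0)
    )
    print("\nPass/fail tally per rule (rows = rule, columns = outcome):")
    print(tally.to_string())

    fails = cls[(cls["passed"] == "false")]
    if len(fails):
        print("\nFailing cells:")
        print(fails[["parameter", "rater_group", "age_group", "mode", "rule",
                     "observed", "cutoff"]].round(3).to_string(index=False))
    else:
        print("\nNo failing cells.")


if __name__ == "__main__":
    main()
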