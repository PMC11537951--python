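"""Generate the synthetic standardisation exercise analysed by the later steps.

The exercise follows the two-tier design of a multi-site survey
training: 12 site-lead pairs measuring 15 shared volunteers and 46
fieldworker pairs measuring 75 volunteers, five anthropometric
parameters, two rounds per rater, 2-11 raters per volunteer.  The full
measurement table (a few thousand rows) goes to scratch/; the small
design-summary and ground-truth tables go to results/.
"""

from pathlib import Path

from anthro_reliability.records import validate, write_measurements
from anthro_reliability.synth import study_like_dataset

SEED = 2022  # shared by all analysis steps

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    df, truth = study_like_dataset(SEED)
    df, report = validate(df)
    print("Simulated standardisation exercise")
    print(report.summary())

    write_measurements(df, SCRATCH / "synthetic_measurements.csv")
    print(f"\nfull table -> {SCRATCH / 'synthetic_measurements.csv'}")

    design = (
        df.groupby(["rater_group", "age_group"])
        .agg(volunteers=("volunteer_id", "nunique"), raters=("rater_id", "nunique"),
             observations=("value", "size"))
        .reset_index()
    )
    design.to_csv(RESULTS / "design_summary.csv", index=False)
    truth.as_frame().to_csv(RESULTS / "ground_truth.csv", index=False)
    print(f"design summary -> {RESULTS / 'design_summary.csv'}")
    print(f"generating variance components -> {RESULTS / 'ground_truth.csv'}")

    k = (
        df[df["round"] == 1]
        .groupby(["parameter", "volunteer_id"])["rater_id"].nunique()
    )
    print(f"\nraters per volunteer: min {k.min()}, median {k.median():.0f}, max {k.max()}")


if __name__ == "__main__":
    main()
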