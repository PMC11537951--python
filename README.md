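# anthro-reliability

Reliability assessment for anthropometric measurements in survey
training ("standardisation") exercises: before fieldworkers measure
thousands of survey participants, they repeatedly measure a small pool
of volunteers, and those repeats are summarised into measurement-error
statistics that say whether the team is ready.

This package implements the complete statistical chain for such an
exercise — for survey methodologists, nutrition epidemiologists and
anyone running anthropometry quality control:

* **Technical error of measurement (TEM)** — the pooled within-subject
  error SD.  For groups of replicate measurements with sizes $k_i$,

  $$\mathrm{TEM} = \sqrt{\frac{\sum_i \sum_j (x_{ij} - \bar x_i)^2}{\sum_i (k_i - 1)}}$$

  which reduces exactly to the classical $\sqrt{\sum d^2 / 2N}$ for
  duplicate measurements and handles the unbalanced case (each
  volunteer measured by a different number of raters).
* **Relative TEM** ($\%\mathrm{TEM} = 100\cdot\mathrm{TEM}/\bar x$) and the
  **coefficient of reliability** ($R = 1 - \mathrm{TEM}^2/SD^2$).
* **One-way random-effects ICC** (single-rater) on unbalanced replicate
  groups, using Searle's effective group size
  $k_0 = (M - \sum k_i^2/M)/(g-1)$.
* **F-comparison** of two rater groups' TEMs,
  $F = \mathrm{TEM}_a^2/\mathrm{TEM}_b^2$ on the pooled-variance degrees
  of freedom.
* **Bland-Altman agreement**, in both the intra-rater (round 2 vs
  round 1) and inter-rater (each rater vs the volunteer mean)
  constructions, with 2-SD limits of agreement.
* A **stratified report pipeline** (per parameter, rater group and
  volunteer age group) and **acceptability-threshold classification**
  against published cutoffs.
* A **synthetic-exercise generator** with known variance components,
  used throughout the tests to show that the estimators recover the
  generating parameters.

Measurements are weight (kg), length/height, mid-upper-arm, waist and
calf circumference (cm); raters are "site leads" (trainer
anthropometrists) and "fieldworkers" (trained two-person teams); each
rater measures each volunteer twice.  Intra-rater statistics use both
rounds; inter-rater statistics use first-round measurements only, and
volunteers measured by a single rater are excluded from them.

## Worked example

```python
from anthro_reliability import (
    study_like_dataset, validate, run_reliability_report, write_report,
)

records, truth = study_like_dataset(seed=2022)   # simulated exercise
records, report = validate(records)
table = run_reliability_report(records)
print(table.rows[table.rows.age_group == "all"].head(4).round(3).to_string(index=False))
```

prints (abridged):

```
    parameter rater_group age_group  n_volunteers  inter_n  inter_tem  inter_pct_tem  inter_r  inter_icc  intra_n  intra_tem  intra_pct_tem  intra_r  intra_icc
       weight   site_lead       all            15       72      0.056          0.200    1.000      1.000      144      0.063          0.227    1.000      1.000
       weight fieldworker       all            75      306      0.229          0.725    1.000      1.000      612      0.193          0.613    1.000      1.000
length_height   site_lead       all            15       72      0.562          0.461    1.000      1.000      144      0.523          0.429    1.000      1.000
length_height fieldworker       all            75      306      1.013          0.885    0.999      0.999      612      0.902          0.788    0.999      0.999
```

Reading a row: 75 volunteers were measured for weight by fieldworkers;
the 306 first-round measurements give an inter-rater TEM of 0.229 kg —
a typical repeat differs from another rater's measurement of the same
person by about a quarter of a kilogram — which is 0.73% of the mean
weight, and both R and the ICC round to 1.000 because between-person
variation dwarfs this error.  The intra-rater TEM (0.193 kg, both
rounds, 612 observations) is smaller, as repeats by the same rater
agree better than measurements by different raters.

The same chain runs from the shell:

```sh
anthro-reliability simulate --seed 2022 --out exercise.csv
anthro-reliability analyze --input exercise.csv --out report/
```

or as the numbered analysis scripts under `analysis/` (simulate ->
reliability report -> Bland-Altman -> threshold classification), which
write their tables under `results/`.

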