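# Methods

## The measurement model

A standardisation exercise yields observations

$$x_{v,r,t} = \mu_v + b_r + \varepsilon_{v,r,t},$$

where $\mu_v$ is volunteer $v$'s true value, $b_r$ a systematic offset
of rater $r$ (technique, equipment handling) and $\varepsilon$
independent measurement error; $t \in \{1,2\}$ indexes the two rounds.
All reliability statistics in the package are moments of this model
estimated from two replicate structures:

* **intra-rater groups** — the two rounds of one (volunteer, rater)
  pair; the within-group SD estimates $\sigma_e$ (rater offsets cancel);
* **inter-rater groups** — the first-round measurements of all raters
  on one volunteer; the within-group SD estimates
  $\sqrt{\sigma_r^2 + \sigma_e^2}$.

Using only first-round measurements for inter-rater analysis keeps the
two observations per rater from entering one group as pseudo-replicates;
volunteers measured by a single rater carry no between-rater information
and are excluded from the inter-rater view (and reported).

## Estimators

**TEM.** The pooled within-group variance
$\mathrm{TEM}^2 = \sum_i\sum_j (x_{ij}-\bar x_i)^2 / \sum_i (k_i-1)$ is
the one-way ANOVA within mean square. This generalisation was chosen
over the classical fixed-$K$ formula because the design is unbalanced
(2–11 raters per volunteer); it reduces exactly to the classical
two-measurement form $\sqrt{\sum d^2/2N}$ and to the balanced
multi-rater form, both asserted in tests.

**%TEM and R.** $\%\mathrm{TEM} = 100\,\mathrm{TEM}/\bar x$ and
$R = 1 - \mathrm{TEM}^2/SD^2$, where $\bar x$ and $SD$ are the mean and
SD of exactly the observations entering that cell's TEM. Denominator
conventions vary in the literature (first-round only vs all
measurements, per-volunteer-mean SD vs observation SD); computing all
three statistics from one observation set keeps every report cell
internally consistent, and the identities hold exactly (same
floating-point expression) in every emitted row. Negative $R$
(error exceeding between-subject spread) is reported with a warning,
never truncated, because truncation hides pathological strata.

**One-way ICC.** The single-rater intraclass correlation
$(\,\mathrm{MSB}-\mathrm{MSW})/(\mathrm{MSB}+(k_0-1)\mathrm{MSW})$ with
Searle's $k_0 = (M-\sum k_i^2/M)/(g-1)$ for unbalanced groups. The
one-way model is the right choice here because rater identity is not
crossed with volunteers (each volunteer meets an arbitrary subset of
raters), which also means "missing cells" in a subjects-by-raters
matrix reduce to unequal group sizes — no imputation needed. Balanced
designs reproduce the textbook ICC(1,1) (cross-checked against an
independent implementation); intra-rater ICC treats each
(volunteer, rater) pair as a group of two rounds. Negative estimates
(bounded below by $-1/(k_0-1)$) are reported as computed.

**F-comparison of TEMs.** $F = \mathrm{TEM}_a^2/\mathrm{TEM}_b^2$
referred to $F(\nu_a, \nu_b)$ with $\nu = \sum_i (k_i-1)$, the degrees
of freedom of each pooled variance, and a two-sided p-value
$2\min(P(F\le f), P(F\ge f))$. With these $\nu$ the statistic is an
exact pivot under equal error variances, so null p-values are uniform —
the calibration property the test suite checks. Conventions based on
observation counts ($n-1$) appear in the applied literature; callers
can reproduce them by passing any degrees of freedom they prefer, but
the default is the calibrated choice.

**Bland-Altman.** Intra-rater: difference round 2 − round 1 (the sign
convention is a flag; the width of the limits is invariant) against the
pair mean. Inter-rater: each rater's first measurement minus the mean
of the volunteer's included first-round measurements, against that mean;
since each point's reference is the group's own mean, per-volunteer
differences sum to zero and the overall bias is structurally zero —
asserted at 1e-10 as a regression test. Bias CI uses the
$t_{n-1}$ quantile. Limits of agreement are bias ± 2·SD of differences;
the multiplier 2 (not 1.96) is the convention of field anthropometry
exercises and is configurable. Degenerate zero-SD strata yield
equal limits plus a warning, never NaN.

## Age strata and report layout

Ages map to three strata: [0, 2) years, [2, 12] and (12, ∞). The
verbal labels these strata carry in survey protocols ("0–2", "2–12",
">12") overlap at the boundaries; the package fixes the convention that
2-year-olds and 12-year-olds are in the middle group (">12" read
literally) and makes the boundaries configurable. Weight,
length/height and MUAC are age-stratified by default; waist and calf
circumference are measured in adolescents/adults only under the survey
protocol, so stratifying them would duplicate the whole-sample row
(config-driven, not hard-coded). Report CSVs carry full precision;
the markdown rendering rounds to 3 decimals and prints undefined
statistics as "NA".

## Input validation

Duplicate (volunteer, rater, parameter, round) keys are fatal by
default with an opt-in keep-first mode; averaging duplicates is never
offered because it would bias the TEM downward. Values off the
instrument grid (0.01 kg for scales, 0.1 cm for boards and tapes,
tolerance 1e-9) are warnings, not errors — unit conversions legitimately
produce them. Unparseable rows are collected with row numbers, never
silently dropped.

## The synthetic generator

`generate_dataset` draws from the measurement model above —
$\mu_v \sim N(\mu_{pop}, \sigma_b^2)$, $b_r \sim N(0, \sigma_r^2)$,
$\varepsilon \sim N(0, \sigma_e^2)$ — then rounds to the instrument
grid. The number of raters per volunteer follows a discrete
distribution on 2..11 with median 4, matching the design of a training
exercise where every volunteer is measured by a handful of the teams
present. Ground truth returned with each dataset gives the population
TEM ($\sigma_e$ intra-rater, $\sqrt{\sigma_r^2+\sigma_e^2}$
inter-rater) and reliabilities
$\rho = \sigma_b^2/(\sigma_b^2+\sigma_r^2+\sigma_e^2)$ and
$\rho_{intra} = (\sigma_b^2+\sigma_r^2)/(\sigma_b^2+\sigma_r^2+\sigma_e^2)$.

The `study_like_dataset` preset reproduces the design shape of a
two-tier national-survey exercise: 12 site-lead pairs sharing 15
volunteers and 46 fieldworker pairs sharing 75 volunteers (5 and
27/26/22 per age stratum respectively), five parameters, two rounds.
Its anthropometric means and SDs (infant weight ~9 kg, adult height
~165 cm, adult waist ~85 cm, ...) are package constants chosen once as
plausible for a general population — the preset emulates a design, not
any particular survey's data. Error SDs are larger for fieldworkers
than site leads (less prior anthropometry experience), infant length
error is doubled (restless infants, length-board technique), and small
per-rater offsets ($\sigma_r > 0$) produce the inter > intra error
ordering real exercises show.

What the generator does **not** emulate: digit preference and heaping,
transcription errors, heteroscedastic error within a stratum,
volunteer-specific difficulty, inter-site differences. Passing
parameter-recovery tests therefore shows the estimators are correct
under the assumed variance-components model, not that real exercises
satisfy that model.

## Problem sizes and numerical choices

The validation suite uses sizes at which Monte-Carlo error is well
inside the asserted bands: 200 random instances for the TEM/ANOVA
equivalence (tolerance 1e-12 relative, the estimators are algebraically
identical), 500–1,000 volunteers for parameter recovery (TEM asserted
within ±0.02 of $\sigma_e=0.3$, ICC within ±0.01 of 0.990), 10,000
differences for the 2-SD coverage band [0.94, 0.97] (normal expectation
0.9545), and 2,000 simulated exercises for the F-calibration
Kolmogorov–Smirnov bound of 0.05 (the 5% critical value at that size is
0.030). Degenerate inputs (all-identical values, empty strata,
single-rater volunteers) yield NaN markers plus warnings rather than
exceptions, so one bad stratum never aborts a report.

## Known limitations

* Measurement *accuracy* (closeness to a gold standard) is out of
  scope; all statistics here are about agreement between repeats.
* The TEM F-comparison assumes independent normal errors with equal
  variance within each group; heavy-tailed error inflates its type-I
  rate.
* Thresholds ship as published (%TEM cutoffs for weight/height only,
  ICC/R > 0.9); there are no published %TEM norms for circumference
  measurements, which the classification output leaves visible as
  unlabelled cells.
* The one-way ICC deliberately ignores rater identity; a two-way model
  (consistency or absolute agreement with fixed raters) is a different
  design and is not provided.
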