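# vfhome

Analysis pipeline for **home visual-field (VF) monitoring** in glaucoma:
agreement and variability statistics for longitudinal perimetry records from
two devices (an in-clinic standard automated perimeter and a head-mounted
home perimeter), plus a Monte-Carlo simulator that quantifies how testing
frequency, measurement repeatability and imperfect patient compliance
translate into the time needed to detect glaucomatous VF progression.

It is written for clinical researchers evaluating tele-perimetry programmes
and for methodologists studying progression-detection power.

## The statistics at the core

For repeated measurements x₁…xₙ of one VF index (mean deviation MD in dB,
or the visual field index VFI in %) of a perimetrically stable eye:

* **Intertest variability** — RMSE over all ordered pairs,
  `RMSE = sqrt( Σ_{i≠j} (x_i − x_j)² / M )` with `M = n(n−1)`;
  algebraically `√2 ×` the sample SD.
* **Repeatability coefficient** over N eyes with k repeats each,
  `RC = 1.96 · sqrt( (1/N) Σ_i 2·Var(x_i) )` — the 95% bound on the
  absolute difference between two repeated measurements under no change.
* **Progression rate** — OLS slope of the index on time (years), with
  `SE_β = sqrt( SSR / (n−2) / Σ(t_i − t̄)² )` and a two-sided t test;
  progression is flagged when the MD slope is negative with p < 0.05.
* **Bland-Altman** limits of agreement (mean difference ± 1.96 SD) on
  per-eye paired device means.

The simulator generates MD trajectories `md(t) = md₀ + β·t + ε`,
`ε ~ N(0, σ²)` with `σ = RC/(1.96·√2)`, on a semiannual clinic schedule or
a fortnightly (2 tests/month) home schedule thinned by compliance
trajectories drawn from a pool calibrated to observed adherence decay, and
reports sensitivity, specificity and the time to detect 80% of progressing
eyes per true rate β ∈ {−0.5, −1, −1.5, −2} dB/year.

## Worked example

```sh
vfhome synth --n-patients 25 --seed 7 --out vf_tests.csv
vfhome stats --tests vf_tests.csv --index md --out report.json
vfhome compliance --tests vf_tests.csv
vfhome detection-times --seed 1 --n 2000 --out detection_times.csv
```

`stats` reports (for the synthetic cohort above): a reliability rate of
0.829 — the fraction of tests with false positives < 20%, false negatives
< 20% and fixation losses < 33% — a home-minus-clinic MD mean difference of
0.12 dB with 95% limits of agreement [−1.08, 1.33] dB, and a Pearson r of
0.985 between per-eye device means.  `compliance` prints a retention rate
of 0.72 (18 of 25 enrolled patients ever tested at home) and per-6-month
compliance fractions.  `detection-times` chains pool → simulate → detect
for both schedules and writes:

```
schedule,rate_db_per_year,time_to_80pct_years
home,-0.5,3.75
home,-1.0,2.37
home,-1.5,1.77
home,-2.0,1.38
clinic,-0.5,6.46
clinic,-1.0,4.4
clinic,-1.5,3.42
clinic,-2.0,2.93
```

i.e. fortnightly home testing — even with decaying compliance — roughly
halves the follow-up needed to detect 80% of progressing eyes relative to
semiannual clinic perimetry, at a specificity held near 97%.

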