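# Methods

## Data model

One row per perimetry test of one eye on one device: MD (dB), PSD (dB),
VFI (%), and the three reliability indices (false-positive rate,
false-negative rate, fixation losses, %).  Time is integer days since the
patient's first test; a month is 30.4375 days, a year 365.25 days, and
compliance windows are half-open `[start, end)` in days — no real-calendar
arithmetic anywhere.  A bilateral home session produces one record per eye
on the same day and counts as **one** test event for retention/compliance
purposes.  Reliability screening uses strict inequalities
(fp < 20%, fn < 20%, fl < 33%); boundary values fail.

## Estimators

* Pairwise RMSE is computed literally over all `M = n(n−1)` ordered pairs
  (series are short); the identity `RMSE = √2 · SD` is asserted in tests to
  1e-12 rather than used as the implementation.
* RC uses the unbiased (n−1) variance per series and averages `2·Var`
  across eyes (the eye, not the patient, is the repeat unit).
* Trend fits are OLS of index on time in years; the slope SE comes from
  the residual sum of squares with n−2 df and p-values from the t
  distribution (not the normal), two-sided.  A zero-residual fit gets
  SE = 0 and p = 0 for a nonzero slope, p = 1 for a flat one; a slope
  tolerance of 1e-9 index-units/year absorbs floating-point cancellation
  so constant noiseless series are never flagged.
* Bland-Altman operates on per-eye averages with both eyes pooled; the
  inter-eye correlation within patients is ignored, a deliberate
  simplification that slightly understates the variance of the limits of
  agreement.  Pearson r is reported as undefined when either side is
  constant.

## Noise model

Per-test measurement error is homoscedastic Gaussian with
`σ = RC / (1.96·√2)` — the unique per-test SD consistent with a given
repeatability coefficient when repeats are independent.  Defaults: MD RC
3.4 dB (clinic device) and 3.0 dB (home device) for the cohort generator;
the progression simulator uses 3.3 dB and 2.9 dB, the values the simulated
devices are required to reproduce (verified by recomputing RC on simulated
stable repeats, 500 eyes × 10 tests, within 3%).  Whether real VF noise
grows with damage severity is not modelled; homoscedasticity is the
documented simplification.

## Synthetic cohort

25 patients × 2 eyes by default.  True stable MD per eye is drawn from a
normal(−5.2, 4.2²) dB truncated to [−14.8, 1.7] dB.  VFI and PSD are given
plausible monotone mappings of MD (VFI ≈ 100 + 2.5·MD %, PSD ≈ 2 +
0.55·|MD| dB) — convenience scales for exercising the pipeline, not fitted
models.  Device offsets (home − clinic): +0.12 dB MD, +1.92% VFI,
+0.06 dB PSD.  A fixed retention fraction (0.72) of patients ever test at
home; the rest contribute clinic records only.

Reliability indices are drawn from a lapse mixture: with probability
1 − pass-rate (home 0.17, clinic 0.14) a test is an attention lapse whose
fixation-loss rate is uniform on [34, 50]% (failing the screen); otherwise
indices come from Beta distributions whose means are set so the overall
means match the emulated study (fp 4.7/3.7%, fn 5.0/3.1%, fl 9.6/12.3%
for home/clinic).  A pure Beta marginal cannot produce a 14–17% exceedance
of the screening bounds while keeping means this small — the tail of any
fixed-mean Beta is bounded by the mean — so the mixture is structural, not
cosmetic.

## Compliance pool

Adherence enters the simulation as piecewise-constant 2-month trajectories
of retention probability relative to the nominal fortnightly schedule.
The pool is a mixture over ten archetypes (sustained compliers, gradual
decliners, early faders) whose weights are fitted by non-negative least
squares so that the pool's exact binomial probabilities of a member taking
≥1 and ≥2 tests/month in each 6-month block match the observed study
marginals (≥1/mo: 83/67/56/44%; ≥2/mo: 67/44/33/11%) within ±5 points.
Weights become integer counts by largest-remainder rounding; calibration
failure raises an error reporting achieved vs. target fractions.

Two deliberate choices where the construction is underdetermined by the
period marginals:

* **Faders end at small nonzero rates (0.10–0.15) rather than zero.**
  Beyond the 2-year calibration span the final rate is held, so a hard
  zero would freeze a member's information forever and cap attainable
  sensitivity below 80% for slow progression; sporadic continued testing
  is both the more realistic reading of lapsed participants and the only
  one consistent with 80% detection ever being reached on the home
  schedule.
* **Rates are capped at 1** (the thinning probability of a scheduled
  test).  Real cohorts contain over-testers (>2 tests/month), which a
  thinned fixed schedule cannot represent; consequently the pool's implied
  mean frequency (~1.3 tests/month) sits below the ~1.6 observed in
  practice.  This biases the simulation slightly against the home
  schedule, i.e. conservatively.

## Progression simulation and detection

Sequences follow `md(t) = md₀ + β·t + ε` with β constant, on a semiannual
(0.5-year) or fortnightly (24/year; 26/year available) schedule starting
at t = 0.  Thinning is Bernoulli per scheduled test with the period's
compliance probability — this preserves the expected deleted fraction and
stays reproducible from the seed, unlike deleting an exact rounded count —
and the baseline test is always retained (enrolment is supervised).
Values are clamped to the instrument range [−35, 10] dB; clamp events are
counted on each sequence.

Detection at horizon h uses all tests with t ≤ h and flags a sequence when
n ≥ 3 (the minimum for a defined slope SE), the OLS slope is negative and
the two-sided p < 0.05.  The negative-slope gate makes the nominal test
conservative, so specificity sits near 97.5% rather than 95%.  Evaluation
is **pointwise per horizon** (each horizon is an independent look), which
matches specificity being maintained near 95% across horizons; an
uncorrected sequential "ever flagged" mode is provided for comparison but
inflates false positives.  Time-to-80% is the linearly interpolated first
upward crossing of the sensitivity curve on a 0.1-year grid from 0.5 years;
a jump out of zero sensitivity (the 3-test legality boundary) is not
interpolated, and a level never reached is reported as null, never as a
large number.

All randomness derives from one seed through named substreams
(`(seed, domain, rate-index, sequence-index)`), so any single sequence is
reproducible in isolation and batches are composition-independent.

## Problem sizes

Headline results use 2000 simulated sequences per progression rate and a
pool of 1000 trajectories — enough that the Monte-Carlo SE of a
sensitivity is ≈0.01 and detection times are stable to ≈±0.1 years across
seeds — and 500 eyes × 10 repeats for repeatability recovery.  Parameter-
recovery checks on the synthetic cohort use 250 patients (500 eyes).

## Limitations

Pointwise 24-2 sensitivities, nonlinear or episodic progression, severity-
dependent noise, learning effects, seasonal patterns and real-calendar
scheduling are out of scope.  The compliance pool reproduces period
marginals, not individual patients' observed trajectories; the synthetic
cohort demonstrates estimator correctness and parameter recovery, not the
behaviour of any real population.
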