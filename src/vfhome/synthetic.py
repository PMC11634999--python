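"""Synthetic study-like cohorts and compliance-trajectory pools.

The generator emulates the statistical structure of a two-year home
visual-field monitoring study on perimetrically stable glaucoma patients:

* initial MD drawn from a truncated normal (mean -5.2 dB, SD 4.2 dB,
  range [-14.8, 1.7] dB);
* clinic tests every 6 months on the standard perimeter, home tests
  nominally fortnightly (2 per month) on the portable device;
* homoscedastic Gaussian per-test noise with SD = RC / (1.96 * sqrt(2)),
  the unique per-test SD consistent with a printed repeatability
  coefficient (3.4 dB clinic MD, 3.0 dB home MD);
* small fixed device offsets (home minus clinic: +0.12 dB MD, +1.92% VFI);
* testing compliance that decays over the follow-up, drawn from a pool of
  piecewise-constant 2-month trajectories calibrated so the pool's
  fractions meeting 1 and 2 tests/month per 6-month block match the
  observed study marginals;
* reliability indices drawn so that roughly 83% of home and 86% of clinic
  tests pass the <20%/<20%/<33% screening criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from ._rng import DOMAIN_COHORT, DOMAIN_POOL, substream
from .agreement import noise_sd_from_rc
from .exceptions import CalibrationError, InsufficientDataError, ValidationError
from .records import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    MD_BOUNDS_DB,
    Device,
    Eye,
    Setting,
    VFTestRecord,
)

# ---------------------------------------------------------------------------
# Compliance trajectories


@dataclass(frozen=True)
class ComplianceTrajectory:
    """Per-period testing-compliance fractions for one participant.

    ``rates[i]`` is the probability that a nominally scheduled test in
    period ``i`` (periods of ``period_months`` months) is actually taken.
    Beyond the last period the final rate is held; after ``dropout_period``
    (when set) the rate is zero.
    """

    rates: tuple
    period_months: float = 2.0
    dropout_period: Optional[int] = None

    def __post_init__(self):
        r = tuple(float(x) for x in self.rates)
        if not r:
            raise ValidationError("rates must be non-empty", field="rates")
        if any(not (0.0 <= x <= 1.0) for x in r):
            raise ValidationError("rates must lie in [0, 1]", field="rates")
        if self.period_months <= 0:
            raise ValidationError("must be positive", field="period_months")
        object.__setattr__(self, "rates", r)

    def rate_at(self, t_years: float) -> float:
        idx = int(math.floor(t_years * 12.0 / self.period_months))
        if self.dropout_period is not None and idx > self.dropout_period:
            return 0.0
        if idx >= len(self.rates):
            idx = len(self.rates) - 1
        return self.rates[idx]


@dataclass(frozen=True)
class ComplianceTargets:
    """Per-6-month-block calibration targets for the trajectory pool:
    fraction of participants taking >=1 and >=2 tests per month."""

    ge1_per_block: tuple = (0.83, 0.67, 0.56, 0.44)
    ge2_per_block: tuple = (0.67, 0.44, 0.33, 0.11)

    def __post_init__(self):
        g1 = tuple(float(x) for x in self.ge1_per_block)
        g2 = tuple(float(x) for x in self.ge2_per_block)
        if len(g1) != len(g2) or not g1:
            raise ValidationError("target rows must be non-empty and equal "
                                  "length")
        if any(not (0 <= x <= 1) for x in g1 + g2):
            raise ValidationError("targets must lie in [0, 1]")
        if any(b > a for a, b in zip(g1, g2)):
            raise ValidationError(
                "fraction meeting 2 tests/month cannot exceed the fraction "
                "meeting 1 test/month")
        object.__setattr__(self, "ge1_per_block", g1)
        object.__setattr__(self, "ge2_per_block", g2)

    @property
    def n_blocks(self) -> int:
        return len(self.ge1_per_block)


DEFAULT_COMPLIANCE_TARGETS = ComplianceTargets()

# Trajectory archetypes: per-6-month-block retention probabilities relative
# to the nominal fortnightly schedule.  The catalog spans sustained
# compliers, gradual decliners and early faders; faders keep a small
# residual rate (sporadic testing) rather than vanishing outright, so
# long-horizon detection remains possible for every simulated patient.
_ARCHETYPE_BLOCK_RATES: tuple = (
    (1.00, 1.00, 1.00, 1.00),   # sustained fortnightly
    (1.00, 1.00, 1.00, 0.55),   # late lapse
    (1.00, 1.00, 0.80, 0.55),   # mid-study decline
    (1.00, 0.80, 0.55, 0.30),   # gradual decline
    (0.80, 0.80, 0.80, 0.80),   # steady monthly-plus
    (0.80, 0.80, 0.55, 0.30),   # monthly then fading
    (0.80, 0.55, 0.30, 0.15),   # fast decline
    (0.80, 0.30, 0.15, 0.10),   # early fader
    (0.55, 0.30, 0.30, 0.30),   # chronic low
    (0.30, 0.15, 0.10, 0.10),   # near-immediate fader
)


def _block_meet_probs(
    block_rates: Sequence[float],
    tests_per_month: float = 2.0,
    block_months: float = 6.0,
    period_months: float = 2.0,
) -> np.ndarray:
    """P(test count in each block >= 1 and >= 2 per month), exactly.

    The count in a block is Binomial over the scheduled tests with the
    block's retention probability.
    """
    n_sched = int(round(tests_per_month * block_months))
    thresholds = (int(round(block_months)), 2 * int(round(block_months)))
    out = np.empty((len(block_rates), 2))
    for b, r in enumerate(block_rates):
        for j, thr in enumerate(thresholds):
            out[b, j] = float(stats.binom.sf(thr - 1, n_sched, r))
    return out


def _expand_blocks(block_rates: Sequence[float],
                   period_months: float = 2.0,
                   block_months: float = 6.0) -> tuple:
    per_block = int(round(block_months / period_months))
    rates = []
    for r in block_rates:
        rates.extend([r] * per_block)
    return tuple(rates)


def build_compliance_pool(
    targets: ComplianceTargets = DEFAULT_COMPLIANCE_TARGETS,
    pool_size: int = 1000,
    seed: int = 0,
    period_months: float = 2.0,
    tolerance: float = 0.05,
) -> list[ComplianceTrajectory]:
    """Construct a pool of compliance trajectories matching period marginals.

    Mixture weights over the archetype catalog are fitted by non-negative
    least squares so that the pool's implied fractions of participants
    meeting >=1 and >=2 tests/month per 6-month block (exact binomial
    probabilities under Bernoulli thinning of the fortnightly schedule)
    match ``targets`` within ``tolerance``.  The fitted weights are turned
    into exact archetype counts by largest-remainder rounding and the pool
    is shuffled deterministically from ``seed``.

    Raises :class:`CalibrationError` when the targets cannot be met,
    reporting achieved versus requested fractions.
    """
    if pool_size < 1:
        raise ValidationError("pool_size must be >= 1", field="pool_size")
    n_blocks = targets.n_blocks
    catalog = [a[:n_blocks] if len(a) >= n_blocks
               else a + (a[-1],) * (n_blocks - len(a))
               for a in _ARCHETYPE_BLOCK_RATES]
    # design matrix: rows = (block x {ge1, ge2}), cols = archetypes
    probs = [_block_meet_probs(a, period_months=period_months)
             for a in catalog]
    a_mat = np.stack([p.T.ravel() for p in probs], axis=1)  # (2B, K)
    target_vec = np.concatenate([targets.ge1_per_block,
                                 targets.ge2_per_block])
    # enforce weights summing to one via a heavily weighted extra row
    lam = 4.0
    a_aug = np.vstack([a_mat, lam * np.ones(a_mat.shape[1])])
    b_aug = np.concatenate([target_vec, [lam]])
    w, _ = optimize.nnls(a_aug, b_aug)
    if w.sum() <= 0:
        raise CalibrationError("weight fit degenerate (all-zero weights)")
    w = w / w.sum()
    # largest-remainder rounding to integer archetype counts
    raw = w * pool_size
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = pool_size - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    achieved = a_mat @ (counts / pool_size)
    err = np.abs(achieved - target_vec)
    if err.max() > tolerance:
        lines = []
        labels = [f"ge1 block {b}" for b in range(n_blocks)] + \
                 [f"ge2 block {b}" for b in range(n_blocks)]
        for lab, ach, tgt in zip(labels, achieved, target_vec):
            lines.append(f"{lab}: achieved {ach:.3f} vs target {tgt:.3f}")
        raise CalibrationError(
            "compliance pool calibration failed (max error "
            f"{err.max():.3f} > {tolerance}):\n" + "\n".join(lines))
    pool = []
    for arch, c in zip(catalog, counts):
        traj = ComplianceTrajectory(
            rates=_expand_blocks(arch, period_months=period_months),
            period_months=period_months)
        pool.extend([traj] * int(c))
    order = substream(seed, DOMAIN_POOL).permutation(len(pool))
    return [pool[i] for i in order]


def pool_implied_fractions(
    pool: Sequence[ComplianceTrajectory],
    tests_per_month: float = 2.0,
    block_months: float = 6.0,
    n_blocks: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-block fractions of pool members meeting >=1 and >=2
    tests/month, for calibration reporting and verification."""
    if not pool:
        raise InsufficientDataError("empty pool")
    ge1 = np.zeros(n_blocks)
    ge2 = np.zeros(n_blocks)
    for traj in pool:
        block_rates = [traj.rate_at((b * block_months + 1e-9) / 12.0)
                       for b in range(n_blocks)]
        # within-block rate is piecewise constant in the default pools;
        # evaluate at each period midpoint and average the schedule
        p = _block_meet_probs(block_rates, tests_per_month, block_months)
        ge1 += p[:, 0]
        ge2 += p[:, 1]
    return ge1 / len(pool), ge2 / len(pool)


def sample_trajectory(
    pool: Sequence[ComplianceTrajectory], rng: np.random.Generator
) -> ComplianceTrajectory:
    """Uniform draw from the pool."""
    if not pool:
        raise InsufficientDataError("cannot sample from an empty pool")
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic home-monitoring cohort.

    MD distribution and device repeatability/bias defaults reproduce the
    study conditions the analysis assumes; see the methods note for the
    provenance of each value.
    """

    n_patients: int = 25
    md_mean: float = -5.2
    md_sd: float = 4.2
    md_range: tuple = (-14.8, 1.7)
    rc_clinic: float = 3.4          # MD repeatability coefficient, dB
    rc_home: float = 3.0
    rc_vfi_clinic: float = 9.9      # VFI repeatability coefficient, %
    rc_vfi_home: float = 7.1
    md_bias_home_minus_clinic: float = 0.12    # dB
    vfi_bias_home_minus_clinic: float = 1.92   # %
    psd_bias_home_minus_clinic: float = 0.06   # dB
    psd_noise_sd: float = 0.8                  # dB per test
    duration_years: float = 2.0
    clinic_interval_months: float = 6.0
    home_freq_per_month: float = 2.0
    retention: float = 0.72
    reliability_pass_home: float = 0.83
    reliability_pass_clinic: float = 0.86
    mean_fp_pct: tuple = (3.7, 4.7)   # (clinic, home)
    mean_fn_pct: tuple = (3.1, 5.0)
    mean_fl_pct: tuple = (12.3, 9.6)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not self.md_range[0] < self.md_range[1]:
            raise ValidationError("md_range must be increasing")
        for name in ("rc_clinic", "rc_home", "rc_vfi_clinic", "rc_vfi_home"):
            if getattr(self, name) < 0:
                raise ValidationError("must be non-negative", field=name)
        if not (0.0 <= self.retention <= 1.0):
            raise ValidationError("retention must be in [0, 1]")

    @property
    def noise_sd_md_clinic(self) -> float:
        return 0.0 if self.rc_clinic == 0 else noise_sd_from_rc(self.rc_clinic)

    @property
    def noise_sd_md_home(self) -> float:
        return 0.0 if self.rc_home == 0 else noise_sd_from_rc(self.rc_home)


def truncated_normal_md(
    spec: CohortSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Initial (true, stable) MD values from the cohort's truncated normal."""
    lo, hi = spec.md_range
    a = (lo - spec.md_mean) / spec.md_sd
    b = (hi - spec.md_mean) / spec.md_sd
    return stats.truncnorm.rvs(a, b, loc=spec.md_mean, scale=spec.md_sd,
                               size=size, random_state=rng)


# Unreliable tests are modelled as attention lapses that blow up fixation
# losses past the screening bound; between lapses the indices sit at low
# baseline levels so the printed index means are preserved.
_LAPSE_FL_RANGE = (34.0, 50.0)


def _reliability_params(spec: CohortSpec, setting: Setting):
    i = 1 if setting is Setting.HOME else 0
    p_pass = (spec.reliability_pass_home if setting is Setting.HOME
              else spec.reliability_pass_clinic)
    p_lapse = 1.0 - p_pass
    mu_lapse = 0.5 * (_LAPSE_FL_RANGE[0] + _LAPSE_FL_RANGE[1])
    mu_fl_good = (spec.mean_fl_pct[i] - p_lapse * mu_lapse) / max(p_pass, 1e-9)
    mu_fl_good = min(max(mu_fl_good, 0.3), 32.0)
    return p_lapse, mu_fl_good, spec.mean_fp_pct[i], spec.mean_fn_pct[i]


def _draw_reliability(spec: CohortSpec, setting: Setting,
                      size: int, rng: np.random.Generator):
    p_lapse, mu_fl_good, mu_fp, mu_fn = _reliability_params(spec, setting)

    def beta_pct(mean_pct, a, n):
        b = a * (100.0 / mean_pct - 1.0)
        return 100.0 * rng.beta(a, b, size=n)

    fp = np.clip(beta_pct(mu_fp, 2.0, size), 0.0, 100.0)
    fn = np.clip(beta_pct(mu_fn, 2.0, size), 0.0, 100.0)
    fl = np.where(
        rng.random(size) < p_lapse,
        rng.uniform(*_LAPSE_FL_RANGE, size=size),
        np.clip(beta_pct(mu_fl_good, 1.2, size), 0.0, 100.0),
    )
    return fp, fn, fl


def _true_vfi(md: float) -> float:
    # crude but monotone severity mapping used only to give the synthetic
    # cohort a plausible VFI scale (100% at MD 0)
    return float(np.clip(100.0 + 2.5 * md, 0.0, 100.0))


def _true_psd(md: float) -> float:
    return float(np.clip(2.0 + 0.55 * abs(md), 0.3, 16.0))


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    pool: Optional[Sequence[ComplianceTrajectory]] = None,
) -> list[VFTestRecord]:
    """Generate a synthetic cohort of VF test records.

    Each patient contributes two eyes.  Clinic tests follow the semiannual
    schedule for every patient; home tests exist only for the retained
    fraction and follow the nominal fortnightly schedule thinned by a
    compliance trajectory drawn per patient (one bilateral session per
    retained day).  All randomness derives from ``spec.seed`` through
    per-patient substreams.
    """
    if pool is None:
        pool = build_compliance_pool(seed=spec.seed)
    n = spec.n_patients
    n_home = int(round(n * spec.retention))
    order = substream(spec.seed, DOMAIN_COHORT, 0).permutation(n)
    home_testers = set(order[:n_home])

    records: list[VFTestRecord] = []
    clinic_months = np.arange(
        0.0, spec.duration_years * 12.0 + 1e-9, spec.clinic_interval_months)
    n_home_sched = int(round(spec.duration_years * 12.0
                             * spec.home_freq_per_month))
    home_times_years = np.arange(n_home_sched) / (12.0 *
                                                  spec.home_freq_per_month)

    for p in range(n):
        rng = substream(spec.seed, DOMAIN_COHORT, 1, p)
        pid = f"P{p + 1:03d}"
        true_md = truncated_normal_md(spec, 2, rng)
        if p in home_testers:
            traj = sample_trajectory(pool, rng)
            keep = rng.random(n_home_sched) < np.array(
                [traj.rate_at(t) for t in home_times_years])
            keep[0] = True  # supervised enrolment session
            session_times = home_times_years[keep]
        else:
            session_times = np.empty(0)

        for e, eye in enumerate((Eye.OD, Eye.OS)):
            md0 = float(true_md[e])
            vfi0, psd0 = _true_vfi(md0), _true_psd(md0)
            for dev, setting, times_y, sd_md, sd_vfi, md_b, vfi_b, psd_b in (
                (Device.CLINIC_SAP, Setting.CLINIC,
                 clinic_months / 12.0, spec.noise_sd_md_clinic,
                 noise_sd_from_rc(spec.rc_vfi_clinic)
                 if spec.rc_vfi_clinic else 0.0, 0.0, 0.0, 0.0),
                (Device.HOME_VR, Setting.HOME,
                 session_times, spec.noise_sd_md_home,
                 noise_sd_from_rc(spec.rc_vfi_home)
                 if spec.rc_vfi_home else 0.0,
                 spec.md_bias_home_minus_clinic,
                 spec.vfi_bias_home_minus_clinic,
                 spec.psd_bias_home_minus_clinic),
            ):
                m = len(times_y)
                if m == 0:
                    continue
                md = np.clip(md0 + md_b + rng.normal(0.0, 1.0, m) * sd_md,
                             *MD_BOUNDS_DB)
                vfi = np.clip(vfi0 + vfi_b
                              + rng.normal(0.0, 1.0, m) * sd_vfi, 0.0, 100.0)
                psd = np.clip(psd0 + psd_b
                              + rng.normal(0.0, 1.0, m) * spec.psd_noise_sd,
                              0.0, None)
                fp, fn, fl = _draw_reliability(spec, setting, m, rng)
                for k in range(m):
                    records.append(VFTestRecord(
                        patient_id=pid, eye=eye, device=dev, setting=setting,
                        t_days=int(round(times_y[k] * DAYS_PER_YEAR)),
                        md_db=float(md[k]), psd_db=float(psd[k]),
                        vfi_pct=float(vfi[k]), fp_pct=float(fp[k]),
                        fn_pct=float(fn[k]), fl_pct=float(fl[k]),
                    ))
    return records
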