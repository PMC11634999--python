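"""Monte-Carlo generation of longitudinal mean-deviation (MD) sequences.

Sequences follow a linear true trajectory md(t) = md0 + rate * t with
i.i.d. Gaussian per-test noise, on either the semiannual clinic schedule or
the fortnightly (2 tests/month) home schedule, optionally thinned by a
compliance trajectory (each scheduled test retained independently with the
period's compliance probability; the enrolment test at t = 0 is always
kept).  Values are clamped to the instrument range [-35, 10] dB and clamp
events are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._rng import DOMAIN_BATCH, substream
from .agreement import noise_sd_from_rc
from .exceptions import ValidationError
from .records import MD_BOUNDS_DB
from .synthetic import (
    CohortSpec,
    ComplianceTrajectory,
    sample_trajectory,
    truncated_normal_md,
)

DEFAULT_RATES_DB_PER_YEAR = (0.0, -0.5, -1.0, -1.5, -2.0)

#: simulated per-test repeatability, matching the study's real devices
RC_SIMULATED_HOME_DB = 2.9
RC_SIMULATED_CLINIC_DB = 3.3


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulation batch.

    ``noise_sd_db`` defaults to the home-device level (RC 2.9 dB =>
    SD 2.9 / (1.96 * sqrt(2)) dB per test).  ``fortnightly_tests_per_year``
    allows the 26/year reading of "fortnightly"; the default 24/year matches
    a prescription of 2 tests per month.
    """

    rates_db_per_year: tuple = DEFAULT_RATES_DB_PER_YEAR
    schedule: str = "fortnightly"           # or "semiannual"
    n_sequences: int = 10_000
    horizon_years: float = 8.0
    noise_sd_db: float = noise_sd_from_rc(RC_SIMULATED_HOME_DB)
    alpha: float = 0.05
    min_tests: int = 3
    compliance: str = "pool"                # or "full"
    fortnightly_tests_per_year: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValidationError("n_sequences must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.schedule not in ("fortnightly", "semiannual"):
            raise ValidationError(f"unknown schedule {self.schedule!r}")
        if self.compliance not in ("pool", "full"):
            raise ValidationError(f"unknown compliance {self.compliance!r}")
        if self.horizon_years <= 0:
            raise ValidationError("horizon_years must be positive")
        if self.noise_sd_db < 0:
            raise ValidationError("noise_sd_db must be non-negative")


@dataclass(frozen=True)
class MDSequence:
    """One simulated longitudinal MD trajectory."""

    times_years: tuple
    md_db: tuple
    true_rate: float
    trajectory_id: int
    n_clamped: int = 0

    def __post_init__(self):
        t = np.asarray(self.times_years, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValidationError(
                "times must be non-empty, non-negative, increasing")
        if len(self.md_db) != t.size:
            raise ValidationError("times and values must align")


def make_schedule(schedule: str, horizon_years: float,
                  fortnightly_tests_per_year: int = 24) -> np.ndarray:
    """Nominal test times: semiannual -> every 0.5 y; fortnightly ->
    ``fortnightly_tests_per_year`` evenly spaced tests per year; both start
    at 0 and stay within the horizon."""
    if horizon_years <= 0:
        raise ValidationError("horizon_years must be positive")
    if schedule == "semiannual":
        step = 0.5
    elif schedule == "fortnightly":
        step = 1.0 / fortnightly_tests_per_year
    else:
        raise ValidationError(f"unknown schedule {schedule!r}")
    n = int(math.floor(horizon_years / step + 1e-9)) + 1
    return np.arange(n) * step


def thin_schedule(
    times: np.ndarray,
    trajectory: ComplianceTrajectory,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli thinning: scheduled test at t kept with probability equal
    to the compliance rate of its period; the baseline test is always kept
    (enrolment is supervised)."""
    times = np.asarray(times, dtype=float)
    rates = np.array([trajectory.rate_at(t) for t in times])
    keep = rng.random(times.size) < rates
    if times.size:
        keep[0] = True
    return times[keep]


def simulate_sequence(
    rate: float,
    retained_times: np.ndarray,
    initial_md: float,
    noise_sd: float,
    rng: np.random.Generator,
    trajectory_id: int = 0,
) -> MDSequence:
    """md(t) = initial + rate*t + N(0, noise_sd^2), clamped to the
    instrument range with clamp events counted."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    t = np.asarray(retained_times, dtype=float)
    raw = initial_md + rate * t + rng.normal(0.0, 1.0, t.size) * noise_sd
    clipped = np.clip(raw, *MD_BOUNDS_DB)
    return MDSequence(
        times_years=tuple(t),
        md_db=tuple(float(v) for v in clipped),
        true_rate=float(rate),
        trajectory_id=trajectory_id,
        n_clamped=int(np.sum(clipped != raw)),
    )


def simulate_batch(
    config: SimulationConfig,
    pool: Optional[Sequence[ComplianceTrajectory]] = None,
    cohort_spec: CohortSpec = CohortSpec(),
) -> dict[float, list[MDSequence]]:
    """Generate ``config.n_sequences`` sequences per progression rate.

    Initial MD is drawn from the cohort's truncated normal; under pool
    compliance one trajectory is drawn per sequence.  Sequence ``i`` of rate
    index ``r`` draws from substream ``(seed, r, i)``, so each sequence is
    reproducible in isolation and independent of batch composition.
    """
    if config.compliance == "pool" and not pool:
        raise ValidationError(
            "pool compliance requested but no pool supplied")
    schedule = make_schedule(config.schedule, config.horizon_years,
                             config.fortnightly_tests_per_year)
    out: dict[float, list[MDSequence]] = {}
    for r_idx, rate in enumerate(config.rates_db_per_year):
        seqs = []
        for i in range(config.n_sequences):
            rng = substream(config.seed, DOMAIN_BATCH, r_idx, i)
            md0 = float(truncated_normal_md(cohort_spec, 1, rng)[0])
            if config.compliance == "pool":
                traj = sample_trajectory(pool, rng)
                times = thin_schedule(schedule, traj, rng)
            else:
                times = schedule
            seqs.append(simulate_sequence(
                rate, times, md0, config.noise_sd_db, rng, trajectory_id=i))
        out[float(rate)] = seqs
    return out


def stable_repeat_series(
    n_eyes: int,
    n_repeats: int,
    noise_sd: float,
    seed: int,
    cohort_spec: CohortSpec = CohortSpec(),
) -> list[np.ndarray]:
    """Zero-slope repeated measurements for RC calibration checks: each eye
    has ``n_repeats`` draws of its true MD plus per-test noise."""
    from ._rng import DOMAIN_STABLE

    out = []
    for i in range(n_eyes):
        rng = substream(seed, DOMAIN_STABLE, i)
        md0 = float(truncated_normal_md(cohort_spec, 1, rng)[0])
        out.append(md0 + rng.normal(0.0, 1.0, n_repeats) * noise_sd)
    return out
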