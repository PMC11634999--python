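"""Agreement and variability statistics for repeated visual-field indices.

Implements the estimators used to compare a home perimeter with the clinical
standard on perimetrically stable eyes:

* intertest variability as the root-mean-squared error over all ordered
  pairs of repeated measurements of one eye,
      RMSE = sqrt( (1/M) * sum_{i != j} (x_i - x_j)^2 ),  M = n(n-1),
  which equals sqrt(2) times the unbiased sample SD;
* the repeatability coefficient over N eyes with k repeats each,
      RC = 1.96 * sqrt( (1/N) * sum_i 2 * Var(x_i) ),
  the 95% bound on the absolute difference between two repeated
  measurements under no true change;
* ordinary least-squares trend fits of an index on time (years), with the
  textbook slope standard error
      SE_beta = sqrt( SSR / (n-2) / sum_i (t_i - tbar)^2 )
  and a two-sided p-value from the t distribution with n-2 df — the slope
  is the clinical standard progression-rate estimate;
* Bland-Altman limits of agreement on per-eye paired device means.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    ValidationError,
)
from .records import DAYS_PER_YEAR, Device, Eye, VFTestRecord


class IndexName(str, enum.Enum):
    MD = "MD"
    VFI = "VFI"
    PSD = "PSD"

    @property
    def attr(self) -> str:
        return {"MD": "md_db", "VFI": "vfi_pct", "PSD": "psd_db"}[self.value]


@dataclass(frozen=True)
class MeasurementSeries:
    """Repeated values of one VF index for one eye on one device."""

    patient_id: str
    eye: Eye
    device: Device
    index_name: IndexName
    times_years: tuple
    values: tuple

    def __post_init__(self):
        t = np.asarray(self.times_years, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size < 1:
            raise ValidationError(
                "times and values must have equal positive length")
        if np.any(t < 0):
            raise ValidationError("times must be non-negative",
                                  field="times_years")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing",
                                  field="times_years")
        object.__setattr__(self, "times_years", tuple(t))
        object.__setattr__(self, "values", tuple(v))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an index on time (slope in index units per year)."""

    slope: float
    intercept: float
    slope_se: float
    p_two_sided: float
    n: int
    residual_ss: float


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary of device2 - device1 paired per-eye means."""

    index_name: IndexName
    mean_diff: float
    loa_low: float
    loa_high: float
    pearson_r: Optional[float]
    n_pairs: int


def series_from_records(
    tests: Iterable[VFTestRecord],
    patient_id: str,
    eye: Eye,
    device: Device,
    index_name: IndexName,
) -> MeasurementSeries:
    """Collect one eye's repeated measurements of an index into a series.

    Records are taken in stable input order within ties on ``t_days``; same-
    day repeats are spread evenly within that day so times remain strictly
    increasing.
    """
    eye, device, index_name = Eye(eye), Device(device), IndexName(index_name)
    sel = [
        r for r in tests
        if r.patient_id == patient_id and r.eye is eye and r.device is device
        and getattr(r, index_name.attr) is not None
    ]
    sel.sort(key=lambda r: r.t_days)  # stable: preserves file order on ties
    if not sel:
        raise InsufficientDataError(
            f"no {index_name.value} records for {patient_id}/{eye.value}"
            f"/{device.value}")
    times, values = [], []
    i = 0
    while i < len(sel):
        j = i
        while j < len(sel) and sel[j].t_days == sel[i].t_days:
            j += 1
        dup = j - i
        for k in range(dup):
            times.append((sel[i].t_days + k / dup) / DAYS_PER_YEAR)
            values.append(getattr(sel[i + k], index_name.attr))
        i = j
    return MeasurementSeries(patient_id, eye, device, index_name,
                             tuple(times), tuple(values))


def _values(series) -> np.ndarray:
    if isinstance(series, MeasurementSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def pairwise_rmse(series) -> float:
    """Intertest variability: RMSE over all ordered pairs of measurements.

    Computed literally over the M = n(n-1) ordered pairs (the collection is
    small in practice); algebraically identical to sqrt(2) * sample SD.
    """
    x = _values(series)
    n = x.size
    if n < 2:
        raise InsufficientDataError(
            f"pairwise RMSE needs at least 2 measurements, got {n}")
    diff = x[:, None] - x[None, :]
    m = n * (n - 1)
    return float(np.sqrt(np.sum(diff * diff) / m))


def repeatability_coefficient(series_set: Iterable) -> float:
    """RC = 1.96 * sqrt(mean over eyes of 2 * unbiased variance)."""
    variances = []
    for i, series in enumerate(series_set):
        x = _values(series)
        if x.size < 2:
            label = (
                f"{series.patient_id}/{series.eye.value}"
                if isinstance(series, MeasurementSeries) else f"series {i}"
            )
            raise InsufficientDataError(
                f"repeatability needs >=2 repeats per series ({label} has "
                f"{x.size})")
        variances.append(np.var(x, ddof=1))
    if not variances:
        raise InsufficientDataError("no series supplied")
    return float(1.96 * math.sqrt(np.mean(2.0 * np.asarray(variances))))


def fit_trend(series) -> TrendFit:
    """OLS of value on time with the slope SE from the residual sum of
    squares; p-value two-sided from t(n-2).

    A perfect fit (zero residuals) gives ``slope_se = 0`` and p = 0 for a
    nonzero slope, p = 1 for a zero slope.
    """
    if isinstance(series, MeasurementSeries):
        t = np.asarray(series.times_years, dtype=float)
        y = np.asarray(series.values, dtype=float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    n = t.size
    if n < 3:
        raise InsufficientDataError(
            f"trend fit needs n >= 3 (slope SE has n-2 df), got {n}")
    sxx = float(np.sum((t - t.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("all measurement times are equal")
    sxy = float(np.sum((t - t.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    ssr = float(np.sum(resid * resid))
    se = math.sqrt(max(ssr, 0.0) / (n - 2) / sxx)
    if se > 0.0:
        tstat = slope / se
        p = 2.0 * float(stats.t.sf(abs(tstat), n - 2))
    else:
        p = 1.0 if slope == 0.0 else 0.0
    return TrendFit(slope=slope, intercept=intercept, slope_se=se,
                    p_two_sided=p, n=n, residual_ss=ssr)


def per_eye_average(
    tests: Iterable[VFTestRecord],
    device: Device,
    index_name: IndexName,
) -> dict[tuple[str, Eye], float]:
    """Arithmetic mean of an index per (patient, eye) on one device."""
    device, index_name = Device(device), IndexName(index_name)
    acc: dict[tuple[str, Eye], list[float]] = {}
    for r in tests:
        if r.device is device:
            v = getattr(r, index_name.attr)
            if v is not None:
                acc.setdefault((r.patient_id, r.eye), []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def bland_altman(
    device1_means: Mapping[tuple[str, Eye], float],
    device2_means: Mapping[tuple[str, Eye], float],
    index_name: IndexName = IndexName.MD,
) -> AgreementReport:
    """Bland-Altman agreement of paired per-eye means (device2 - device1).

    Eyes present on only one device are dropped with a warning.  Limits of
    agreement are mean difference +/- 1.96 * unbiased SD of the differences.
    Pearson r of the paired means is ``None`` when either side is constant.
    """
    keys = sorted(set(device1_means) & set(device2_means))
    unpaired = (set(device1_means) ^ set(device2_means))
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} eye(s) present on only one device were "
            "excluded from the agreement analysis", stacklevel=2)
    if len(keys) < 3:
        raise InsufficientDataError(
            f"Bland-Altman needs >= 3 paired eyes, got {len(keys)}")
    a = np.array([device1_means[k] for k in keys])
    b = np.array([device2_means[k] for k in keys])
    d = b - a
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if a.std() == 0.0 or b.std() == 0.0:
        r = None
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementReport(
        index_name=IndexName(index_name),
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        pearson_r=r,
        n_pairs=len(keys),
    )


def noise_sd_from_rc(rc: float) -> float:
    """Per-test Gaussian noise SD implied by a repeatability coefficient.

    Under RC = 1.96 * sqrt(2 * sigma^2) the unique per-test SD is
    sigma = RC / (1.96 * sqrt(2)).
    """
    if rc <= 0:
        raise ValidationError("repeatability coefficient must be positive")
    return rc / (1.96 * math.sqrt(2.0))
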