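"""Progression flagging and sensitivity/specificity curves.

A simulated eye is flagged as progressing at a follow-up horizon when the
OLS trend of MD on time over all tests up to that horizon has a negative
slope with a two-sided p-value below alpha (the negative-slope gate makes
the nominal-5% test conservative, so specificity sits near 97.5%).
Evaluation is pointwise per horizon; a cumulative ("ever flagged by h")
mode is available for comparison.  Time-to-80%-detection is the linearly
interpolated first upward crossing of the sensitivity curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .simulate import MDSequence


def prefix_trend_stats(
    times: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, slope SE and two-sided p for every prefix of a series.

    Returns arrays of length n where entry k-1 describes the OLS fit on the
    first k points.  Entries with k < 3 or a degenerate design have
    slope/SE = nan and p = 1 (never flagged).  Zero-residual fits get
    p = 0 for a nonzero slope.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = t.size
    k = np.arange(1, n + 1, dtype=float)
    st, sy = np.cumsum(t), np.cumsum(y)
    stt, sty, syy = np.cumsum(t * t), np.cumsum(t * y), np.cumsum(y * y)
    sxx = stt - st * st / k
    sxy = sty - st * sy / k
    syy_c = syy - sy * sy / k
    ok = (k >= 3) & (sxx > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        ssr = np.maximum(syy_c - slope * sxy, 0.0)
        df = k - 2
        se = np.sqrt(np.where(ok, ssr / np.maximum(df, 1)
                              / np.where(sxx > 0, sxx, 1.0), np.nan))
        tstat = np.abs(slope) / se
    p = np.ones(n)
    finite = ok & np.isfinite(tstat)
    p[finite] = 2.0 * stats.t.sf(tstat[finite], df[finite])
    # exact (zero-residual) fits: p -> 0 for a real slope, 1 for a flat
    # one; the slope tolerance absorbs cancellation noise in the cumulative
    # sums so constant noiseless series are never spuriously flagged
    exact = ok & (se <= 1e-10 * np.maximum(1.0, np.abs(slope)))
    p[exact] = np.where(np.abs(slope[exact]) > 1e-9, 0.0, 1.0)
    slope[~ok] = np.nan
    se[~ok] = np.nan
    return slope, se, p


def flag_progression(
    sequence: MDSequence,
    horizon_years: float,
    alpha: float = 0.05,
    min_tests: int = 3,
) -> bool:
    """Significant negative MD trend using all tests with t <= horizon.

    Returns False (not an error) when fewer than ``min_tests`` tests fall
    inside the horizon.
    """
    t = np.asarray(sequence.times_years)
    m = int(np.searchsorted(t, horizon_years, side="right"))
    if m < min_tests:
        return False
    slope, _, p = prefix_trend_stats(t[:m], np.asarray(sequence.md_db)[:m])
    return bool(slope[-1] < 0.0 and p[-1] < alpha)


@dataclass(frozen=True)
class DetectionCurves:
    """Sensitivity per rate and specificity as functions of horizon."""

    horizons_years: tuple
    sensitivity_by_rate: dict      # rate -> np.ndarray over horizons
    specificity: Optional[np.ndarray]
    time_to_80_by_rate: dict       # rate -> float years or None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        h = np.asarray(self.horizons_years)
        for rate, sens in sorted(self.sensitivity_by_rate.items()):
            for j in range(h.size):
                rows.append({
                    "rate_db_per_year": rate,
                    "horizon_years": h[j],
                    "sensitivity": sens[j],
                    "specificity": (np.nan if self.specificity is None
                                    else self.specificity[j]),
                })
        return pd.DataFrame(rows)


def default_horizon_grid(horizon_years: float, step: float = 0.1,
                         start: float = 0.5) -> np.ndarray:
    n = int(round((horizon_years - start) / step))
    return start + step * np.arange(n + 1)


def _flag_matrix(
    sequences: Sequence[MDSequence],
    horizons: np.ndarray,
    alpha: float,
    min_tests: int,
    mode: str,
) -> np.ndarray:
    """Fraction of sequences flagged at each horizon."""
    flagged = np.zeros(horizons.size)
    for seq in sequences:
        t = np.asarray(seq.times_years)
        slope, _, p = prefix_trend_stats(t, np.asarray(seq.md_db))
        hit = (slope < 0.0) & (p < alpha)
        hit[: max(min_tests - 1, 0)] = False
        if mode == "sequential":
            hit = np.maximum.accumulate(hit)
        counts = np.searchsorted(t, horizons, side="right")
        ok = counts >= 1
        idx = np.maximum(counts - 1, 0)
        flagged += np.where(ok, hit[idx], False)
    return flagged / len(sequences)


def evaluate_curves(
    batches: Mapping[float, Sequence[MDSequence]],
    horizons: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    min_tests: int = 3,
    level: float = 0.80,
    mode: str = "pointwise",
) -> DetectionCurves:
    """Sensitivity/specificity curves over a horizon grid.

    ``batches`` maps true progression rate (dB/year) to its sequences; the
    0 dB/year batch provides specificity = 1 - flagged fraction (omitted
    with a warning when absent).  ``mode`` is ``"pointwise"`` (fraction
    flagged using all data up to each horizon, the default) or
    ``"sequential"`` (ever flagged by the horizon).
    """
    if mode not in ("pointwise", "sequential"):
        raise ValidationError(f"unknown evaluation mode {mode!r}")
    if horizons is None:
        h_max = max(max(s.times_years[-1] for s in seqs)
                    for seqs in batches.values())
        horizons = default_horizon_grid(h_max)
    horizons = np.asarray(horizons, dtype=float)

    sensitivity_by_rate: dict = {}
    specificity = None
    for rate, seqs in batches.items():
        frac = _flag_matrix(seqs, horizons, alpha, min_tests, mode)
        if rate == 0.0:
            specificity = 1.0 - frac
        else:
            sensitivity_by_rate[float(rate)] = frac
    if specificity is None:
        import warnings

        warnings.warn("no 0 dB/year batch supplied; specificity omitted",
                      stacklevel=2)
    tt = {
        rate: time_to_sensitivity(horizons, sens, level)
        for rate, sens in sensitivity_by_rate.items()
    }
    return DetectionCurves(
        horizons_years=tuple(horizons),
        sensitivity_by_rate=sensitivity_by_rate,
        specificity=specificity,
        time_to_80_by_rate=tt,
    )


def time_to_sensitivity(
    horizons: np.ndarray, sensitivity: np.ndarray, level: float = 0.80
) -> Optional[float]:
    """Linearly interpolated first upward crossing of ``level``; ``None``
    when the curve never reaches it within the horizon.

    A jump out of zero sensitivity (the minimum-test legality boundary) is
    not interpolated: detection was impossible before the jump, so the
    crossing is placed at the jump itself.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError("level must be in (0, 1)")
    h = np.asarray(horizons, dtype=float)
    s = np.asarray(sensitivity, dtype=float)
    idx = np.nonzero(s >= level)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(h[0])
    if s[i] == s[i - 1] or s[i - 1] == 0.0:
        return float(h[i])
    frac = (level - s[i - 1]) / (s[i] - s[i - 1])
    return float(h[i - 1] + frac * (h[i] - h[i - 1]))
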