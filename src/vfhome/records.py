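"""Data model and CSV I/O for visual-field (VF) test records.

A record holds the summary indices of one perimetry test of one eye on one
device: mean deviation (MD, dB), pattern standard deviation (PSD, dB) and
visual field index (VFI, %), together with the reliability indices used to
screen tests (false-positive rate, false-negative rate, fixation losses, all
in percent).

Time is carried as integer days since the patient's first recorded test;
calendar dates are deliberately out of scope.  One month is 30.4375 days and
one year 365.25 days throughout the package.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import FormatError, InsufficientDataError, ValidationError

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

MD_BOUNDS_DB = (-35.0, 10.0)


class Eye(str, enum.Enum):
    OD = "OD"
    OS = "OS"


class Device(str, enum.Enum):
    """Testing device: in-clinic standard automated perimeter vs. the
    head-mounted home perimeter."""

    CLINIC_SAP = "CLINIC_SAP"
    HOME_VR = "HOME_VR"


class Setting(str, enum.Enum):
    CLINIC = "clinic"
    HOME = "home"


def _check_pct(name: str, value: float, row: Optional[int] = None) -> None:
    if not (0.0 <= value <= 100.0):
        raise ValidationError(
            f"must be in [0, 100], got {value!r}", row=row, field=name
        )


@dataclass(frozen=True)
class VFTestRecord:
    """One visual-field test of one eye on one device.

    ``md_db``, ``psd_db`` and ``vfi_pct`` may be ``None`` when an index was
    not reported; reliability indices are required because they drive the
    reliability filter.
    """

    patient_id: str
    eye: Eye
    device: Device
    setting: Setting
    t_days: int
    md_db: Optional[float]
    psd_db: Optional[float]
    vfi_pct: Optional[float]
    fp_pct: float
    fn_pct: float
    fl_pct: float

    def __post_init__(self):
        object.__setattr__(self, "eye", Eye(self.eye))
        object.__setattr__(self, "device", Device(self.device))
        object.__setattr__(self, "setting", Setting(self.setting))
        if int(self.t_days) != self.t_days or self.t_days < 0:
            raise ValidationError(
                f"must be a non-negative integer, got {self.t_days!r}",
                field="t_days",
            )
        object.__setattr__(self, "t_days", int(self.t_days))
        if self.md_db is not None and not (
            MD_BOUNDS_DB[0] <= self.md_db <= MD_BOUNDS_DB[1]
        ):
            raise ValidationError(
                f"must be in [{MD_BOUNDS_DB[0]}, {MD_BOUNDS_DB[1]}] dB, "
                f"got {self.md_db!r}",
                field="md_db",
            )
        if self.psd_db is not None and self.psd_db < 0:
            raise ValidationError(
                f"must be non-negative, got {self.psd_db!r}", field="psd_db"
            )
        if self.vfi_pct is not None:
            _check_pct("vfi_pct", self.vfi_pct)
        _check_pct("fp_pct", self.fp_pct)
        _check_pct("fn_pct", self.fn_pct)
        _check_pct("fl_pct", self.fl_pct)

    @property
    def t_years(self) -> float:
        return self.t_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class ReliabilityCriteria:
    """Strict upper bounds on the reliability indices.

    A test is reliable iff every index is strictly below its bound.  The
    defaults (<20% false positives, <20% false negatives, <33% fixation
    losses) are the conventional perimetric screening thresholds.
    """

    fp_max_pct: float = 20.0
    fn_max_pct: float = 20.0
    fl_max_pct: float = 33.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 < v <= 100.0):
                raise ValidationError(
                    f"must be in (0, 100], got {v!r}", field=f.name
                )

    def is_reliable(self, rec: VFTestRecord) -> bool:
        return (
            rec.fp_pct < self.fp_max_pct
            and rec.fn_pct < self.fn_max_pct
            and rec.fl_pct < self.fl_max_pct
        )


CSV_COLUMNS = (
    "patient_id",
    "eye",
    "device",
    "setting",
    "t_days",
    "md_db",
    "psd_db",
    "vfi_pct",
    "fp_pct",
    "fn_pct",
    "fl_pct",
)

_OPTIONAL_FLOAT = {"md_db", "psd_db", "vfi_pct"}
_REQUIRED_FLOAT = {"fp_pct", "fn_pct", "fl_pct"}


def read_tests(path) -> list[VFTestRecord]:
    """Read VF test records from a CSV file.

    The header must contain all columns of :data:`CSV_COLUMNS` (extra columns
    are ignored).  Leading lines starting with ``#`` are treated as comments.
    Optional indices may be empty strings.  Raises :class:`FormatError` for a
    bad header and :class:`ValidationError` (with the 1-based data row
    number) for an invalid field.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None:
        raise FormatError(f"{path}: empty file")
    missing = set(CSV_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    records: list[VFTestRecord] = []
    for rownum, row in enumerate(reader, start=1):
        kwargs: dict = {}
        for col in CSV_COLUMNS:
            raw = (row[col] or "").strip()
            if col in _OPTIONAL_FLOAT:
                kwargs[col] = float(raw) if raw else None
            elif col in _REQUIRED_FLOAT:
                if not raw:
                    raise ValidationError("required value missing",
                                          row=rownum, field=col)
                kwargs[col] = float(raw)
            elif col == "t_days":
                try:
                    kwargs[col] = int(raw)
                except ValueError:
                    raise ValidationError(
                        f"must be an integer, got {raw!r}",
                        row=rownum, field=col) from None
            else:
                kwargs[col] = raw
        try:
            records.append(VFTestRecord(**kwargs))
        except ValidationError as err:
            raise ValidationError(str(err), row=rownum) from None
        except ValueError as err:  # bad enum value
            raise ValidationError(str(err), row=rownum) from None
    return records


def write_tests(path, records: Iterable[VFTestRecord],
                header_comment: Optional[str] = None) -> None:
    """Write records as RFC-4180 CSV; ``header_comment`` (if given) is
    emitted as a leading ``#`` line that :func:`read_tests` will skip."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.patient_id,
                rec.eye.value,
                rec.device.value,
                rec.setting.value,
                rec.t_days,
                "" if rec.md_db is None else repr(rec.md_db),
                "" if rec.psd_db is None else repr(rec.psd_db),
                "" if rec.vfi_pct is None else repr(rec.vfi_pct),
                repr(rec.fp_pct),
                repr(rec.fn_pct),
                repr(rec.fl_pct),
            ])


def sort_records(records: Sequence[VFTestRecord]) -> list[VFTestRecord]:
    """Sort by (patient, eye, device, t_days) with a stable tie-break on
    input order."""
    return sorted(
        records,
        key=lambda r: (r.patient_id, r.eye.value, r.device.value, r.t_days),
    )


def apply_reliability_filter(
    tests: Sequence[VFTestRecord],
    criteria: ReliabilityCriteria = ReliabilityCriteria(),
) -> tuple[list[VFTestRecord], float]:
    """Split off the reliable subset and return it with the reliability rate.

    Reliability uses strict inequalities on every index; a fixation-loss rate
    of exactly 33% fails the default criteria.
    """
    if len(tests) == 0:
        raise InsufficientDataError(
            "reliability rate undefined for an empty collection")
    reliable = [t for t in tests if criteria.is_reliable(t)]
    return reliable, len(reliable) / len(tests)


def home_session_days(
    tests: Iterable[VFTestRecord],
) -> dict[str, list[int]]:
    """Unique home-test session days per patient.

    A bilateral home session produces one record per eye on the same day;
    compliance counts sessions, so days are de-duplicated per patient.
    """
    sessions: dict[str, set[int]] = {}
    for rec in tests:
        if rec.setting is Setting.HOME:
            sessions.setdefault(rec.patient_id, set()).add(rec.t_days)
    return {pid: sorted(days) for pid, days in sessions.items()}


def retention_rate(
    tests: Iterable[VFTestRecord], enrolled_ids: Iterable[str]
) -> float:
    """Fraction of enrolled participants with at least one home test."""
    enrolled = set(enrolled_ids)
    if not enrolled:
        raise InsufficientDataError("enrolled_ids must be non-empty")
    testers = {t.patient_id for t in tests if t.setting is Setting.HOME}
    return len(enrolled & testers) / len(enrolled)


def compliance_by_period(
    tests: Iterable[VFTestRecord],
    participant_ids: Iterable[str],
    period_months: int = 6,
    freq_per_month: float = 2.0,
    total_months: int = 24,
) -> list[float]:
    """Per-period fraction of participants meeting the prescribed test
    frequency.

    The follow-up of ``total_months`` is cut into consecutive half-open
    windows of ``period_months`` (months of 30.4375 days, anchored at each
    patient's day 0).  A participant complies in a window when their number
    of home sessions there is at least ``freq_per_month * period_months``.
    The denominator is the full ``participant_ids`` cohort in every window,
    not just participants still active.
    """
    ids = list(dict.fromkeys(participant_ids))
    if not ids:
        raise InsufficientDataError("participant_ids must be non-empty")
    if freq_per_month <= 0:
        raise ValidationError("must be positive", field="freq_per_month")
    if period_months <= 0 or total_months % period_months != 0:
        raise ValidationError(
            "period_months must be positive and divide total_months",
            field="period_months",
        )
    sessions = home_session_days(tests)
    n_windows = total_months // period_months
    required = freq_per_month * period_months
    out = []
    for w in range(n_windows):
        lo = w * period_months * DAYS_PER_MONTH
        hi = (w + 1) * period_months * DAYS_PER_MONTH
        n_ok = 0
        for pid in ids:
            count = sum(1 for d in sessions.get(pid, ()) if lo <= d < hi)
            if count >= required:
                n_ok += 1
        out.append(n_ok / len(ids))
    return out


def average_test_frequency(
    tests: Iterable[VFTestRecord],
    participant_id: str,
    window_months: float,
) -> float:
    """Home sessions per month for one participant over a window starting at
    their day 0.  Zero sessions gives 0."""
    if window_months <= 0:
        raise ValidationError("must be positive", field="window_months")
    days = home_session_days(tests).get(participant_id, [])
    hi = window_months * DAYS_PER_MONTH
    count = sum(1 for d in days if d < hi)
    return count / window_months
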