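"""Dispensing-record data model and CSV input/output.

Pharmacy dispensing databases record, per refill line, the medication, the
dispensation date, the quantity dispensed (package size or a multiple) and the
prescribed daily dosage.  Possession-based adherence indices are computed from
exactly these elements, so this module is the single place where they are
parsed, validated and normalised.

Dates may be calendar dates (ISO ``YYYY-MM-DD``, or European ``DD.MM.YY``
behind an explicit dialect flag) or positive integer day indices ("day 1",
"day 15", ...).  A file uses one mode throughout; modes are never mixed.

Dosage schedules follow the morning-noon-evening notation used on Swiss/German
prescriptions: ``1-0-0`` is one tablet every morning, ``1-0-1`` morning and
evening, ``1/2-0-1/2`` half a tablet twice a day.  Halves (and any decimal
token) are held as exact :class:`fractions.Fraction` so that a daily dose of
two half-tablets is exactly 1, with no binary-float drift.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from fractions import Fraction
from typing import IO, Iterable, Optional, Sequence, Union

import pandas as pd

Day = Union[date, int]

__all__ = [
    "Day",
    "DosageSchedule",
    "DispensingEvent",
    "MedicationHistory",
    "ObservationWindow",
    "PatientRecord",
    "CsvDialect",
    "ScheduleError",
    "RecordValidationError",
    "parse_schedule",
    "parse_day",
    "day_diff",
    "day_add",
    "days_supply",
    "read_records",
    "write_records",
]


class ScheduleError(ValueError):
    """Raised for malformed or uninterpretable dosage schedules."""


class RecordValidationError(ValueError):
    """Raised for invalid dispensing records; carries the offending row."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# day arithmetic


def day_diff(later: Day, earlier: Day) -> int:
    """Number of days from ``earlier`` to ``later`` (calendar or integer mode)."""
    if isinstance(later, int) and isinstance(earlier, int):
        return later - earlier
    if isinstance(later, date) and isinstance(earlier, date):
        return (later - earlier).days
    raise TypeError("cannot mix calendar dates and integer day indices")


def day_add(d: Day, n: int) -> Day:
    if isinstance(d, int):
        return d + n
    return date.fromordinal(d.toordinal() + n)


def parse_day(text: str, dialect: "CsvDialect") -> Day:
    """Parse one date cell according to the dialect's date mode."""
    text = str(text).strip()
    mode = dialect.date_mode
    if mode == "day":
        value = int(text)
        if value < 1:
            raise ValueError(f"integer day index must be >= 1, got {value}")
        return value
    if mode == "european":
        return datetime.strptime(text, "%d.%m.%y").date()
    return date.fromisoformat(text)


# ---------------------------------------------------------------------------
# domain types


_HALF_GLYPH = "½"
_DASHES = re.compile(r"[-‐‑‒–—]")


def _parse_dose_token(token: str, position: str) -> Fraction:
    token = token.strip()
    if token == _HALF_GLYPH:
        return Fraction(1, 2)
    token = token.replace(_HALF_GLYPH, "+1/2") if _HALF_GLYPH in token else token
    try:
        if "/" in token:
            return Fraction(token)
        return Fraction(token)  # handles "1", "0.5", "2"
    except (ValueError, ZeroDivisionError) as exc:
        raise ScheduleError(f"non-numeric {position} dose token {token!r}") from exc


@dataclass(frozen=True)
class DosageSchedule:
    """Prescribed daily dosage as morning-noon-evening unit counts."""

    morning: Fraction
    noon: Fraction
    evening: Fraction

    def __post_init__(self):
        for name in ("morning", "noon", "evening"):
            value = getattr(self, name)
            if not isinstance(value, Fraction):
                object.__setattr__(self, name, Fraction(value))
            if getattr(self, name) < 0:
                raise ScheduleError(f"negative {name} dose")

    @property
    def daily_dose(self) -> Fraction:
        return self.morning + self.noon + self.evening

    def text(self) -> str:
        def fmt(x: Fraction) -> str:
            return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"

        return "-".join(fmt(x) for x in (self.morning, self.noon, self.evening))


def parse_schedule(text: str) -> DosageSchedule:
    """Parse a morning-noon-evening dosage string such as ``"1-0-1"``.

    Accepts ASCII hyphens and typographic dashes as separators, and doses as
    integers, decimals, the ``1/2`` fraction form or the ``½`` glyph.
    Raises :class:`ScheduleError` for a wrong token count, a non-numeric token
    or a zero total daily dose (uninterpretable for possession computation,
    like pro-re-nata instructions).
    """
    tokens = _DASHES.split(str(text).strip())
    if len(tokens) != 3:
        raise ScheduleError(
            f"schedule {text!r} must have three dash-separated tokens, got {len(tokens)}"
        )
    morning, noon, evening = (
        _parse_dose_token(tok, pos) for tok, pos in zip(tokens, ("morning", "noon", "evening"))
    )
    schedule = DosageSchedule(morning, noon, evening)
    if schedule.daily_dose == 0:
        raise ScheduleError(f"schedule {text!r} has zero total daily dose")
    return schedule


@dataclass(frozen=True)
class DispensingEvent:
    """One refill line: medication, date, quantity, dosage schedule in force."""

    medication_id: str
    date: Day
    quantity: Fraction
    schedule: DosageSchedule
    therapy_class: Optional[str] = None
    event_flag: Optional[str] = None

    def __post_init__(self):
        if not isinstance(self.quantity, Fraction):
            object.__setattr__(self, "quantity", Fraction(self.quantity))
        if self.quantity <= 0:
            raise RecordValidationError(
                f"quantity must be positive, got {self.quantity} for {self.medication_id}"
            )
        if isinstance(self.date, int) and self.date < 1:
            raise RecordValidationError(f"integer day index must be >= 1, got {self.date}")


def days_supply(event: DispensingEvent) -> Fraction:
    """Days the dispensation can cover: quantity divided by the daily dose.

    May be fractional; downstream consumption is done in units, never in
    rounded days.
    """
    dose = event.schedule.daily_dose
    if dose <= 0:
        raise ScheduleError("daily dose must be positive for days'-supply computation")
    return event.quantity / dose


def _merge_same_day(events: Sequence[DispensingEvent]) -> list[DispensingEvent]:
    """Sort by date and merge same-day refills of the medication by summing quantity."""
    merged: dict = {}
    for ev in sorted(events, key=lambda e: (e.date if isinstance(e.date, int) else e.date.toordinal())):
        if ev.date in merged:
            prev = merged[ev.date]
            merged[ev.date] = replace(prev, quantity=prev.quantity + ev.quantity)
        else:
            merged[ev.date] = ev
    return list(merged.values())


@dataclass
class MedicationHistory:
    """Time-ordered dispensations of one (index) medication.

    ``therapy_end`` optionally caps the days on which the medication is
    expected to be taken (exclusive, half-open like the observation window);
    by default a medication is expected from its first dispensation to the
    window end.
    """

    index_medication: str
    events: list[DispensingEvent]
    therapy_end: Optional[Day] = None

    def __post_init__(self):
        if not self.events:
            raise RecordValidationError(f"history for {self.index_medication} has no events")
        self.events = _merge_same_day(self.events)

    @property
    def therapy_start(self) -> Day:
        return self.events[0].date

    @property
    def total_quantity(self) -> Fraction:
        return sum((e.quantity for e in self.events), Fraction(0))

    @property
    def total_days_supply(self) -> Fraction:
        return sum((days_supply(e) for e in self.events), Fraction(0))


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open observation period ``[start, end)``; length = end - start."""

    start: Day
    end: Day

    def __post_init__(self):
        if self.length_days < 1:
            raise RecordValidationError(
                f"observation window [{self.start}, {self.end}) must span at least one day"
            )

    @property
    def length_days(self) -> int:
        return day_diff(self.end, self.start)

    def offset(self, d: Day) -> int:
        """Day index of ``d`` relative to the window start (0-based)."""
        return day_diff(d, self.start)

    def contains(self, d: Day) -> bool:
        return 0 <= self.offset(d) < self.length_days


@dataclass
class PatientRecord:
    """All medication histories of one patient plus the observation window."""

    patient_id: str
    histories: list[MedicationHistory]
    window: ObservationWindow

    @property
    def refill_dates(self) -> list[Day]:
        """Distinct dispensation dates across the whole regimen, ordered."""
        dates = {e.date for h in self.histories for e in h.events}
        return sorted(dates, key=lambda d: d if isinstance(d, int) else d.toordinal())


# ---------------------------------------------------------------------------
# CSV input / output


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and date conventions for dispensing-record CSV files.

    ``date_mode``: ``"auto"`` detects ISO vs integer-day per file; ``"iso"``,
    ``"day"`` and ``"european"`` force a mode (``european`` = ``DD.MM.YY``).
    """

    patient_id: str = "patient_id"
    medication_id: str = "medication_id"
    date: str = "date"
    quantity: str = "quantity"
    schedule: str = "schedule"
    therapy_class: str = "therapy_class"
    event_flag: str = "event_flag"
    window_start: str = "window_start"
    window_end: str = "window_end"
    therapy_end: str = "therapy_end"
    date_mode: str = "auto"


def _detect_date_mode(values: Iterable[str]) -> str:
    for raw in values:
        text = str(raw).strip()
        if re.fullmatch(r"\d+", text):
            return "day"
        return "iso"
    return "iso"


def read_records(
    source: Union[str, IO[str]],
    dialect: Optional[CsvDialect] = None,
    window: Optional[ObservationWindow] = None,
) -> list[PatientRecord]:
    """Read dispensing records from CSV into per-patient structures.

    Events are grouped per patient and medication, ordered by date, with
    same-day duplicates merged.  If the file carries ``window_start`` /
    ``window_end`` columns (constant per patient) they define the observation
    window; otherwise ``window`` applies to all patients, and if neither is
    given the window runs from each patient's first dispensation to one day
    past the last (half-open, so the last refill date itself is the end).
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(source, dtype=str)
    required = [dialect.patient_id, dialect.medication_id, dialect.date, dialect.quantity, dialect.schedule]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []

    if dialect.date_mode == "auto":
        dialect = replace(dialect, date_mode=_detect_date_mode(df[dialect.date]))

    records: list[PatientRecord] = []
    for patient_id, group in df.groupby(dialect.patient_id, sort=False):
        histories: dict[str, list[DispensingEvent]] = {}
        therapy_ends: dict[str, Day] = {}
        pwindow = window
        for idx, row in group.iterrows():
            rownum = int(idx) + 2  # 1-based with header line
            try:
                when = parse_day(row[dialect.date], dialect)
            except ValueError as exc:
                raise RecordValidationError(f"unparseable date {row[dialect.date]!r}", row=rownum) from exc
            try:
                quantity = Fraction(str(row[dialect.quantity]))
            except ValueError as exc:
                raise RecordValidationError(
                    f"unparseable quantity {row[dialect.quantity]!r}", row=rownum
                ) from exc
            if quantity <= 0:
                raise RecordValidationError(f"non-positive quantity {quantity}", row=rownum)
            try:
                schedule = parse_schedule(row[dialect.schedule])
            except ScheduleError as exc:
                raise RecordValidationError(str(exc), row=rownum) from exc
            therapy_class = None
            if dialect.therapy_class in group.columns and pd.notna(row.get(dialect.therapy_class)):
                therapy_class = str(row[dialect.therapy_class])
            event_flag = None
            if dialect.event_flag in group.columns and pd.notna(row.get(dialect.event_flag)):
                event_flag = str(row[dialect.event_flag])
            med = str(row[dialect.medication_id])
            histories.setdefault(med, []).append(
                DispensingEvent(med, when, quantity, schedule, therapy_class, event_flag)
            )
            if dialect.therapy_end in group.columns and pd.notna(row.get(dialect.therapy_end)):
                cell = str(row[dialect.therapy_end]).strip()
                if cell:
                    therapy_ends[med] = parse_day(cell, dialect)
            if (
                pwindow is None
                and dialect.window_start in group.columns
                and pd.notna(row.get(dialect.window_start))
            ):
                pwindow = ObservationWindow(
                    parse_day(row[dialect.window_start], dialect),
                    parse_day(row[dialect.window_end], dialect),
                )
        history_objs = [
            MedicationHistory(med, evs, therapy_end=therapy_ends.get(med))
            for med, evs in histories.items()
        ]
        if pwindow is None:
            all_dates = sorted(
                {e.date for h in history_objs for e in h.events},
                key=lambda d: d if isinstance(d, int) else d.toordinal(),
            )
            pwindow = ObservationWindow(all_dates[0], day_add(all_dates[-1], 1))
        records.append(PatientRecord(str(patient_id), history_objs, pwindow))
    return records


def _format_day(d: Day) -> str:
    return str(d) if isinstance(d, int) else d.isoformat()


def write_records(records: Sequence[PatientRecord], target: Union[str, IO[str], None] = None) -> str:
    """Serialize patient records to CSV (inverse of :func:`read_records`)."""
    rows = []
    for rec in records:
        for hist in rec.histories:
            for ev in hist.events:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "medication_id": ev.medication_id,
                        "date": _format_day(ev.date),
                        "quantity": str(ev.quantity),
                        "schedule": ev.schedule.text(),
                        "therapy_class": ev.therapy_class or "",
                        "event_flag": ev.event_flag or "",
                        "window_start": _format_day(rec.window.start),
                        "window_end": _format_day(rec.window.end),
                        "therapy_end": (
                            _format_day(hist.therapy_end) if hist.therapy_end is not None else ""
                        ),
                    }
                )
    df = pd.DataFrame(rows)
    if target is None or isinstance(target, str):
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        text = buf.getvalue()
        if isinstance(target, str):
            with open(target, "w") as fh:
                fh.write(text)
        return text
    df.to_csv(target, index=False)
    return ""
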