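"""Per-day supply diary: the unit-ledger engine behind the polypharmacy index.

For every medication the engine walks the observation window day by day,
holding the on-hand stock in dispensing units (exact fractions, so half-tablet
doses and mid-window dose changes stay exact): stock rises by the quantity
dispensed on a dispensation day and falls by the daily dose on every expected
day with stock at least one dose on hand.  A day is *available* iff
consumption happened.  Surplus therefore flows forward automatically — excess
from an early refill is consumed in a later gap — but never backward: a refill
after a stockout leaves the stockout days uncovered (no retroactive
compensation).

A medication is *expected* from its first dispensation to the window end, or
to its own therapy end when one is set (e.g. when a medication exits the
regimen at a review).

End-of-window accounting excludes the extra doses of the last dispensation
that lie beyond the window end: they count neither as covered days nor toward
the accumulated-surplus statistic.  Per-medication gap days (expected but not
available) and the accumulated surplus complete the picture, since a
possession index bounded at 1 cannot itself show oversupply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .records import MedicationHistory, ObservationWindow, PatientRecord
from .standards import StandardsPolicy, dose_breakpoints, dose_on_day, truncate_at_window_end

__all__ = ["MedicationDiary", "SupplyDiary", "StockSummary", "build_diary", "stock_summary"]


@dataclass
class MedicationDiary:
    """Day-by-day ledger of one medication over the window."""

    medication_id: str
    expected: list[bool]
    available: list[bool]
    stock_trace: list[Fraction]
    dispensed_units: Fraction
    consumed_units: Fraction
    end_stock: Fraction
    excluded_excess: Fraction

    @property
    def gap_days(self) -> int:
        return sum(1 for e, a in zip(self.expected, self.available) if e and not a)

    @property
    def expected_days(self) -> int:
        return sum(self.expected)

    @property
    def covered_days(self) -> int:
        return sum(self.available)

    @property
    def surplus_units(self) -> Fraction:
        surplus = self.end_stock - self.excluded_excess
        return surplus if surplus > 0 else Fraction(0)


@dataclass
class SupplyDiary:
    """Per-day, per-medication availability over one patient's window."""

    window: ObservationWindow
    medications: list[MedicationDiary]

    @property
    def medication_ids(self) -> list[str]:
        return [m.medication_id for m in self.medications]


@dataclass(frozen=True)
class StockSummary:
    """End-of-window stock accounting for one patient.

    ``mean_gap_pct`` is the mean over medications of the per-medication days
    without supply as a share of the window, reported with a negative sign
    (deficit convention: -10 means the average medication lacked supply on
    10 % of the observation days).
    """

    surplus_units: Fraction
    gap_days_per_medication: dict
    gap_days_any: int
    mean_gap_pct: Fraction

    @property
    def gap_days_total(self) -> int:
        return sum(self.gap_days_per_medication.values())


def _simulate_medication(
    history: MedicationHistory, window: ObservationWindow, truncate_last: bool
) -> MedicationDiary:
    length = window.length_days
    end = length
    if history.therapy_end is not None:
        end = min(end, max(window.offset(history.therapy_end), 0))

    fills: dict[int, Fraction] = {}
    pre_window_stock = Fraction(0)
    dispensed = Fraction(0)
    for ev in history.events:
        off = window.offset(ev.date)
        if off < 0:
            # pre-window fill: only what is still on hand at the window start
            # enters the ledger (and the conservation accounting)
            remaining = ev.quantity - ev.schedule.daily_dose * (-off)
            if remaining > 0:
                pre_window_stock += remaining
                dispensed += remaining
        elif off < end:
            fills[off] = fills.get(off, Fraction(0)) + ev.quantity
            dispensed += ev.quantity

    breakpoints = dose_breakpoints(history)
    first = min(fills) if fills else 0
    if pre_window_stock > 0:
        first = 0

    expected = [False] * length
    available = [False] * length
    trace: list[Fraction] = [Fraction(0)] * length
    stock = pre_window_stock
    consumed = Fraction(0)
    for day in range(length):
        if day in fills:
            stock += fills[day]
        if first <= day < end:
            expected[day] = True
            dose = dose_on_day(breakpoints, window.offset, day)
            if stock >= dose:
                stock -= dose
                consumed += dose
                available[day] = True
        trace[day] = stock

    excess = truncate_at_window_end(history, window) if truncate_last else Fraction(0)
    return MedicationDiary(
        medication_id=history.index_medication,
        expected=expected,
        available=available,
        stock_trace=trace,
        dispensed_units=dispensed,
        consumed_units=consumed,
        end_stock=stock,
        excluded_excess=excess,
    )


def build_diary(record: PatientRecord, policy: Optional[StandardsPolicy] = None) -> SupplyDiary:
    """Simulate each medication's stock forward over the patient's window.

    The record is assumed to have passed standards preprocessing (merging,
    eligibility, window determination); the diary itself only consumes.
    """
    policy = policy or StandardsPolicy()
    meds = [
        _simulate_medication(h, record.window, policy.truncate_last_dispensation)
        for h in record.histories
    ]
    return SupplyDiary(record.window, meds)


def stock_summary(diary: SupplyDiary) -> StockSummary:
    """Accumulated surplus and gap-day accounting for a built diary."""
    gaps = {m.medication_id: m.gap_days for m in diary.medications}
    length = diary.window.length_days
    n = len(diary.medications)
    any_missing = sum(
        1
        for day in range(length)
        if any(m.expected[day] and not m.available[day] for m in diary.medications)
    )
    mean_gap = (
        -Fraction(sum(gaps.values()), n) / length * 100 if n else Fraction(0)
    )
    return StockSummary(
        surplus_units=sum((m.surplus_units for m in diary.medications), Fraction(0)),
        gap_days_per_medication=gaps,
        gap_days_any=any_missing,
        mean_gap_pct=mean_gap,
    )
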