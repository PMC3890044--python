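"""Standardisation rules applied to raw dispensing records before any index.

Possession indices are only comparable when the observation window, the
eligibility rules and the handling of switching, duplication, dose changes and
end-of-window oversupply are fixed.  This module implements that rule set:

* start the observation period at day 1 with the first dispensation (no
  artificial initial gap), end it at the last refill date or at the medication
  review date (no artificial terminal gap);
* exclude patients with two refills or less;
* collapse therapeutic switches, generic switches, combination-pill switches
  and therapeutic duplication into ONE index medication (the product with the
  first refill in time);
* honour prescribed dose changes from their effective date;
* exclude the extra doses of the last dispensation that fall beyond the window
  end, and allow carryover of excess supply forward in time only — a later
  refill never retroactively covers an earlier day without supply.

Medications with variable ("take 1 or 2") or as-needed instructions cannot be
converted into days of supply and are disregarded with an explicit verdict.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from datetime import date
from fractions import Fraction
from typing import Optional, Sequence, Union

import yaml

from .records import (
    Day,
    DosageSchedule,
    DispensingEvent,
    MedicationHistory,
    ObservationWindow,
    PatientRecord,
    day_add,
    day_diff,
)

__all__ = [
    "StandardsPolicy",
    "DoseChange",
    "Eligibility",
    "EligibilityError",
    "determine_window",
    "check_eligibility",
    "merge_equivalent_medications",
    "apply_dose_changes",
    "truncate_at_window_end",
    "apply_standards",
]

DISREGARD_FLAGS = {"prn", "as_needed", "variable_dose"}
MERGE_FLAGS = {"switch", "duplicate", "generic", "combination"}


class EligibilityError(ValueError):
    pass


@dataclass(frozen=True)
class StandardsPolicy:
    """Named switches for every standardisation rule, defaults reproduce the
    full rule set.

    ``start_rule``: ``"first-fill"`` or ``"fixed-date"`` (with ``start_date``).
    ``end_rule``: ``"last-refill"`` or ``"review-date"`` (with ``review_date``).
    ``min_refills``: patients with fewer refill dates are excluded (default 3,
    i.e. two refills or less are excluded); ``min_refills_scope`` is
    ``"patient"`` by default, ``"medication"`` applies the rule per history.
    ``carryover``: surplus supply flows forward into later gaps (never back).
    ``truncate_last_dispensation``: doses of the final dispensation beyond the
    window end are excluded from coverage and surplus accounting.
    """

    start_rule: str = "first-fill"
    start_date: Optional[Day] = None
    end_rule: str = "review-date"
    review_date: Optional[Day] = None
    min_refills: int = 3
    min_refills_scope: str = "patient"
    carryover: bool = True
    truncate_last_dispensation: bool = True
    merge_switch: bool = True
    merge_duplication: bool = True
    merge_generic: bool = True
    merge_combination: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "StandardsPolicy":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown policy key(s): {', '.join(sorted(unknown))}")
        data = dict(data)
        for key in ("start_date", "review_date"):
            value = data.get(key)
            if isinstance(value, str):
                data[key] = date.fromisoformat(value)
        return cls(**data)

    @classmethod
    def from_yaml(cls, source: str) -> "StandardsPolicy":
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def fingerprint(self) -> str:
        payload = {f.name: str(getattr(self, f.name)) for f in fields(self)}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DoseChange:
    """A prescribed change of the daily dosage, effective from a given date."""

    medication_id: str
    effective_date: Day
    new_schedule: DosageSchedule


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    rule: str
    reason: str


def determine_window(record: PatientRecord, policy: StandardsPolicy) -> ObservationWindow:
    """Observation window under the policy's start and end rules (half-open).

    With the default first-fill start the window opens on the earliest
    dispensation date across all medications.  A calendar review date is the
    (excluded) end bound; an integer review day N means "through day N" and
    maps to the half-open end N+1.  The last-refill end rule closes the window
    on the final dispensation date itself.
    """
    all_dates = record.refill_dates
    if not all_dates:
        raise EligibilityError("record has no dispensations")
    if policy.start_rule == "first-fill":
        start = all_dates[0]
    elif policy.start_rule == "fixed-date":
        if policy.start_date is None:
            raise ValueError("fixed-date start rule requires start_date")
        start = policy.start_date
    else:
        raise ValueError(f"unknown start rule {policy.start_rule!r}")

    if policy.end_rule == "last-refill":
        end = all_dates[-1]
        if day_diff(end, start) < 1:  # single refill date: degenerate window
            end = day_add(end, 1)
    elif policy.end_rule == "review-date":
        if policy.review_date is None:
            end = record.window.end
        else:
            end = (
                policy.review_date + 1
                if isinstance(policy.review_date, int)
                else policy.review_date
            )
        if day_diff(end, start) < 1:
            raise EligibilityError(f"review date {end} is not after the first dispensation {start}")
    else:
        raise ValueError(f"unknown end rule {policy.end_rule!r}")
    return ObservationWindow(start, end)


def _is_disregarded(history: MedicationHistory) -> bool:
    return any(e.event_flag in DISREGARD_FLAGS for e in history.events)


def check_eligibility(
    subject: Union[MedicationHistory, PatientRecord], policy: StandardsPolicy
) -> Eligibility:
    """Apply the refill-count exclusion (and the variable-dose/as-needed
    disregard rule for single histories)."""
    if isinstance(subject, MedicationHistory):
        if _is_disregarded(subject):
            return Eligibility(False, "variable-dose-or-prn", "disregarded: dosage not quantifiable")
        n = len(subject.events)
    else:
        n = len(subject.refill_dates)
    if n < policy.min_refills:
        return Eligibility(
            False,
            "min-refills",
            f"excluded: two refills or less ({n} refill date(s) < {policy.min_refills})",
        )
    return Eligibility(True, "min-refills", f"included: {n} refill dates")


def _sort_key(d: Day):
    return d if isinstance(d, int) else d.toordinal()


def merge_equivalent_medications(
    histories: Sequence[MedicationHistory], policy: StandardsPolicy
) -> list[MedicationHistory]:
    """Collapse switched / duplicated / generic / combination products sharing
    a therapeutic class into one history under the index medication.

    A history participates in merging when its events carry a therapy class
    and either an explicit merge annotation (``switch``, ``duplicate``,
    ``generic``, ``combination``) or another history of the same class exists
    and duplication merging is enabled.  The index medication is the product
    with the first refill in time; merged events are the union, ordered, with
    no event lost or double-counted.  Idempotent and order-independent.
    """
    flag_enabled = {
        "switch": policy.merge_switch,
        "duplicate": policy.merge_duplication,
        "generic": policy.merge_generic,
        "combination": policy.merge_combination,
    }
    by_class: dict[str, list[MedicationHistory]] = {}
    untouched: list[MedicationHistory] = []
    for hist in histories:
        cls = next((e.therapy_class for e in hist.events if e.therapy_class), None)
        flags = {e.event_flag for e in hist.events if e.event_flag in MERGE_FLAGS}
        mergeable = cls is not None and (
            any(flag_enabled.get(f, False) for f in flags)
            or (not flags and policy.merge_duplication)
        )
        if mergeable:
            by_class.setdefault(cls, []).append(hist)
        else:
            untouched.append(hist)

    merged: list[MedicationHistory] = []
    for cls, group in by_class.items():
        if len(group) == 1:
            merged.append(group[0])
            continue
        events = [e for h in group for e in h.events]
        index = min(group, key=lambda h: (_sort_key(h.therapy_start), h.index_medication))
        ends = [h.therapy_end for h in group if h.therapy_end is not None]
        therapy_end = max(ends, key=_sort_key) if len(ends) == len(group) else None
        merged.append(MedicationHistory(index.index_medication, events, therapy_end=therapy_end))
    result = untouched + merged
    return sorted(result, key=lambda h: (_sort_key(h.therapy_start), h.index_medication))


def apply_dose_changes(
    history: MedicationHistory, changes: Sequence[DoseChange]
) -> MedicationHistory:
    """Attach prescribed dose changes to a history.

    The consumption rate used by the supply diary switches to the new daily
    dose from the effective date forward; on-hand stock is preserved in units
    and therefore re-expressed in days at the new rate automatically.
    """
    relevant = [c for c in changes if c.medication_id == history.index_medication]
    if not relevant:
        return history
    seen: dict = {}
    for change in relevant:
        key = _sort_key(change.effective_date)
        if key in seen and seen[key].new_schedule != change.new_schedule:
            raise ValueError(
                f"contradictory dose changes for {history.index_medication} on {change.effective_date}"
            )
        seen[key] = change
    ordered = [seen[k] for k in sorted(seen)]
    new = MedicationHistory(history.index_medication, list(history.events), history.therapy_end)
    new.dose_changes = [(c.effective_date, c.new_schedule) for c in ordered]  # type: ignore[attr-defined]
    return new


def dose_breakpoints(history: MedicationHistory) -> list[tuple[Day, DosageSchedule]]:
    """Step function of the daily dosage in force: each dispensation's schedule
    applies from its date, overridden by any prescribed dose changes."""
    points = [(e.date, e.schedule) for e in history.events]
    points.extend(getattr(history, "dose_changes", []))
    points.sort(key=lambda p: _sort_key(p[0]))
    return points


def dose_on_day(breakpoints: Sequence[tuple[Day, DosageSchedule]], window_offset_fn, day: int) -> Fraction:
    """Daily dose in force on a window-relative day (last breakpoint wins)."""
    dose = breakpoints[0][1].daily_dose
    for when, schedule in breakpoints:
        if window_offset_fn(when) <= day:
            dose = schedule.daily_dose
        else:
            break
    return dose


def truncate_at_window_end(
    history: MedicationHistory, window: ObservationWindow
) -> Fraction:
    """Units of the final dispensation that can only be consumed after the end
    of the observation period (or the medication's own therapy end).

    These units count neither toward covered days nor toward the end-of-window
    surplus statistic.  Returned in dispensing units (exact fraction).
    """
    last = history.events[-1]
    end = window.length_days
    if history.therapy_end is not None:
        end = min(end, window.offset(history.therapy_end))
    start = window.offset(last.date)
    if start >= end:
        return last.quantity
    breakpoints = dose_breakpoints(history)
    consumable = sum(
        (dose_on_day(breakpoints, window.offset, d) for d in range(max(start, 0), end)),
        Fraction(0),
    )
    excess = last.quantity - consumable
    return excess if excess > 0 else Fraction(0)


def apply_standards(record: PatientRecord, policy: StandardsPolicy) -> PatientRecord:
    """Full preprocessing pipeline: disregard unquantifiable medications,
    enforce eligibility, merge equivalent products, fix the window.

    Raises :class:`EligibilityError` when the patient is excluded.
    """
    kept = []
    for hist in record.histories:
        if _is_disregarded(hist):
            continue
        kept.append(hist)
    if not kept:
        raise EligibilityError(f"patient {record.patient_id}: no quantifiable medications")
    working = PatientRecord(record.patient_id, kept, record.window)
    verdict = check_eligibility(working, policy)
    if not verdict.eligible:
        raise EligibilityError(f"patient {record.patient_id}: {verdict.reason}")
    histories = merge_equivalent_medications(working.histories, policy)
    if policy.min_refills_scope == "medication":
        histories = [h for h in histories if check_eligibility(h, policy).eligible]
        if not histories:
            raise EligibilityError(f"patient {record.patient_id}: no eligible medication history")
    window = determine_window(working, policy)
    return PatientRecord(record.patient_id, histories, window)
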