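"""The daily polypharmacy possession ratio (DPPR) and averaged-MPR comparators.

The DPPR scores each day in the observation period by the proportion of the
medications expected that day that are actually available (0 = none, 1 = all,
k/m in between), then averages the scores over the window:

    DPPR = ( sum over days of  available_d / expected_d ) / number of days

Because every day's score is bounded by 1, the index cannot be inflated by
oversupply, stockpiling or duplication — the failure mode of averaging
single-medication MPRs over a regimen, where surplus of one medication
compensates missing days of another.  Two averaged-MPR comparators are kept
first class because both circulate in practice:

* ``pooled``: sum of all days' supply over the sum of the per-medication
  observation days;
* ``mean``: mean of the per-medication total days' supply over a common
  window length.

Scores are exact rationals (thirds, quarters, sixths) throughout; rounding
happens only when a report is formatted.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .diary import StockSummary, SupplyDiary, build_diary, stock_summary
from .records import MedicationHistory, ObservationWindow, PatientRecord
from .standards import StandardsPolicy, apply_standards

__all__ = [
    "DailyScore",
    "AdherenceReport",
    "daily_scores",
    "scores_from_segments",
    "compute_dppr",
    "average_mpr",
    "average_mpr_from_supplies",
    "build_report",
    "round_half_up",
]


@dataclass(frozen=True)
class DailyScore:
    """Availability score of one day: available / expected medications."""

    day: int
    available_count: int
    expected_count: int

    @property
    def score(self) -> Fraction:
        if self.expected_count == 0:
            return Fraction(0)
        return Fraction(self.available_count, self.expected_count)

    @property
    def counted(self) -> bool:
        """Days with no expected medication are dropped from the denominator."""
        return self.expected_count > 0


@dataclass(frozen=True)
class AdherenceReport:
    patient_id: str
    dppr: Fraction
    average_mpr_pooled: Fraction
    average_mpr_mean: Fraction
    stock: StockSummary
    window: ObservationWindow
    policy_fingerprint: str


def daily_scores(diary: SupplyDiary) -> list[DailyScore]:
    """One score per window day from a built supply diary."""
    scores = []
    for day in range(diary.window.length_days):
        expected = sum(1 for m in diary.medications if m.expected[day])
        available = sum(1 for m in diary.medications if m.available[day])
        scores.append(DailyScore(day, available, expected))
    return scores


def scores_from_segments(segments: Sequence[tuple]) -> list[DailyScore]:
    """Expand a run-length decomposition ``[(days, available, expected), ...]``
    into daily scores (used for published per-day decompositions)."""
    scores = []
    day = 0
    for days, available, expected in segments:
        for _ in range(days):
            scores.append(DailyScore(day, available, expected))
            day += 1
    return scores


def compute_dppr(scores: Sequence[DailyScore]) -> Fraction:
    """Sum the daily scores and divide by the number of scored days."""
    counted = [s for s in scores if s.counted]
    if not counted:
        raise ValueError("no scored days: every day has zero expected medications")
    return sum((s.score for s in counted), Fraction(0)) / len(counted)


def _supply_in_window(history: MedicationHistory, window: ObservationWindow) -> Fraction:
    from .single_med import _numerator  # shared inclusion rule (boundary fill counts)

    return _numerator(history, window, include_last=True)


def _med_window_days(history: MedicationHistory, window: ObservationWindow) -> int:
    if history.therapy_end is not None:
        return min(window.length_days, window.offset(history.therapy_end))
    return window.length_days


def average_mpr(record: PatientRecord, variant: str = "pooled") -> Fraction:
    """Averaged single-medication MPR over a regimen (known to overestimate).

    ``pooled``: sum of days' supply over sum of per-medication window days
    (a medication's own therapy end caps its denominator).
    ``mean``: mean of per-medication days' supply over the common window.
    """
    if not record.histories:
        raise ValueError("record has no medications")
    supplies = [_supply_in_window(h, record.window) for h in record.histories]
    if variant == "pooled":
        lengths = [_med_window_days(h, record.window) for h in record.histories]
        return sum(supplies, Fraction(0)) / sum(lengths)
    if variant == "mean":
        return average_mpr_from_supplies(supplies, record.window.length_days, variant="mean")
    raise ValueError(f"unknown average-MPR variant {variant!r}")


def average_mpr_from_supplies(
    supplies: Sequence[Fraction],
    window_days: int,
    lengths: Optional[Sequence[int]] = None,
    variant: str = "mean",
) -> Fraction:
    """Averaged MPR from per-medication days'-supply totals.

    Useful when only summary totals are known (e.g. published case tables).
    """
    supplies = [Fraction(s) for s in supplies]
    if not supplies:
        raise ValueError("no medications")
    if variant == "mean":
        return (sum(supplies, Fraction(0)) / len(supplies)) / window_days
    if variant == "pooled":
        lengths = list(lengths) if lengths is not None else [window_days] * len(supplies)
        return sum(supplies, Fraction(0)) / sum(lengths)
    raise ValueError(f"unknown average-MPR variant {variant!r}")


def build_report(
    record: PatientRecord,
    policy: Optional[StandardsPolicy] = None,
    preprocess: bool = True,
) -> AdherenceReport:
    """Standards preprocessing + supply diary + all indices, in one call."""
    policy = policy or StandardsPolicy()
    prepared = apply_standards(record, policy) if preprocess else record
    diary = build_diary(prepared, policy)
    return AdherenceReport(
        patient_id=prepared.patient_id,
        dppr=compute_dppr(daily_scores(diary)),
        average_mpr_pooled=average_mpr(prepared, "pooled"),
        average_mpr_mean=average_mpr(prepared, "mean"),
        stock=stock_summary(diary),
        window=prepared.window,
        policy_fingerprint=policy.fingerprint(),
    )


def round_half_up(value: Fraction, digits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), as adherence
    percentages are conventionally reported."""
    value = Fraction(value)
    scale = Fraction(10) ** digits
    scaled = value * scale
    sign = -1 if scaled < 0 else 1
    rounded = (abs(scaled) + Fraction(1, 2)).__floor__() * sign
    result = Fraction(rounded, 1) / scale
    return float(result) if digits > 0 else int(result)
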