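"""Single-medication possession indices: refill intervals, MPR variants, gaps.

For one medication observed over a window, each refill interval ``n`` carries
the days' supply obtained at its start (``A_n`` = quantity / daily dose), the
days elapsed before the subsequent fill or the window end (``B_n``), the
interval adherence ``A_n/B_n`` and the gap ``G_n = B_n - A_n`` (positive: days
without supply; negative: surplus).  From these the classical indices follow:

* MPR, uncapped: total days' supply over the window divided by the window
  length, with or without the supply of the last dispensation — may exceed 1.
* capped variant: unweighted mean of per-interval ratios truncated at 1.0
  (the proportion-of-days-covered style of index) — bounded by 1.
* gap proportion: sum of (signed, or negative-zeroed) gaps over the window.
* days without medication: total positive gap days, optionally after forward
  carryover of surplus.

Two window conventions are supported and auto-detected from the window: when
the window opens on the first dispensation date, intervals run fill-to-fill
("refill-date start"); when it opens earlier or later ("arbitrary start") the
first interval runs from the window start to the second in-window fill, and
supply on hand from a pre-window dispensation is credited to it.

Carryover follows the forward-only rule: surplus supply from an interval can
be consumed in later intervals with gaps, but a later refill never recolours
an earlier uncovered day (no retroactive compensation).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .records import (
    DispensingEvent,
    MedicationHistory,
    ObservationWindow,
    days_supply,
)

__all__ = [
    "IntervalMetrics",
    "MprResult",
    "interval_metrics",
    "medication_window",
    "mpr",
    "gap_proportion",
    "days_without_medication",
]


def medication_window(history: MedicationHistory, window: ObservationWindow) -> ObservationWindow:
    """The patient window capped at the medication's own therapy end, if any."""
    if history.therapy_end is None:
        return window
    end = min(window.offset(window.end), window.offset(history.therapy_end))
    from .records import day_add

    return ObservationWindow(window.start, day_add(window.start, end))


@dataclass(frozen=True)
class IntervalMetrics:
    """Supply, length, adherence ratio and gap for one refill interval."""

    index_n: int
    A_n: Fraction  # days' supply credited to the interval
    B_n: int  # days elapsed to the next fill / window end
    G_n: Fraction  # B_n - A_n; positive = gap, negative = surplus

    @property
    def ratio(self) -> Fraction:
        return self.A_n / self.B_n


@dataclass(frozen=True)
class MprResult:
    numerator_days: Fraction
    denominator_days: int
    value: Fraction
    variant: str


def _pre_window_leftover(history: MedicationHistory, window: ObservationWindow) -> Fraction:
    """Units-per-day leftover, in days of supply, from fills before the window
    start that would still be on hand on day 0 (consumption from fill date)."""
    leftover = Fraction(0)
    for ev in history.events:
        off = window.offset(ev.date)
        if off >= 0:
            break
        remaining = days_supply(ev) + off  # off is negative days already elapsed
        if remaining > 0:
            leftover += remaining
    return leftover


def _window_events(history: MedicationHistory, window: ObservationWindow) -> list[DispensingEvent]:
    return [e for e in history.events if 0 <= window.offset(e.date) < window.length_days]


def interval_metrics(
    history: MedicationHistory,
    window: Optional[ObservationWindow] = None,
    carryover: bool = False,
) -> list[IntervalMetrics]:
    """Per-interval supply/length/gap records for one medication.

    With ``carryover=True`` surplus is reallocated forward: each interval's
    oversupply may be consumed by later intervals with gaps (earliest surplus
    first), so a deficit interval's gap shrinks by the surplus actually
    available to it and a surplus interval keeps only the surplus that is
    never needed later.  Reallocation is strictly forward in time.
    """
    window = window or ObservationWindow(history.therapy_start, history.events[-1].date)
    events = _window_events(history, window)
    if not events:
        raise ValueError("no dispensations inside the observation window")
    length = window.length_days

    starts: list[int]
    supplies: list[Fraction]
    if window.offset(events[0].date) == 0:
        # refill-date start: intervals run fill-to-fill, last fill to window end
        starts = [window.offset(e.date) for e in events]
        supplies = [days_supply(e) for e in events]
    else:
        # arbitrary start: first interval runs from the window start to the
        # second fill; the first in-window fill and any pre-window leftover
        # supply are credited to it
        starts = [0] + [window.offset(e.date) for e in events[1:]]
        supplies = [days_supply(events[0]) + _pre_window_leftover(history, window)] + [
            days_supply(e) for e in events[1:]
        ]

    bounds = starts[1:] + [length]
    metrics = [
        IntervalMetrics(i + 1, supplies[i], bounds[i] - starts[i], bounds[i] - starts[i] - supplies[i])
        for i in range(len(starts))
        if bounds[i] > starts[i]
    ]
    if carryover:
        metrics = _carryover_adjust(metrics)
    return metrics


def _carryover_adjust(metrics: list[IntervalMetrics]) -> list[IntervalMetrics]:
    """Forward allocation of surplus to later gaps (no retroactive effect)."""
    gaps = [m.G_n for m in metrics]
    surplus_pool: list[list] = []  # [index, remaining surplus] in time order
    adjusted = list(gaps)
    for i, g in enumerate(gaps):
        if g < 0:
            surplus_pool.append([i, -g])
            continue
        shortfall = g
        for entry in surplus_pool:
            if shortfall == 0:
                break
            draw = min(entry[1], shortfall)
            entry[1] -= draw
            shortfall -= draw
        adjusted[i] = shortfall
    for idx, remaining in surplus_pool:
        adjusted[idx] = -remaining
    return [
        IntervalMetrics(m.index_n, m.B_n - adjusted[i], m.B_n, adjusted[i])
        for i, m in enumerate(metrics)
    ]


def _numerator(history: MedicationHistory, window: ObservationWindow, include_last: bool) -> Fraction:
    # every dispensation up to and including the window-end boundary counts;
    # the "without last refill" variant drops the latest of them
    events = [e for e in history.events if 0 <= window.offset(e.date) <= window.length_days]
    if not events:
        raise ValueError("no dispensations inside the observation window")
    total = sum((days_supply(e) for e in events), Fraction(0))
    total += _pre_window_leftover(history, window)
    if not include_last:
        total -= days_supply(events[-1])
    return total


def mpr(
    history: MedicationHistory,
    window: Optional[ObservationWindow] = None,
    include_last_refill: bool = True,
    cap_intervals: bool = False,
) -> MprResult:
    """Medication possession ratio over the observation window.

    Uncapped: total days' supply / window length; ``include_last_refill``
    controls whether the final dispensation's supply enters the numerator
    (a fill exactly on the window-end date counts as the last refill).
    ``cap_intervals``: unweighted mean of per-interval ratios truncated at
    1.0, which is bounded by 1 and underestimates relative to the uncapped
    form whenever oversupply exists.
    """
    window = window or ObservationWindow(history.therapy_start, history.events[-1].date)
    if cap_intervals:
        intervals = interval_metrics(history, window)
        capped = [min(m.ratio, Fraction(1)) for m in intervals]
        value = sum(capped, Fraction(0)) / len(capped)
        return MprResult(sum(capped, Fraction(0)), len(capped), value, "capped-intervals")
    numerator = _numerator(history, window, include_last_refill)
    variant = "with-last-refill" if include_last_refill else "without-last-refill"
    return MprResult(numerator, window.length_days, numerator / window.length_days, variant)


def gap_proportion(
    history: MedicationHistory,
    window: Optional[ObservationWindow] = None,
    negatives_to_zero: bool = False,
    carryover: bool = False,
) -> Fraction:
    """Proportion of time without adequate supply: sum of gaps over the window.

    Signed by default (negative values flag surplus); ``negatives_to_zero``
    zeroes surplus intervals first, masking oversupply.  With ``carryover``
    gaps are computed from the carryover-adjusted intervals.
    """
    metrics = interval_metrics(history, window, carryover=carryover)
    gaps = [max(m.G_n, Fraction(0)) if negatives_to_zero else m.G_n for m in metrics]
    total_b = sum(m.B_n for m in metrics)
    return sum(gaps, Fraction(0)) / total_b


def days_without_medication(
    history: MedicationHistory,
    window: Optional[ObservationWindow] = None,
    carryover: bool = False,
) -> Fraction:
    """Total days without supply: the sum of positive interval gaps.

    Carryover can only reduce the count (surplus fills later gaps), never
    increase it.
    """
    metrics = interval_metrics(history, window, carryover=carryover)
    return sum((m.G_n for m in metrics if m.G_n > 0), Fraction(0))
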