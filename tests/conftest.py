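from fractions import Fraction

import pytest

import adherence as adh


@pytest.fixture
def fig1():
    """Single-medication scenario: history plus both window conventions."""
    record = adh.builtin_fixture("fig1_single")
    extras = adh.fixture_extras("fig1_single")
    return record.histories[0], extras["refill_window"], extras["arbitrary_window"]


@pytest.fixture
def fig2():
    return adh.builtin_fixture("fig2_polypharmacy")


@pytest.fixture
def box1_m1():
    return adh.builtin_fixture("box1_M1")


def brute_force_coverage(events, window):
    """Independent per-day unit-consumption oracle.

    Walks the window day by day with stock in units; a day is covered iff at
    least one daily dose is on hand at that day's dosing rate (the schedule of
    the most recent dispensation).  Deliberately re-derived here, separate
    from the package's diary implementation.
    """
    length = window.length_days
    fills = {}
    for ev in events:
        off = window.offset(ev.date)
        if 0 <= off < length:
            fills.setdefault(off, Fraction(0))
            fills[off] += ev.quantity
    schedule_points = sorted(
        (window.offset(e.date), e.schedule.daily_dose) for e in events
    )
    first = min(fills) if fills else length
    covered = []
    stock = Fraction(0)
    for day in range(length):
        stock += fills.get(day, Fraction(0))
        if day < first:
            covered.append(None)  # not yet expected
            continue
        dose = schedule_points[0][1]
        for when, d in schedule_points:
            if when <= day:
                dose = d
        if stock >= dose:
            stock -= dose
            covered.append(True)
        else:
            covered.append(False)
    return covered, stock
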