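"""Built-in dispensing scenarios used throughout the tests and documentation.

Three families of scenarios are registered:

* ``fig1_single`` — a seven-dispensation single-medication refill history over
  a 250-day observation period, analysed both from the first refill date and
  from an arbitrary (shifted) start date.  This is the classic once-daily
  chronic-medication scenario used to show how the medication possession ratio
  reacts to the choice of window, gaps, oversupply and capping.
* ``fig2_polypharmacy`` — three concurrent once-daily medications with pack
  sizes 14/30/60 and 15 dispensations, the scenario in which naively averaged
  MPRs reach 135 % while the per-day index stays bounded.
* ``box1_M1`` / ``box1_F1`` / ``box1_F2`` — three real 31-month refill
  histories from a community pharmacy (a 4-, 3- and 6-medication regimen),
  transcribed from the published case tables.

Transcription notes.  The published case tables are flattened in extraction
and column alignment of a few cells is ambiguous.  The M1 and F2 transcriptions
below reproduce every published per-medication supply total exactly and are
therefore trusted at event level.  For F1 the published totals cannot be
reconciled with any cell assignment we could read (the metformin column parses
to 2000 units where the published calculation uses 500 days' supply, and 18
refill rows parse where 17 refill dates are reported); the F1 events are a
best-effort reading, and all F1 summary quantities used in validation come
from the published per-day segment decomposition and totals, which this module
also carries verbatim (``extras``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from fractions import Fraction
from typing import Optional

from .records import (
    DispensingEvent,
    MedicationHistory,
    ObservationWindow,
    PatientRecord,
    parse_schedule,
)

__all__ = ["builtin_fixture", "fixture_extras", "fixture_names", "UnknownFixtureError"]


class UnknownFixtureError(KeyError):
    pass


def _d(text: str):
    return datetime.strptime(text, "%d.%m.%y").date()


# ---------------------------------------------------------------------------
# single-medication scenario (once daily, seven dispensations, 250-day window)
#
# Refills (absolute day, quantity): intervals from the first refill are
# 70/20/85/40/25/10 days against supplies 60/30/60/60/30/30; the final 30-unit
# refill falls exactly on the window end.  The "arbitrary" window starts 20
# days before the first fill and ends 250 days later, which drops the last two
# dispensations from the window.

_FIG1_FILLS = [(21, 60), (91, 30), (111, 60), (196, 60), (236, 30), (261, 30), (271, 30)]
_FIG1_REFILL_WINDOW = ObservationWindow(21, 271)
_FIG1_ARBITRARY_WINDOW = ObservationWindow(1, 251)


def _fig1_record() -> PatientRecord:
    schedule = parse_schedule("1-0-0")
    events = [DispensingEvent("antihypertensive", day, qty, schedule) for day, qty in _FIG1_FILLS]
    history = MedicationHistory("antihypertensive", events)
    return PatientRecord("fig1", [history], _FIG1_REFILL_WINDOW)


# ---------------------------------------------------------------------------
# polypharmacy averaging scenario: 3 once-daily medications, 15 dispensations.
# Integer "day k ... end at day N" inputs map to the half-open [1, N+1).

_FIG2_MEDS = [
    # (medication, pack, fill days, inclusive end day)
    ("med1_pack14", 14, [1, 15, 29, 43, 57, 71, 101], 110),
    ("med2_pack30", 30, [1, 41, 61, 120], 120),
    ("med3_pack60", 60, [1, 31, 51, 101], 110),
]


def _fig2_record() -> PatientRecord:
    schedule = parse_schedule("1-0-0")
    histories = []
    for med, pack, days, end in _FIG2_MEDS:
        events = [DispensingEvent(med, day, pack, schedule) for day in days]
        histories.append(MedicationHistory(med, events, therapy_end=end + 1))
    return PatientRecord("fig2", histories, ObservationWindow(1, 121))


# The published per-day score decomposition for this scenario (count of days,
# medications available, medications expected).  Exact fractions sum to
# 105/120 = 87.5 %; note the decomposition is NOT fully consistent with a
# per-day reconstruction from the raw refills (see docs/methods.md).
_FIG3_SEGMENTS = [
    (10, 1, 1), (20, 3, 3), (10, 2, 3), (54, 3, 3),
    (6, 2, 3), (10, 1, 3), (9, 2, 3), (1, 3, 3),
]


# ---------------------------------------------------------------------------
# Box-table patients.  Rows: (date, per-medication quantity); 0 = no fill.

_M1_MEDS = [
    ("atorvastatin_20", "1-0-0"),
    ("metoprolol_25", "1-0-0"),
    ("aspirin_100", "1-0-0"),
    ("salmeterol_fluticasone", "1-0-0"),
]
_M1_ROWS = [
    ("11.01.11", [100, 0, 90, 60]),
    ("05.04.11", [100, 0, 196, 60]),
    ("11.10.11", [100, 100, 98, 60]),
    ("12.01.12", [100, 100, 98, 60]),
    ("07.03.12", [100, 100, 98, 60]),
    ("27.06.12", [0, 0, 0, 60]),
    ("08.08.12", [100, 100, 98, 120]),
    ("07.12.12", [100, 100, 98, 60]),
    ("27.02.13", [100, 100, 98, 60]),
    ("23.04.13", [0, 0, 0, 60]),
    ("14.06.13", [100, 100, 98, 120]),
]
_M1_REVIEW = "31.07.13"
_M1_SEGMENTS = [
    (60, 3, 3), (24, 2, 3), (60, 3, 3), (56, 2, 3), (73, 1, 3),
    (60, 4, 4), (33, 3, 4), (55, 4, 4), (65, 4, 4), (47, 3, 4),
    (40, 4, 4), (2, 2, 4), (100, 4, 4), (3, 2, 4), (18, 1, 4),
    (77, 4, 4), (5, 3, 4), (55, 4, 4), (52, 4, 4), (47, 4, 4),
]

_F1_MEDS = [
    ("metformin_850", "1-0-1"),
    ("fosinopril_20", "1-0-0"),
    ("glibornurid_25", "1/2-0-1/2"),
]
_F1_ROWS = [
    ("18.01.11", [100, 98, 0]),
    ("18.03.11", [100, 98, 100]),
    ("14.05.11", [100, 0, 0]),
    ("27.06.11", [100, 98, 100]),
    ("12.08.11", [100, 0, 0]),
    ("01.10.11", [100, 98, 100]),
    ("21.11.11", [100, 0, 0]),
    ("23.01.12", [100, 98, 100]),
    ("01.03.12", [100, 0, 0]),
    ("16.04.12", [100, 98, 100]),
    ("19.06.12", [100, 0, 0]),
    ("02.08.12", [200, 98, 100]),
    ("20.11.12", [100, 98, 100]),
    ("31.12.12", [100, 0, 0]),
    ("19.02.13", [100, 98, 100]),
    ("08.04.13", [100, 0, 0]),
    ("25.05.13", [100, 98, 100]),
    ("16.07.13", [200, 0, 100]),
]
_F1_REVIEW = "31.07.13"
_F1_SEGMENTS = [
    (50, 2, 2), (9, 1, 2), (50, 3, 3), (7, 2, 3), (43, 3, 3), (1, 2, 3),
    (46, 3, 3), (50, 3, 3), (51, 3, 3), (53, 3, 3), (6, 2, 3), (4, 1, 3),
    (38, 3, 3), (46, 3, 3), (64, 3, 3), (44, 3, 3), (108, 3, 3), (2, 1, 3),
    (41, 3, 3), (50, 3, 3), (48, 3, 3), (47, 3, 3), (52, 3, 3), (15, 3, 3),
]

_F2_MEDS = [
    ("gliclazid_30", "2-0-0"),
    ("sitagliptin_100", "1-0-0"),
    ("aspirin_100", "1-0-0"),
    ("valsartan_80", "1-0-0"),
    ("simvastatin_80", "0-0-1/2"),
    ("ginkgo_biloba", "1-0-1"),
]
_F2_ROWS = [
    ("04.01.11", [120, 98, 0, 0, 0, 0]),
    ("10.02.11", [120, 196, 0, 98, 100, 240]),
    ("03.05.11", [0, 0, 28, 0, 0, 0]),
    ("21.06.11", [120, 0, 0, 98, 0, 120]),
    ("04.08.11", [240, 0, 98, 0, 0, 0]),
    ("18.10.11", [0, 0, 0, 196, 0, 0]),
    ("08.11.11", [0, 98, 0, 0, 0, 0]),
    ("03.12.11", [0, 0, 0, 0, 100, 120]),
    ("03.01.12", [120, 0, 98, 0, 0, 0]),
    ("15.03.12", [120, 98, 0, 98, 0, 0]),
    ("14.05.12", [120, 0, 0, 0, 0, 0]),
    ("04.06.12", [0, 0, 98, 0, 0, 0]),
    ("25.06.12", [0, 98, 0, 98, 0, 0]),
    ("25.08.12", [120, 98, 98, 0, 100, 0]),
    ("20.10.12", [240, 0, 98, 98, 0, 240]),
    ("25.01.13", [120, 98, 0, 0, 0, 0]),
    ("25.02.13", [0, 0, 0, 0, 0, 120]),
    ("05.04.13", [120, 98, 98, 0, 0, 0]),
    ("13.05.13", [0, 0, 0, 0, 100, 0]),
    ("13.07.13", [0, 98, 98, 98, 0, 120]),
]
_F2_REVIEW = "31.07.13"
_F2_SEGMENTS = [
    (37, 2, 2), (82, 5, 5), (1, 6, 6), (15, 5, 6), (12, 4, 6), (10, 3, 6),
    (11, 2, 6), (44, 5, 6), (16, 6, 6), (9, 5, 6), (29, 4, 6), (21, 3, 6),
    (7, 4, 6), (14, 3, 6), (2, 4, 6), (23, 3, 6), (15, 5, 6), (16, 4, 6),
    (29, 6, 6), (13, 5, 6), (18, 4, 6), (12, 3, 6), (26, 5, 6), (34, 4, 6),
    (21, 4, 6), (16, 5, 6), (1, 4, 6), (4, 3, 6), (18, 4, 6), (43, 3, 6),
    (56, 5, 6), (79, 6, 6), (18, 5, 6), (23, 6, 6), (2, 5, 6), (6, 4, 6),
    (16, 5, 6), (12, 4, 6), (11, 3, 6), (13, 4, 6), (25, 3, 6), (39, 4, 6),
    (21, 3, 6), (1, 2, 6), (18, 5, 6),
]


def _box_record(patient_id, meds, rows, review) -> PatientRecord:
    histories = []
    for col, (med, sched_text) in enumerate(meds):
        schedule = parse_schedule(sched_text)
        events = [
            DispensingEvent(med, _d(date), qtys[col], schedule)
            for date, qtys in rows
            if qtys[col] > 0
        ]
        histories.append(MedicationHistory(med, events))
    start = _d(rows[0][0])
    return PatientRecord(patient_id, histories, ObservationWindow(start, _d(review)))


@dataclass(frozen=True)
class _Fixture:
    build: object
    extras: dict = field(default_factory=dict)


_REGISTRY = {
    "fig1_single": _Fixture(
        _fig1_record,
        {
            "refill_window": _FIG1_REFILL_WINDOW,
            "arbitrary_window": _FIG1_ARBITRARY_WINDOW,
        },
    ),
    "fig2_polypharmacy": _Fixture(
        _fig2_record,
        {
            "segments": _FIG3_SEGMENTS,
            "published_mprs_pct": {"med1_pack14": 89, "med2_pack30": 100, "med3_pack60": 218},
            "published_pooled_mpr_pct": 135,
            "published_dppr_pct": Fraction(105, 120) * 100,
        },
    ),
    "box1_M1": _Fixture(
        lambda: _box_record("M1", _M1_MEDS, _M1_ROWS, _M1_REVIEW),
        {
            "segments": _M1_SEGMENTS,
            "supply_day_totals": [900, 700, 972, 780],
            "gap_totals": [-96, -23, -18, -238],
            "window_days": 932,
        },
    ),
    "box1_F1": _Fixture(
        lambda: _box_record("F1", _F1_MEDS, _F1_ROWS, _F1_REVIEW),
        {
            "segments": _F1_SEGMENTS,
            "supply_day_totals": [500, 980, 1000],
            "gap_totals": [-22, 0, -13],
            "window_days": 925,
            "event_level_trusted": False,
        },
    ),
    "box1_F2": _Fixture(
        lambda: _box_record("F2", _F2_MEDS, _F2_ROWS, _F2_REVIEW),
        {
            "segments": _F2_SEGMENTS,
            "supply_day_totals": [780, 980, 714, 784, 800, 480],
            "gap_totals": [-159, -66, -186, -204, -223, -497],
            "window_days": 939,
        },
    ),
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def builtin_fixture(name: str) -> PatientRecord:
    """Return a registered scenario as a fresh :class:`PatientRecord`."""
    try:
        fx = _REGISTRY[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {', '.join(fixture_names())}"
        ) from None
    return fx.build()


def fixture_extras(name: str) -> dict:
    """Auxiliary published data for a scenario (windows, segment decompositions,
    per-medication supply/gap totals)."""
    try:
        return dict(_REGISTRY[name].extras)
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {', '.join(fixture_names())}"
        ) from None
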