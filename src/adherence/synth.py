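"""Synthetic dispensing-history generator with known ground-truth possession.

Real refill behaviour is irregular: patients refill late (gaps), early
(overlap and stockpiling), switch products mid-therapy, start medications
mid-window and have dosages changed.  The generator emulates these behaviours
with a per-medication refill loop whose *target possession* is controlled, and
keeps its own per-day coverage bookkeeping, so estimator bias (averaged MPR
vs per-day index vs truth) is measurable without any external data.

Per medication the loop dispenses one pack at a time.  After each fill the
next refill is scheduled around the depletion date of the on-hand stock:
late by a random delay whose mean matches the target possession (coverage per
cycle = supply / (supply + delay)), early with probability ``p_stockpile``
(overlap: surplus accumulates), plus symmetric day jitter.  Switching emits
the continuation under a new product of the same therapeutic class with
explicit ``switch`` annotations, so the standards merge path is exercised
end to end; dose changes double or halve the schedule mid-history.

All randomness comes from one :class:`numpy.random.Generator` seeded from the
config: a fixed config and seed reproduce the records byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .records import (
    DispensingEvent,
    MedicationHistory,
    ObservationWindow,
    PatientRecord,
    parse_schedule,
)

__all__ = ["SynthConfig", "generate", "ground_truth"]


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 10
    n_medications: tuple = (2, 4)  # inclusive range
    pack_sizes: tuple = (14, 30, 60, 100)
    schedules: tuple = ("1-0-0", "1-0-1", "1/2-0-1/2")
    target_possession: float = 0.8
    refill_jitter: int = 3  # uniform on [-j, +j] days around the planned refill
    p_stockpile: float = 0.1
    p_switch: float = 0.0
    p_dose_change: float = 0.0
    p_mid_entry: float = 0.2  # medication enters the regimen mid-window
    window_days: int = 360
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.target_possession <= 1):
            raise ValueError("target_possession must be in (0, 1]")
        if self.window_days < 2:
            raise ValueError("window must span at least 2 days")
        if min(self.pack_sizes) <= 0:
            raise ValueError("pack sizes must be positive")


def _simulate_medication(rng: np.random.Generator, cfg: SynthConfig, med_id: str):
    """Generate one medication's fills; returns (events, per-day dose list)."""
    pack = int(rng.choice(cfg.pack_sizes))
    schedule = parse_schedule(str(rng.choice(cfg.schedules)))
    start = 0
    if rng.random() < cfg.p_mid_entry:
        start = int(rng.integers(1, max(2, cfg.window_days // 2)))

    switch_at = None
    if rng.random() < cfg.p_switch:
        switch_at = int(rng.integers(start + 1, cfg.window_days))
    dose_change_at = None
    changed_schedule = None
    if rng.random() < cfg.p_dose_change:
        dose_change_at = int(rng.integers(start + 1, cfg.window_days))
        dose = schedule.daily_dose
        changed_schedule = parse_schedule("1-0-1" if dose <= 1 else "1-0-0")

    p = cfg.target_possession
    events: list[DispensingEvent] = []
    stock = Fraction(0)
    day = start + 1  # day index (1-based, integer-day mode)
    while day <= cfg.window_days:
        current_schedule = schedule
        if dose_change_at is not None and day > dose_change_at and changed_schedule is not None:
            current_schedule = changed_schedule
        product = med_id
        flag = None
        therapy_class = None
        if switch_at is not None:
            therapy_class = f"class_{med_id}"
            flag = "switch"
            if day > switch_at:
                product = f"{med_id}b"
        events.append(DispensingEvent(product, day, pack, current_schedule, therapy_class, flag))
        stock += pack
        supply_days = stock / current_schedule.daily_dose
        depletion = day + int(supply_days)  # first day the stock no longer covers
        mean_gap = float(supply_days) * (1 - p) / p
        delay = int(rng.integers(0, int(2 * mean_gap) + 1)) if mean_gap > 0 else 0
        if cfg.p_stockpile > 0 and rng.random() < cfg.p_stockpile:
            early = int(rng.integers(1, max(2, pack // 2)))
            next_fill = max(day + 1, depletion - early)
        else:
            jitter = int(rng.integers(-cfg.refill_jitter, cfg.refill_jitter + 1))
            next_fill = max(day + 1, depletion + delay + jitter)
        consumed_days = min(next_fill, cfg.window_days + 1) - day
        stock -= current_schedule.daily_dose * consumed_days
        if stock < 0:
            stock = Fraction(0)
        day = next_fill
    return events


def _coverage(events: Sequence[DispensingEvent], window_days: int) -> list[bool]:
    """Generator-side per-day coverage bookkeeping (truth), unit ledger."""
    fills: dict[int, Fraction] = {}
    schedules = sorted(((e.date, e.schedule) for e in events), key=lambda p: p[0])
    for e in events:
        fills[e.date] = fills.get(e.date, Fraction(0)) + e.quantity
    first = min(fills)
    covered = [False] * (window_days + 1)  # 1-based days
    stock = Fraction(0)
    for day in range(first, window_days + 1):
        if day in fills:
            stock += fills[day]
        dose = schedules[0][1].daily_dose
        for when, sched in schedules:
            if when <= day:
                dose = sched.daily_dose
            else:
                break
        if stock >= dose:
            stock -= dose
            covered[day] = True
    return covered


def _simulate(cfg: SynthConfig):
    rng = np.random.default_rng(cfg.seed)
    window = ObservationWindow(1, cfg.window_days + 1)
    results = []
    for i in range(cfg.n_patients):
        n_meds = int(rng.integers(cfg.n_medications[0], cfg.n_medications[1] + 1))
        all_events: dict[str, list[DispensingEvent]] = {}
        med_event_groups: list[list[DispensingEvent]] = []
        for m in range(n_meds):
            med_id = f"med{m + 1}"
            events = _simulate_medication(rng, cfg, med_id)
            med_event_groups.append(events)
            for e in events:
                all_events.setdefault(e.medication_id, []).append(e)
        histories = [MedicationHistory(mid, evs) for mid, evs in all_events.items()]
        record = PatientRecord(f"p{i + 1:04d}", histories, window)

        # truth: mean over days (from each medication's first fill) of the
        # share of expected medications covered, per the generator's ledger
        coverages = [_coverage(evs, cfg.window_days) for evs in med_event_groups]
        firsts = [min(e.date for e in evs) for evs in med_event_groups]
        score_sum = Fraction(0)
        scored_days = 0
        for day in range(1, cfg.window_days + 1):
            expected = sum(1 for f in firsts if f <= day)
            if expected == 0:
                continue
            available = sum(
                1 for f, cov in zip(firsts, coverages) if f <= day and cov[day]
            )
            score_sum += Fraction(available, expected)
            scored_days += 1
        truth = score_sum / scored_days if scored_days else Fraction(0)
        results.append((record, truth))
    return results


def generate(config: SynthConfig) -> list[PatientRecord]:
    """Generate dispensing records; valid input for the record reader as-is."""
    return [record for record, _ in _simulate(config)]


def ground_truth(records: Sequence[PatientRecord], config: SynthConfig) -> dict:
    """True per-patient possession proportions for records from :func:`generate`.

    Recomputed from the generator's own per-day coverage bookkeeping; raises
    if the records do not match the config (wrong seed or edited records).
    """
    regenerated = _simulate(config)
    if len(regenerated) != len(records):
        raise ValueError("records do not match config: different patient count")
    truths = {}
    for given, (rebuilt, truth) in zip(records, regenerated):
        if given.patient_id != rebuilt.patient_id or [
            (e.medication_id, e.date, e.quantity) for h in given.histories for e in h.events
        ] != [(e.medication_id, e.date, e.quantity) for h in rebuilt.histories for e in h.events]:
            raise ValueError(f"records do not match config for patient {given.patient_id}")
        truths[given.patient_id] = truth
    return truths
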