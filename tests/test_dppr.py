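from dataclasses import replace
from fractions import Fraction

import pytest

import adherence as adh
from adherence.dppr import DailyScore
from adherence.standards import StandardsPolicy

from conftest import brute_force_coverage

F = Fraction


class TestDailyScores:
    def test_score_is_available_over_expected(self):
        assert DailyScore(0, 2, 3).score == F(2, 3)
        assert DailyScore(0, 0, 4).score == 0
        assert DailyScore(0, 4, 4).score == 1

    def test_zero_expected_days_are_dropped(self):
        scores = [DailyScore(0, 0, 0), DailyScore(1, 1, 1)]
        assert adh.compute_dppr(scores) == 1
        with pytest.raises(ValueError):
            adh.compute_dppr([DailyScore(0, 0, 0)])

    def test_scores_from_diary(self, fig2):
        scores = adh.daily_scores(adh.build_diary(fig2))
        assert len(scores) == 120
        assert scores[0].expected_count == 3 and scores[0].available_count == 3
        # days 111-119: only the 30-pack medication is still expected, stocked out
        assert scores[111].expected_count == 1 and scores[111].available_count == 0


class TestComputeDppr:
    def test_published_segment_decomposition_is_exactly_105_over_120(self):
        segments = adh.fixture_extras("fig2_polypharmacy")["segments"]
        value = adh.compute_dppr(adh.scores_from_segments(segments))
        assert value == F(105, 120)
        assert float(value * 100) == 87.5

    def test_all_available_gives_one(self):
        assert adh.compute_dppr([DailyScore(d, 3, 3) for d in range(10)]) == 1

    def test_bounded_by_one_and_label_invariant(self, fig2):
        value = adh.compute_dppr(adh.daily_scores(adh.build_diary(fig2)))
        assert value <= 1
        shuffled = adh.PatientRecord(fig2.patient_id, list(reversed(fig2.histories)), fig2.window)
        assert adh.compute_dppr(adh.daily_scores(adh.build_diary(shuffled))) == value


class TestAverageMpr:
    def test_pooled_over_per_medication_windows(self, fig2):
        # per-medication MPRs 98/110, 120/120, 240/110 pool to 458/340
        assert adh.average_mpr(fig2, "pooled") == F(458, 340)
        assert adh.round_half_up(adh.average_mpr(fig2, "pooled") * 100) == 135

    def test_single_medication_equals_uncapped_mpr(self, fig1):
        history, window, _ = fig1
        record = adh.PatientRecord("p", [history], window)
        expected = adh.mpr(history, window).value
        assert adh.average_mpr(record, "pooled") == expected
        assert adh.average_mpr(record, "mean") == expected

    def test_from_published_supply_totals(self):
        # mean-variant on the published per-medication days'-supply totals
        assert adh.round_half_up(
            adh.average_mpr_from_supplies([900, 700, 972, 780], 932) * 100
        ) == 90
        assert adh.round_half_up(
            adh.average_mpr_from_supplies([500, 980, 1000], 925) * 100
        ) == 89

    def test_no_medications_rejected(self, fig2):
        with pytest.raises(ValueError):
            adh.average_mpr_from_supplies([], 100)


class TestInsensitivityProperties:
    def test_oversupply_insensitive(self, fig2):
        # doubling every quantity of an always-covered medication cannot
        # change a per-day index bounded at 1
        base = adh.compute_dppr(adh.daily_scores(adh.build_diary(fig2)))
        doubled_histories = []
        for hist in fig2.histories:
            if hist.index_medication == "med3_pack60":
                events = [replace(e, quantity=e.quantity * 2) for e in hist.events]
                doubled_histories.append(
                    adh.MedicationHistory(hist.index_medication, events, hist.therapy_end)
                )
            else:
                doubled_histories.append(hist)
        doubled = adh.PatientRecord("p", doubled_histories, fig2.window)
        assert adh.compute_dppr(adh.daily_scores(adh.build_diary(doubled))) == base
        # whereas the averaged MPR inflates
        assert adh.average_mpr(doubled, "pooled") > adh.average_mpr(fig2, "pooled")

    def test_duplication_insensitive_after_standards_merge(self, fig2):
        # splitting one medication's fills across two same-class products that
        # the standards re-merge leaves the per-day index unchanged
        base = adh.compute_dppr(adh.daily_scores(adh.build_diary(fig2)))
        histories = []
        for hist in fig2.histories:
            if hist.index_medication == "med1_pack14":
                a_events = [
                    replace(e, therapy_class="c1", event_flag="duplicate")
                    for e in hist.events[::2]
                ]
                b_events = [
                    replace(e, medication_id="med1_alt", therapy_class="c1", event_flag="duplicate")
                    for e in hist.events[1::2]
                ]
                histories.append(
                    adh.MedicationHistory("med1_pack14", a_events, hist.therapy_end)
                )
                histories.append(
                    adh.MedicationHistory("med1_alt", b_events, hist.therapy_end)
                )
            else:
                histories.append(hist)
        split = adh.PatientRecord("p", histories, fig2.window)
        merged = adh.merge_equivalent_medications(split.histories, StandardsPolicy())
        assert len(merged) == 3
        remerged = adh.PatientRecord("p", merged, fig2.window)
        assert adh.compute_dppr(adh.daily_scores(adh.build_diary(remerged))) == base

    def test_matches_independent_per_day_oracle(self, fig2):
        diary = adh.build_diary(fig2)
        value = adh.compute_dppr(adh.daily_scores(diary))
        # brute-force recount, per medication, per day
        per_med = []
        for hist in fig2.histories:
            covered, _ = brute_force_coverage(hist.events, fig2.window)
            end = fig2.window.offset(hist.therapy_end)
            per_med.append([c if d < end else None for d, c in enumerate(covered)])
        total = F(0)
        days = 0
        for day in range(fig2.window.length_days):
            expected = sum(1 for cov in per_med if cov[day] is not None)
            available = sum(1 for cov in per_med if cov[day])
            if expected:
                total += F(available, expected)
                days += 1
        assert value == total / days


class TestReports:
    def test_m1_report_values(self, box1_m1):
        policy = StandardsPolicy(review_date=box1_m1.window.end)
        report = adh.build_report(box1_m1, policy)
        assert adh.round_half_up(report.average_mpr_mean * 100) == 90
        assert adh.round_half_up(report.dppr * 100) == 88
        assert adh.round_half_up(report.stock.mean_gap_pct) == -10
        assert report.policy_fingerprint == policy.fingerprint()

    def test_overestimation_direction_for_overadherer(self):
        record = adh.builtin_fixture("box1_F2")
        report = adh.build_report(
            record, StandardsPolicy(review_date=record.window.end)
        )
        assert report.dppr < report.average_mpr_mean

    def test_single_medication_dppr_is_covered_share(self, fig1):
        history, window, _ = fig1
        record = adh.PatientRecord("p", [history], window)
        # integer review day is inclusive: day end-1 closes the half-open window
        report = adh.build_report(record, StandardsPolicy(review_date=window.end - 1))
        diary = adh.build_diary(record)
        med = diary.medications[0]
        assert report.dppr == F(med.covered_days, window.length_days)
        assert report.dppr <= adh.mpr(history, window).value

    def test_empty_regimen_rejected(self):
        empty = adh.PatientRecord("p", [], adh.ObservationWindow(1, 10))
        with pytest.raises(ValueError):
            adh.average_mpr(empty)
        with pytest.raises(adh.EligibilityError):
            adh.build_report(empty, StandardsPolicy())


class TestRounding:
    @pytest.mark.parametrize(
        "value, digits, expected",
        [(F(1855, 20), 1, 92.8), (F(105, 120) * 100, 1, 87.5), (F(-201, 20), 0, -10),
         (F(5, 2), 0, 3), (F(-5, 2), 0, -3)],
    )
    def test_half_away_from_zero(self, value, digits, expected):
        assert adh.round_half_up(value, digits) == expected
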