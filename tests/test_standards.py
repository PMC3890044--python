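from datetime import date
from fractions import Fraction

import pytest

import adherence as adh
from adherence.standards import StandardsPolicy


def _hist(med, fills, schedule="1-0-0", therapy_class=None, flag=None):
    sched = adh.parse_schedule(schedule)
    return adh.MedicationHistory(
        med, [adh.DispensingEvent(med, d, q, sched, therapy_class, flag) for d, q in fills]
    )


class TestWindowDetermination:
    def test_first_fill_to_review_date(self, box1_m1):
        policy = StandardsPolicy(review_date=date(2013, 7, 31))
        window = adh.determine_window(box1_m1, policy)
        assert window.start == date(2011, 1, 11)
        assert window.length_days == 932

    def test_integer_review_day_is_inclusive(self, fig2):
        window = adh.determine_window(fig2, StandardsPolicy(review_date=120))
        assert window == adh.ObservationWindow(1, 121)
        assert window.length_days == 120

    def test_last_refill_end_rule(self, fig1):
        history, _, _ = fig1
        record = adh.PatientRecord("p", [history], adh.ObservationWindow(21, 271))
        window = adh.determine_window(record, StandardsPolicy(end_rule="last-refill"))
        assert window == adh.ObservationWindow(21, 271)  # final dispensation day 271

    def test_review_before_first_fill_rejected(self, fig2):
        with pytest.raises(adh.EligibilityError):
            adh.determine_window(fig2, StandardsPolicy(review_date=0))


class TestEligibility:
    @pytest.mark.parametrize("n, eligible", [(0, False), (2, False), (3, True)])
    def test_refill_count_rule(self, n, eligible):
        policy = StandardsPolicy()
        if n == 0:
            record = None
            if not eligible:
                with pytest.raises(adh.RecordValidationError):
                    _hist("m", [])
            return
        hist = _hist("m", [(d, 10) for d in range(1, 10 * n, 10)][:n])
        verdict = adh.check_eligibility(hist, policy)
        assert verdict.eligible is eligible
        if not eligible:
            assert "two refills or less" in verdict.reason

    def test_variable_dose_medication_disregarded(self):
        hist = _hist("prn_med", [(1, 10), (11, 10), (21, 10)], flag="prn")
        verdict = adh.check_eligibility(hist, StandardsPolicy())
        assert not verdict.eligible
        assert "disregarded" in verdict.reason

    def test_patient_excluded_end_to_end(self):
        record = adh.PatientRecord(
            "p", [_hist("m", [(1, 10), (11, 10)])], adh.ObservationWindow(1, 22)
        )
        with pytest.raises(adh.EligibilityError, match="two refills or less"):
            adh.apply_standards(record, StandardsPolicy())


class TestMerging:
    def test_therapeutic_switch_collapses_to_index_medication(self):
        a = _hist("productA", [(1, 30), (31, 30)], therapy_class="statin", flag="switch")
        b = _hist("productB", [(61, 30), (91, 30)], therapy_class="statin", flag="switch")
        merged = adh.merge_equivalent_medications([a, b], StandardsPolicy())
        assert len(merged) == 1
        assert merged[0].index_medication == "productA"  # first refill in time
        assert len(merged[0].events) == 4

    def test_combination_pill_continues_earlier_history(self):
        early = _hist("mono1", [(1, 30)], therapy_class="combo", flag="combination")
        later = _hist("mono2", [(10, 30)], therapy_class="combo", flag="combination")
        combo = _hist("combopill", [(40, 30)], therapy_class="combo", flag="combination")
        merged = adh.merge_equivalent_medications([early, later, combo], StandardsPolicy())
        assert len(merged) == 1
        assert merged[0].index_medication == "mono1"

    def test_distinct_classes_untouched(self):
        a = _hist("a", [(1, 30)], therapy_class="x")
        b = _hist("b", [(1, 30)], therapy_class="y")
        merged = adh.merge_equivalent_medications([a, b], StandardsPolicy())
        assert sorted(h.index_medication for h in merged) == ["a", "b"]

    def test_no_annotations_no_merge(self):
        a = _hist("a", [(1, 30)])
        b = _hist("b", [(1, 30)])
        assert len(adh.merge_equivalent_medications([a, b], StandardsPolicy())) == 2

    def test_idempotent_order_independent_and_conserving(self):
        a = _hist("a", [(1, 30), (31, 30)], therapy_class="c", flag="duplicate")
        b = _hist("b", [(15, 60)], therapy_class="c", flag="duplicate")
        c = _hist("c", [(5, 14)], therapy_class="other")
        total = sum(h.total_quantity for h in (a, b, c))
        once = adh.merge_equivalent_medications([a, b, c], StandardsPolicy())
        twice = adh.merge_equivalent_medications(once, StandardsPolicy())
        reordered = adh.merge_equivalent_medications([c, b, a], StandardsPolicy())
        for result in (once, twice, reordered):
            assert sum(h.total_quantity for h in result) == total
            assert [h.index_medication for h in result] == [h.index_medication for h in once]

    def test_merge_flags_can_be_disabled(self):
        a = _hist("a", [(1, 30)], therapy_class="c", flag="switch")
        b = _hist("b", [(31, 30)], therapy_class="c", flag="switch")
        policy = StandardsPolicy(merge_switch=False, merge_duplication=False)
        assert len(adh.merge_equivalent_medications([a, b], policy)) == 2


class TestDoseChanges:
    def _coverage_days(self, history, window):
        diary = adh.build_diary(
            adh.PatientRecord("p", [history], window), StandardsPolicy()
        )
        return diary.medications[0].covered_days

    @pytest.mark.parametrize(
        "new_schedule, expected_covered",
        [("1-0-1", 10 + 15), ("1-0-0", 10 + 30)],  # dose 1->2 halves, 1->1 keeps
    )
    def test_on_hand_stock_reexpressed_at_new_rate(self, new_schedule, expected_covered):
        # 40 units at dose 1/day; after 10 days the dose changes; the 30 units
        # on hand must last 30/new_dose further days (brute-force oracle:
        # unit-by-unit consumption)
        hist = _hist("m", [(1, 40)])
        changed = adh.apply_dose_changes(
            hist, [adh.DoseChange("m", 11, adh.parse_schedule(new_schedule))]
        )
        window = adh.ObservationWindow(1, 101)
        assert self._coverage_days(changed, window) == expected_covered

    def test_no_changes_is_identity(self):
        hist = _hist("m", [(1, 40), (41, 40)])
        assert adh.apply_dose_changes(hist, []) is hist

    def test_contradictory_changes_rejected(self):
        hist = _hist("m", [(1, 40)])
        changes = [
            adh.DoseChange("m", 11, adh.parse_schedule("1-0-1")),
            adh.DoseChange("m", 11, adh.parse_schedule("2-0-1")),
        ]
        with pytest.raises(ValueError, match="contradictory"):
            adh.apply_dose_changes(hist, changes)


class TestEndOfWindowTruncation:
    @pytest.mark.parametrize(
        "pack, fill_day, expected_excess",
        [(60, 101, 50), (14, 101, 4), (10, 101, 0)],  # window day 110 inclusive
    )
    def test_last_dispensation_excess(self, pack, fill_day, expected_excess):
        hist = _hist("m", [(1, 100), (fill_day, pack)])
        hist.therapy_end = 111
        window = adh.ObservationWindow(1, 121)
        assert adh.truncate_at_window_end(hist, window) == expected_excess

    def test_exact_depletion_leaves_nothing(self):
        hist = _hist("m", [(1, 30)])
        assert adh.truncate_at_window_end(hist, adh.ObservationWindow(1, 31)) == 0


class TestPolicyConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text("min_refills: 4\ncarryover: false\nend_rule: last-refill\n")
        policy = StandardsPolicy.from_yaml(str(path))
        assert policy.min_refills == 4 and not policy.carryover

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown policy key"):
            StandardsPolicy.from_dict({"min_refils": 3})

    def test_fingerprint_tracks_content(self):
        assert StandardsPolicy().fingerprint() == StandardsPolicy().fingerprint()
        assert StandardsPolicy().fingerprint() != StandardsPolicy(min_refills=4).fingerprint()


class TestDefaultsKeepEventsInsideWindow:
    def test_no_artificial_initial_or_terminal_gap_on_fixtures(self):
        for name in ("box1_M1", "box1_F1", "box1_F2"):
            record = adh.builtin_fixture(name)
            policy = StandardsPolicy(review_date=record.window.end)
            prepared = adh.apply_standards(record, policy)
            assert prepared.window.start == prepared.refill_dates[0]
            for hist in prepared.histories:
                for ev in hist.events:
                    assert prepared.window.contains(ev.date)
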