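"""The sustained twofold-increase classifier and imaging pairing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmon.monitoring import (
    ImagingEvent,
    TimePoint,
    classify_patient,
    evaluate_against_imaging,
    percent_change_series,
    select_representative_mutation,
    sustained_increase_flag,
)


def tl(baseline, series, mutation="m1", below_lod=None):
    """Timeline with a day-0 baseline and monthly follow-ups."""
    points = [TimePoint("s0", 0.0, {mutation: baseline})]
    for k, c in enumerate(series, start=1):
        flags = {}
        if below_lod and k in below_lod:
            flags = {mutation: True}
        points.append(TimePoint(f"s{k}", 28.0 * k, {mutation: c}, flags))
    return points


class TestPercentChange:
    def test_increase(self):
        series = percent_change_series(tl(100, [250]), "m1")
        assert series == [(28.0, 150.0)]

    def test_no_change_and_below_lod(self):
        series = percent_change_series(tl(100, [100, 5], below_lod={2}), "m1")
        assert series[0][1] == 0.0
        assert series[1][1] == -100.0  # below LoD counts as zero

    def test_undetectable_baseline_excluded(self):
        with pytest.raises(ValueError):
            percent_change_series(tl(0.0, [10.0]), "m1")


class TestSustainedIncreaseFlag:
    def test_confirmed_pair_flags(self):
        flagged, first, confirm = sustained_increase_flag(
            [(28, 210.0), (56, 220.0)], 100.0
        )
        assert flagged and (first, confirm) == (28, 56)

    def test_unconfirmed_spike_does_not_flag(self):
        flagged, *_ = sustained_increase_flag(
            [(28, 210.0), (56, 150.0), (84, 400.0)], 100.0
        )
        assert not flagged

    def test_earliest_qualifying_pair_wins(self):
        flagged, first, confirm = sustained_increase_flag(
            [(28, 150.0), (56, 400.0), (84, 410.0), (112, 90.0)], 100.0
        )
        assert flagged and (first, confirm) == (56, 84)

    def test_boundary_exactly_twofold_counts(self):
        flagged, *_ = sustained_increase_flag([(28, 200.0), (56, 200.0)], 100.0)
        assert flagged

    def test_single_sample_cannot_flag(self):
        assert not sustained_increase_flag([(28, 500.0)], 100.0)[0]

    @given(st.lists(st.floats(min_value=0, max_value=1000), min_size=2, max_size=8),
           st.integers(min_value=0, max_value=7),
           st.floats(min_value=1, max_value=1000))
    @settings(derandomize=True, max_examples=60)
    def test_flag_monotone_in_concentration(self, concs, idx, bump):
        # raising any post-baseline concentration never un-flags
        idx = idx % len(concs)
        series = [(28.0 * (k + 1), c) for k, c in enumerate(concs)]
        bumped = list(concs)
        bumped[idx] += bump
        series_b = [(28.0 * (k + 1), c) for k, c in enumerate(bumped)]
        if sustained_increase_flag(series, 100.0)[0]:
            assert sustained_increase_flag(series_b, 100.0)[0]

    def test_threshold_extremes(self):
        series = [(28, 120.0), (56, 130.0)]
        assert not sustained_increase_flag(series, 100.0, fold_threshold=1e12)[0]
        assert sustained_increase_flag(series, 100.0, fold_threshold=1.0)[0]


class TestClassifyPatient:
    def two_mutation_timeline(self, a_series, b_series, a0=100.0, b0=50.0):
        points = [TimePoint("s0", 0.0, {"A": a0, "B": b0})]
        for k, (a, b) in enumerate(zip(a_series, b_series), start=1):
            points.append(TimePoint(f"s{k}", 28.0 * k, {"A": a, "B": b}))
        return points

    def test_or_rule_over_mutations(self):
        timeline = self.two_mutation_timeline([250, 260], [40, 30])
        call = classify_patient("p", timeline)
        assert call.flagged and call.triggering_mutation == "A"

    def test_not_flagged_when_no_mutation_flags(self):
        call = classify_patient("p", self.two_mutation_timeline([150, 120], [60, 55]))
        assert not call.flagged and call.evaluable

    def test_earliest_confirm_day_breaks_ties(self):
        # A confirms at day 56, B only at day 84
        points = [
            TimePoint("s0", 0.0, {"A": 100.0, "B": 100.0}),
            TimePoint("s1", 28.0, {"A": 210.0, "B": 90.0}),
            TimePoint("s2", 56.0, {"A": 220.0, "B": 300.0}),
            TimePoint("s3", 84.0, {"A": 230.0, "B": 310.0}),
        ]
        call = classify_patient("p", points)
        assert call.triggering_mutation == "A" and call.flag_day == 56.0
        assert call.first_exceed_day == 28.0

    def test_tie_broken_by_higher_baseline(self):
        points = [
            TimePoint("s0", 0.0, {"A": 50.0, "B": 100.0}),
            TimePoint("s1", 28.0, {"A": 150.0, "B": 300.0}),
            TimePoint("s2", 56.0, {"A": 160.0, "B": 310.0}),
        ]
        call = classify_patient("p", points)
        assert call.triggering_mutation == "B"

    def test_unevaluable_without_detectable_baseline(self):
        points = [
            TimePoint("s0", 0.0, {"A": 0.0}),
            TimePoint("s1", 28.0, {"A": 100.0}),
            TimePoint("s2", 56.0, {"A": 200.0}),
        ]
        call = classify_patient("p", points)
        assert not call.evaluable and not call.flagged


class TestRepresentativeMutation:
    def timeline(self):
        return [
            TimePoint("s0", 0.0, {"A": 100.0, "B": 50.0}),
            TimePoint("s1", 63.0, {"A": 500.0, "B": 300.0}),
        ]

    def test_highest_concentration_wins(self):
        assert select_representative_mutation(self.timeline(), 70.0) == "A"

    def test_single_mutation_identity(self):
        points = [TimePoint("s0", 0.0, {"A": 10.0}), TimePoint("s1", 63.0, {"A": 5.0})]
        assert select_representative_mutation(points, 70.0) == "A"

    def test_tie_breaks_to_higher_baseline(self):
        points = [
            TimePoint("s0", 0.0, {"A": 100.0, "B": 50.0}),
            TimePoint("s1", 63.0, {"A": 400.0, "B": 400.0}),
        ]
        assert select_representative_mutation(points, 70.0) == "A"

    def test_no_sample_in_window(self):
        assert select_representative_mutation(self.timeline(), 120.0, pairing_window=21) is None


class TestEvaluateAgainstImaging:
    def test_ppv_arithmetic(self):
        # 12 flagged patients, 10 with PD on the following imaging -> PPV 10/12
        calls, timelines, imaging = [], {}, {}
        for i in range(12):
            pid = f"p{i}"
            calls.append(classify_patient(pid, tl(100.0, [250.0, 260.0])))
            timelines[pid] = tl(100.0, [250.0, 260.0])
            outcome = "PD" if i < 10 else "SD"
            imaging[pid] = [ImagingEvent(day=70.0, outcome=outcome)]
        out = evaluate_against_imaging(calls, timelines, imaging)
        assert out["n_flagged"] == 12
        assert out["ppv"] == pytest.approx(10 / 12)
        assert out["median_lead_time_days"] == pytest.approx(42.0)  # 70 - 28

    def test_no_flags_ppv_undefined(self):
        calls = [classify_patient("p", tl(100.0, [110.0, 120.0]))]
        out = evaluate_against_imaging(calls, {"p": tl(100.0, [110.0, 120.0])},
                                       {"p": [ImagingEvent(day=70.0, outcome="SD")]})
        assert out["ppv"] is None and out["n_flagged"] == 0

    def test_flagged_without_imaging_reported_separately(self):
        timeline = tl(100.0, [250.0, 260.0])
        calls = [classify_patient("p", timeline)]
        out = evaluate_against_imaging(calls, {"p": timeline}, {})
        assert out["flagged_without_imaging"] == ["p"] and out["ppv"] is None

    def test_row_order_invariance(self):
        timelines = {
            "a": tl(100.0, [250.0, 260.0]),
            "b": tl(100.0, [50.0, 60.0]),
        }
        imaging = {
            "a": [ImagingEvent(day=70.0, outcome="PD")],
            "b": [ImagingEvent(day=70.0, outcome="SD")],
        }
        calls = [classify_patient(p, timelines[p]) for p in ("a", "b")]
        out1 = evaluate_against_imaging(calls, timelines, imaging)
        out2 = evaluate_against_imaging(list(reversed(calls)), timelines, imaging)
        assert out1["ppv"] == out2["ppv"]
        assert [c.patient_id for c in out1["calls"]] == [c.patient_id for c in out2["calls"]]

    def test_invalid_outcome_rejected(self):
        with pytest.raises(ValueError):
            ImagingEvent(day=70.0, outcome="XX")
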