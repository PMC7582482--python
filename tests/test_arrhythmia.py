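"""Deviant-RR flagging, event classification rules and tabulation."""

import numpy as np
import pytest

from conftest import published_counts_as_dicts
from mousebeat import arrhythmia as arr, simulate as sim
from mousebeat.ecg import PWaveMap, RRSeries


def series_from_rr(rr):
    r = np.concatenate([[0.0], np.cumsum(rr)])
    return RRSeries(r, beat_flags=np.zeros(r.size, dtype=int))


def pwaves_for(series, pr=20.0, orphans=(), pr_override=None):
    p = series.r_times - pr
    prs = np.full(series.n_beats, pr)
    if pr_override:
        for i, v in pr_override.items():
            prs[i] = v
            p[i] = series.r_times[i] - v
    return PWaveMap(p, prs, np.asarray(orphans, dtype=float))


class TestFlagDeviantRR:
    def test_constant_rhythm_no_candidates(self):
        assert arr.flag_deviant_rr(np.full(200, 100.0)).size == 0

    def test_short_interval_flagged(self):
        rr = np.full(50, 100.0)
        rr[25] = 60.0
        assert list(arr.flag_deviant_rr(rr)) == [25]

    def test_long_interval_flagged(self):
        rr = np.full(50, 100.0)
        rr[30] = 160.0
        assert list(arr.flag_deviant_rr(rr)) == [30]

    def test_series_shorter_than_window_empty(self):
        assert arr.flag_deviant_rr(np.full(5, 100.0)).size == 0

    def test_rr_level_candidates_catch_all_injected(self):
        base = RRSeries(np.arange(3000, dtype=float) * 100.0,
                        beat_flags=np.zeros(3000, dtype=int))
        specs = [sim.EventSpec(t, 5, pause_multiple=2.3) for t in sim.EVENT_TYPES]
        out, truth = sim.inject_events(base, specs, seed=2)
        cand = set(arr.flag_deviant_rr(out.rr))
        for ev in truth.event_log:
            near = {i for i in cand
                    if out.r_times[i] >= ev.t_start_ms - 150
                    and out.r_times[i] <= ev.t_end_ms + 50}
            assert near, f"no candidate near {ev.event_type}"


class TestClassification:
    def test_single_extrasystole_definition_case(self):
        rr = np.full(40, 100.0)
        rr[20], rr[21] = 60.0, 140.0
        s = series_from_rr(rr)
        events = arr.classify_events(s, arr.flag_deviant_rr(rr), pwaves_for(s))
        assert [e.event_type for e in events] == ["extrasystole_single"]
        assert not events[0].review_flag

    @pytest.mark.parametrize("n_premature,expected", [
        (2, "extrasystole_doublet"), (3, "extrasystole_run"),
        (5, "extrasystole_run")])
    def test_consecutive_prematures(self, n_premature, expected):
        rr = np.full(60, 100.0).tolist()
        rr[25:25 + n_premature + 1] = [60.0] * n_premature + [
            (n_premature + 1) * 100.0 - n_premature * 60.0]
        rr = np.asarray(rr)
        s = series_from_rr(rr)
        events = arr.classify_events(s, arr.flag_deviant_rr(rr), pwaves_for(s))
        assert [e.event_type for e in events] == [expected]

    def test_pause_without_p_is_sinus_arrest(self):
        rr = np.full(40, 100.0)
        rr[20] = 230.0
        s = series_from_rr(rr)
        events = arr.classify_events(s, arr.flag_deviant_rr(rr), pwaves_for(s))
        assert [e.event_type for e in events] == ["sinus_arrest"]

    def test_doubled_pause_with_p_is_blocked(self):
        rr = np.full(40, 100.0)
        rr[20] = 200.0
        s = series_from_rr(rr)
        t_mid_p = s.r_times[20] + 80.0  # P of the dropped beat
        events = arr.classify_events(s, arr.flag_deviant_rr(rr),
                                     pwaves_for(s, orphans=[t_mid_p]))
        assert [e.event_type for e in events] == ["blocked_p"]

    def test_blocked_with_pr_ramp_is_av_block(self):
        rr = np.full(40, 100.0)
        rr[20] = 200.0
        s = series_from_rr(rr)
        t_mid_p = s.r_times[20] + 80.0
        pw = pwaves_for(s, orphans=[t_mid_p],
                        pr_override={18: 25.0, 19: 30.0, 20: 36.0})
        events = arr.classify_events(s, arr.flag_deviant_rr(rr), pw)
        assert [e.event_type for e in events] == ["av_block"]

    def test_missing_p_info_downgrades_to_review(self):
        rr = np.full(40, 100.0)
        rr[20] = 200.0
        s = series_from_rr(rr)
        events = arr.classify_events(s, arr.flag_deviant_rr(rr), None)
        assert len(events) == 1
        assert events[0].review_flag

    def test_idempotent(self):
        rr = np.full(60, 100.0)
        rr[20], rr[21] = 60.0, 140.0
        rr[40] = 230.0
        s = series_from_rr(rr)
        cand = arr.flag_deviant_rr(rr)
        pw = pwaves_for(s)
        a = arr.classify_events(s, cand, pw)
        b = arr.classify_events(s, cand, pw)
        assert [(e.event_type, e.beat_start, e.beat_end) for e in a] == \
               [(e.event_type, e.beat_start, e.beat_end) for e in b]

    def test_partition_each_candidate_in_one_event(self, detected):
        _, _, series, events = detected
        cand = arr.flag_deviant_rr(series.rr)
        spans = [(e.beat_start, e.beat_end) for e in events]
        for i in cand:
            covering = [s for s in spans if s[0] <= i <= s[1] + 1]
            assert len(covering) >= 1
        # non-overlap after merging
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert a2 > b1


class TestRecovery:
    def test_full_pipeline_recovers_injections(self, synthetic_recording, detected):
        _, _, truth = synthetic_recording
        _, _, _, events = detected
        matched = set()
        correct = 0
        for ev in truth.event_log:
            hits = [e for e in events
                    if e.t_start_ms < ev.t_end_ms and e.t_end_ms > ev.t_start_ms]
            if any(e.event_type == ev.event_type for e in hits):
                correct += 1
            matched.update(id(e) for e in hits)
        assert correct / len(truth.event_log) >= 0.85
        spurious = sum(1 for e in events if id(e) not in matched)
        assert spurious <= 0.05 * len(truth.event_log)


class TestTabulation:
    def test_published_counts_reproduce_totals_and_shares(self):
        counts = published_counts_as_dicts()
        geno = {k: k.split("_")[0] for k in counts}
        table = arr.tabulate_events(counts, geno)
        assert table.genotype_totals.loc["WT", "Total"] == 150
        assert table.genotype_totals.loc["MFS", "Total"] == 1572
        assert table.percentages.loc["WT", "sinus_arrest"] == 48.7
        assert table.percentages.loc["MFS", "extrasystole_single"] == 75.6

    def test_row_sums_equal_subject_totals(self):
        counts = published_counts_as_dicts()
        geno = {k: k.split("_")[0] for k in counts}
        table = arr.tabulate_events(counts, geno)
        types = list(sim.EVENT_TYPES)
        assert (table.counts[types].sum(axis=1) == table.counts["Total"]).all()
        assert table.counts["Total"].sum() == 150 + 1572

    def test_percentages_sum_to_100_within_rounding(self):
        counts = published_counts_as_dicts()
        geno = {k: k.split("_")[0] for k in counts}
        table = arr.tabulate_events(counts, geno)
        sums = table.percentages.sum(axis=1)
        assert ((sums - 100.0).abs() <= 0.3).all()

    def test_single_event_is_100_percent(self):
        table = arr.tabulate_events(
            {"s1": {"sinus_arrest": 1}}, {"s1": "WT"})
        assert table.percentages.loc["WT", "sinus_arrest"] == 100.0

    def test_event_lists_accepted(self):
        ev = arr.ArrhythmiaEvent("blocked_p", 3, 4, 300.0, 500.0)
        table = arr.tabulate_events({"s1": [ev, ev]}, {"s1": "MFS"})
        assert table.counts.loc["s1", "blocked_p"] == 2
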