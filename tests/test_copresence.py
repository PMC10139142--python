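import numpy as np
import pandas as pd
import pytest

from carenet.copresence import (
    CleaningReport,
    RosterError,
    clean_records,
    count_alone_episodes,
    detect_interactions,
    detect_interactions_hourly,
    read_records,
    records_to_intervals,
    write_records,
)
from conftest import (
    brute_force_alone,
    brute_force_events,
    intervals_from_spans,
    records_from_spans,
)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

class TestCleaning:
    def test_exact_duplicates_collapse_once(self):
        rec = records_from_spans([("a", "Z1", 0, 10)])
        doubled = pd.concat([rec, rec], ignore_index=True)
        report = CleaningReport()
        out = clean_records(doubled, report=report)
        assert len(out) == 10
        assert report.n_exact_duplicates == 10
        # idempotent
        assert clean_records(out).equals(out)

    def test_conflict_free_input_unchanged(self):
        rec = records_from_spans([("a", "Z1", 0, 50), ("b", "Z2", 10, 60)])
        out = clean_records(rec)
        assert len(out) == 100
        assert set(out.itertuples(index=False, name=None)) == set(
            rec.itertuples(index=False, name=None)
        )

    def test_majority_window_resolves_spurious_zone(self):
        # second 30 registers in A and B, surrounded by 60 s of A
        rec = records_from_spans([("a", "A", 0, 61)])
        ghost = pd.DataFrame(
            [("a", 30, "B")], columns=["device_id", "timestamp", "zone_id"]
        )
        out = clean_records(pd.concat([rec, ghost], ignore_index=True))
        assert len(out) == 61
        assert (out["zone_id"] == "A").all()

    def test_tie_breaks_to_previous_retained_zone(self):
        # equal window support for A and B at t=10; previous second was in B
        spans = [("a", "B", 0, 10), ("a", "A", 11, 21)]
        rec = records_from_spans(spans)
        conflict = pd.DataFrame(
            [("a", 10, "A"), ("a", 10, "B")],
            columns=["device_id", "timestamp", "zone_id"],
        )
        out = clean_records(pd.concat([rec, conflict], ignore_index=True), window_s=30)
        picked = out.loc[out["timestamp"] == 10, "zone_id"].item()
        assert picked == "B"

    def test_tie_without_history_breaks_lexicographically(self):
        conflict = pd.DataFrame(
            [("a", 0, "Q"), ("a", 0, "B")],
            columns=["device_id", "timestamp", "zone_id"],
        )
        out = clean_records(conflict)
        assert out["zone_id"].item() == "B"


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

class TestIntervals:
    def test_contiguous_seconds_merge(self):
        iv = records_to_intervals(records_from_spans([("a", "A", 100, 700)]))
        assert len(iv) == 1
        row = iv.iloc[0]
        assert (row.start, row.end) == (100, 700)

    @pytest.mark.parametrize(
        "gap,n_intervals,total",
        [(30, 1, 630), (60, 1, 660), (61, 2, 600), (120, 2, 600)],
    )
    def test_gap_bridging_rule(self, gap, n_intervals, total):
        rec = records_from_spans(
            [("a", "A", 0, 300), ("a", "A", 300 + gap, 600 + gap)]
        )
        iv = records_to_intervals(rec, max_gap_s=60)
        assert len(iv) == n_intervals
        assert int((iv["end"] - iv["start"]).sum()) == total

    def test_gap_not_bridged_across_zone_change(self):
        rec = records_from_spans([("a", "A", 0, 300), ("a", "B", 310, 600)])
        iv = records_to_intervals(rec)
        assert len(iv) == 2
        assert set(iv["zone_id"]) == {"A", "B"}

    def test_blackout_sized_gap_rejected_as_bridgeable(self):
        with pytest.raises(ValueError):
            records_to_intervals(records_from_spans([("a", "A", 0, 10)]), max_gap_s=3600)

    def test_empty_input(self):
        iv = records_to_intervals(pd.DataFrame(columns=["device_id", "timestamp", "zone_id"]))
        assert len(iv) == 0


# ---------------------------------------------------------------------------
# interaction detection
# ---------------------------------------------------------------------------

class TestDetection:
    def test_overlap_above_threshold_is_one_event(self):
        iv = intervals_from_spans(
            [("a", "B1", 0, 400), ("b", "B1", 10, 400)]
        )
        ev = detect_interactions(iv)
        assert len(ev) == 1
        assert ev.iloc[0].duration_s == 390

    def test_exact_threshold_is_excluded(self):
        iv = intervals_from_spans([("a", "B1", 0, 300), ("b", "B1", 0, 300)])
        assert len(detect_interactions(iv)) == 0
        # strictly greater passes
        iv2 = intervals_from_spans([("a", "B1", 0, 301), ("b", "B1", 0, 301)])
        assert len(detect_interactions(iv2)) == 1

    def test_three_copresent_residents_yield_three_dyads(self):
        iv = intervals_from_spans(
            [(r, "lounge", 0, 600) for r in ("a", "b", "c")]
        )
        ev = detect_interactions(iv)
        assert len(ev) == 3
        pairs = set(map(tuple, ev[["resident_a", "resident_b"]].values))
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}
        assert (ev["resident_a"] < ev["resident_b"]).all()

    def test_unknown_device_skip_or_fail(self):
        iv = intervals_from_spans(
            [("a", "B1", 0, 400), ("ghost", "B1", 0, 400)]
        )
        ev = detect_interactions(iv, roster=["a", "b"])
        assert len(ev) == 0
        with pytest.raises(RosterError):
            detect_interactions(iv, roster=["a", "b"], on_unknown="raise")

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        spans = [
            (r, z, s, s + d)
            for r in "abcd"
            for z, s, d in zip(
                rng.choice(["B1", "lounge"], 5),
                rng.integers(0, 5000, 5),
                rng.integers(100, 900, 5),
            )
        ]
        iv = intervals_from_spans(spans)
        shuffled = iv.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            detect_interactions(iv), detect_interactions(shuffled)
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_per_second_brute_force(self, seed):
        """Randomized small instances: sweep detection equals exhaustive
        per-second pairwise scanning."""
        rng = np.random.default_rng(seed)
        spans = []
        for r in ["a", "b", "c", "d", "e"][: rng.integers(2, 6)]:
            t = 0
            while t < 7200:
                dur = int(rng.integers(60, 1200))
                zone = str(rng.choice(["B1", "B2", "lounge"]))
                if rng.random() < 0.8:
                    spans.append((r, zone, t, min(t + dur, 7200)))
                t += dur
        iv = intervals_from_spans(spans)
        expected = brute_force_events(iv)
        got = detect_interactions(iv)
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)

    def test_hourly_variant_thresholds_within_hour(self):
        iv = intervals_from_spans([("a", "B1", 100, 500), ("b", "B1", 100, 500)])
        hourly = detect_interactions_hourly(iv)
        assert len(hourly) == 1 and hourly.iloc[0].copresence_s == 400
        # 700 s split as 250+450 across an hour boundary: only hour 1 passes
        iv2 = intervals_from_spans(
            [("a", "B1", 3350, 4050), ("b", "B1", 3350, 4050)]
        )
        hourly2 = detect_interactions_hourly(iv2)
        assert list(hourly2["hour"]) == [1]


# ---------------------------------------------------------------------------
# alone episodes
# ---------------------------------------------------------------------------

class TestAloneEpisodes:
    def test_sole_occupant_counted(self):
        iv = intervals_from_spans([("a", "lounge", 0, 600)])
        counts = count_alone_episodes(iv, ["a", "b"])
        assert counts["a"] == 1 and counts["b"] == 0

    def test_copresent_residents_are_never_alone(self):
        iv = intervals_from_spans(
            [("a", "B1", 0, 900), ("b", "B1", 0, 900)]
        )
        counts = count_alone_episodes(iv, ["a", "b"])
        assert counts.sum() == 0

    def test_alone_in_different_zones_both_count(self):
        iv = intervals_from_spans(
            [("a", "B1", 0, 600), ("b", "lounge", 0, 600)]
        )
        counts = count_alone_episodes(iv, ["a", "b"])
        assert counts["a"] == 1 and counts["b"] == 1

    def test_hour_window_clips_and_wraps_midnight(self):
        # 23:55 to 00:20: inside a (22, 6) window, one 1500 s episode
        iv = intervals_from_spans([("a", "lounge", 86100, 87600)])
        assert count_alone_episodes(iv, ["a"], hour_window=(22, 6))["a"] == 1
        # a (0, 6) window clips it to 1200 s, still one episode
        assert count_alone_episodes(iv, ["a"], hour_window=(0, 6))["a"] == 1
        # a (6, 22) window leaves nothing
        assert count_alone_episodes(iv, ["a"], hour_window=(6, 22))["a"] == 0

    def test_zone_class_filter(self, tiny_facility):
        iv = intervals_from_spans([("a", "B1", 0, 600), ("a", "lounge", 700, 1400)])
        only_common = count_alone_episodes(
            iv, ["a"], zone_classes=["common_area"], facility=tiny_facility
        )
        assert only_common["a"] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_second_solitude_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        spans = []
        for r in ["a", "b", "c"]:
            t = 0
            while t < 5400:
                dur = int(rng.integers(60, 1000))
                if rng.random() < 0.75:
                    spans.append((r, str(rng.choice(["B1", "lounge"])), t, min(t + dur, 5400)))
                t += dur
        iv = intervals_from_spans(spans)
        expected = brute_force_alone(iv, ["a", "b", "c"])
        got = count_alone_episodes(iv, ["a", "b", "c"])
        pd.testing.assert_series_equal(
            got, expected, check_names=False, check_dtype=False
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestRecordIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "device_id": rng.choice(["a", "b", "c"], 10_000),
                "timestamp": rng.integers(0, 86_400, 10_000),
                "zone_id": rng.choice(["B1", "B2", "lounge"], 10_000),
            }
        )
        p = tmp_path / "records.csv"
        write_records(rec, p)
        back, n_bad = read_records(p)
        assert n_bad == 0
        pd.testing.assert_frame_equal(
            back, rec.astype({"timestamp": "int64"}), check_dtype=False
        )

    def test_empty_stream_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_records(pd.DataFrame(columns=["device_id", "timestamp", "zone_id"]), p)
        assert p.read_text().strip() == "device_id,timestamp,zone_id"
        back, _ = read_records(p)
        assert len(back) == 0

    def test_malformed_rows_counted_and_skipped(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "device_id,timestamp,zone_id\n"
            "a,100,B1\n"
            "a,not_a_time,B1\n"
            ",200,B1\n"
            "b,300,\n"
            "b,301,lounge\n"
        )
        back, n_bad = read_records(p)
        assert n_bad == 3
        assert len(back) == 2
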