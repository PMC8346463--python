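"""Detection filter cascade: multipath, grouping, PRI, mimic, chronology."""

import numpy as np
import pandas as pd
import pytest

from damtrack import filters, simulate
from damtrack.filters import DetectionEvent, Message


def decode_frame(rows):
    """rows: (receiver, tag_id, time) -> decode DataFrame."""
    return pd.DataFrame(
        [(r, t, tt, "cabled", "direct", -1) for r, t, tt in rows],
        columns=simulate.DECODE_COLUMNS,
    )


class TestMultipathFilter:
    def test_hand_traced_greedy_removal(self):
        df = decode_frame([("A", "X", 0.0), ("A", "X", 0.10), ("A", "X", 0.25), ("A", "X", 5.0)])
        out = filters.multipath_filter(df, window=0.3)
        assert list(out["time"]) == [0.0, 5.0]

    def test_boundary_is_strict(self):
        df = decode_frame([("A", "X", 0.0), ("A", "X", 0.3)])
        out = filters.multipath_filter(df, window=0.3)
        assert list(out["time"]) == [0.0, 0.3]

    def test_per_tag_rule(self):
        df = decode_frame([("A", "X", 0.0), ("A", "Y", 0.05)])
        assert len(filters.multipath_filter(df, 0.3)) == 2

    def test_per_receiver_rule(self):
        df = decode_frame([("A", "X", 0.0), ("B", "X", 0.05)])
        assert len(filters.multipath_filter(df, 0.3)) == 2

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(11)
        df = decode_frame([("A", "X", t) for t in np.sort(rng.uniform(0, 30, 100))])
        once = filters.multipath_filter(df, 0.3)
        twice = filters.multipath_filter(once, 0.3)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(df)


class TestGroupMessages:
    def test_three_phone_cluster(self):
        df = decode_frame([("A", "X", 0.000), ("B", "X", 0.012), ("C", "X", 0.030)])
        msgs = filters.group_messages(df, window=0.1)
        assert len(msgs) == 1 and msgs[0].n_receivers == 3

    def test_next_transmission_is_new_message(self):
        df = decode_frame([("A", "X", 0.0), ("B", "X", 0.012), ("A", "X", 4.2), ("B", "X", 4.21)])
        msgs = filters.group_messages(df, window=0.1)
        assert [m.time for m in msgs] == [0.0, 4.2]

    def test_singleton_message(self):
        msgs = filters.group_messages(decode_frame([("A", "X", 1.0)]), window=0.1)
        assert len(msgs) == 1 and msgs[0].n_receivers == 1

    def test_duplicate_receiver_keeps_earliest(self):
        df = decode_frame([("A", "X", 0.0), ("A", "X", 0.05), ("B", "X", 0.02)])
        msgs = filters.group_messages(df, window=0.1)
        assert msgs[0].decodes == [("A", 0.0), ("B", 0.02)]


class TestSingleDetectionFilter:
    def test_single_receiver_removed_multi_kept(self):
        msgs = [Message("X", [("A", 0.0)]), Message("X", [("A", 4.2), ("B", 4.21)])]
        out = filters.single_detection_filter(msgs)
        assert len(out) == 1 and out[0].n_receivers == 2

    def test_empty_input(self):
        assert filters.single_detection_filter([]) == []

    def test_rejected_for_autonomous_data(self):
        with pytest.raises(ValueError):
            filters.single_detection_filter([], source="autonomous")


def lattice_messages(times, tag="X"):
    return [Message(tag, [("A", t), ("B", t + 0.01)]) for t in times]


class TestPriEventFilter:
    def test_perfect_lattice_forms_one_event(self):
        msgs = lattice_messages([0.0, 4.2, 8.4, 12.6])
        accepted, events = filters.pri_event_filter(msgs, 4.2, 0.2, 4)
        assert len(events) == 1 and events[0].n_messages == 4
        assert len(accepted) == 4

    def test_off_lattice_message_removed(self):
        msgs = lattice_messages([0.0, 4.2, 6.1, 8.4, 12.6])
        accepted, events = filters.pri_event_filter(msgs, 4.2, 0.2, 4)
        assert len(events) == 1 and events[0].n_messages == 4
        assert 6.1 not in {m.time for m in accepted}

    def test_too_few_messages_no_event(self):
        msgs = lattice_messages([0.0, 4.2])
        accepted, events = filters.pri_event_filter(msgs, 4.2, 0.2, 4)
        assert events == [] and accepted == []

    def test_missed_pings_still_on_lattice(self):
        # k up to k_max bridges detection gaps
        msgs = lattice_messages([0.0, 8.4, 12.6, 29.4])
        accepted, events = filters.pri_event_filter(msgs, 4.2, 0.2, 4)
        assert len(events) == 1 and events[0].n_messages == 4

    def test_gap_close_splits_events(self):
        msgs = lattice_messages(
            [0.0, 4.2, 8.4, 12.6] + [t + 1000.0 for t in [0.0, 4.2, 8.4, 12.6]])
        accepted, events = filters.pri_event_filter(msgs, 4.2, 0.2, 4, gap_close=126.0)
        assert len(events) == 2
        assert all(e.n_messages == 4 for e in events)

    def test_tolerance_must_preserve_lattice(self):
        with pytest.raises(ValueError):
            filters.pri_event_filter([], 4.2, tolerance=2.5)


class TestSingleNodePriFilter:
    def test_lattice_decodes_form_event(self):
        df = decode_frame([("N1", "X", t) for t in np.arange(5) * 4.2])
        events = filters.single_node_pri_filter(df, 4.2)
        assert len(events) == 1 and events[0].n_messages == 5

    def test_empty_input(self):
        assert filters.single_node_pri_filter(decode_frame([]), 4.2) == []

    def test_random_false_positives_nearly_all_removed(self):
        # pure noise has no PRI structure: aggregate survival < 1%
        total = survived = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(0, 3600, 40))
            df = decode_frame([("N1", "X", t) for t in times])
            events = filters.single_node_pri_filter(df, 4.2)
            total += len(times)
            survived += sum(e.n_messages for e in events)
        assert survived / total < 0.01


def make_event(tag, times, array="SYN"):
    return DetectionEvent(tag, array, [Message(tag, [("A", t)]) for t in times])


class TestMimicEventFilter:
    def mimic_pair(self):
        ta = np.arange(10) * 4.2
        ev_a = make_event("AAAA", ta)
        ev_b = make_event("BBBB", ta[:8] + 0.005)
        table = {"AAAA": {"BBBB"}, "BBBB": {"AAAA"}}
        return ev_a, ev_b, table

    def test_concurrent_colocated_mimic_removed(self):
        ev_a, ev_b, table = self.mimic_pair()
        kept, removed = filters.mimic_event_filter([ev_a, ev_b], table)
        assert kept == [ev_a]
        assert removed[0][0] is ev_b

    def test_distant_tracks_protect_event(self):
        ev_a, ev_b, table = self.mimic_pair()
        tracks = {
            "AAAA": pd.DataFrame({"time": [0.0, 40.0], "x": [10, 10], "y": [0, 0], "z": [-5, -5]}),
            "BBBB": pd.DataFrame({"time": [0.0, 40.0], "x": [10, 10], "y": [200, 200], "z": [-5, -5]}),
        }
        kept, removed = filters.mimic_event_filter([ev_a, ev_b], table, tracks=tracks)
        assert len(kept) == 2 and removed == []

    def test_unrelated_tags_untouched(self):
        ev_a = make_event("AAAA", np.arange(10) * 4.2)
        ev_c = make_event("CCCC", np.arange(10) * 4.2 + 0.005)
        kept, removed = filters.mimic_event_filter([ev_a, ev_c], {"AAAA": {"BBBB"}})
        assert len(kept) == 2 and removed == []

    def test_tie_keeps_released_tag(self):
        ta = np.arange(10) * 4.2
        ev_a = make_event("AAAA", ta)
        ev_b = make_event("BBBB", ta + 0.005)
        table = {"AAAA": {"BBBB"}, "BBBB": {"AAAA"}}
        kept, _ = filters.mimic_event_filter(
            [ev_a, ev_b], table, tagged_ids={"BBBB"})
        assert [e.tag_id for e in kept] == ["BBBB"]

    def test_non_overlapping_events_untouched(self):
        ev_a = make_event("AAAA", np.arange(10) * 4.2)
        ev_b = make_event("BBBB", np.arange(10) * 4.2 + 1000.0)
        table = {"AAAA": {"BBBB"}, "BBBB": {"AAAA"}}
        kept, removed = filters.mimic_event_filter([ev_a, ev_b], table)
        assert len(kept) == 2 and removed == []


class TestChronologyFilter:
    RKM = {"LGS Forebay": 636.0, "LMN Dam": 589.0, "LGS Dam": 635.0, "Ice Harbor": 538.0}

    def test_upstream_reversal_flagged(self):
        evs = [make_event("X", [0.0, 10.0], "LGS Forebay"),
               make_event("X", [100.0, 110.0], "LMN Dam"),
               make_event("X", [200.0, 210.0], "LGS Dam")]
        kept, flags = filters.chronology_filter(evs, self.RKM)
        assert len(kept) == 2
        assert flags[0][0].array == "LGS Dam"
        assert "upstream" in flags[0][1]

    def test_monotone_downstream_unflagged(self):
        evs = [make_event("X", [0.0], "LGS Forebay"),
               make_event("X", [100.0], "LMN Dam"),
               make_event("X", [200.0], "Ice Harbor")]
        kept, flags = filters.chronology_filter(evs, self.RKM)
        assert len(kept) == 3 and flags == []

    def test_event_before_release_excluded(self):
        evs = [make_event("X", [0.0], "LGS Forebay")]
        kept, flags = filters.chronology_filter(evs, self.RKM, release_times={"X": 50.0})
        assert kept == [] and "release" in flags[0][1]

    def test_long_stationary_event_flagged_as_dropped_tag(self):
        evs = [make_event("X", [0.0, 48 * 3600.0], "LMN Dam")]
        kept, flags = filters.chronology_filter(evs, self.RKM)
        assert kept == [] and "dropped" in flags[0][1]


class TestCascadeProperties:
    def test_filters_never_invent_decodes(self, rng):
        times = np.sort(rng.uniform(0, 100, 200))
        df = decode_frame([(f"P{int(i % 4)}", "X", t) for i, t in enumerate(times)])
        out = filters.multipath_filter(df, 0.3)
        merged = out.merge(df, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_events_to_records_orders_event_ids(self):
        evs = [make_event("X", [100.0, 104.2]), make_event("X", [0.0, 4.2])]
        recs = filters.events_to_records(evs, cabled=True)
        assert [r.event_id for r in recs] == [1, 2]
        assert recs[0].first_datetime < recs[1].first_datetime
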