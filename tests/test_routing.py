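"""Dam geometry, route assignment methods, reconciliation, PIT/operations QA."""

import numpy as np
import pandas as pd
import pytest

from damtrack import dams, routing
from damtrack.filters import Message


def traj_ending_at(x, y, z=-5.0, n=20):
    t = np.arange(n) * 4.2
    return pd.DataFrame({
        "time": t,
        "x": np.linspace(x + 30.0, x, n),
        "y": np.full(n, float(y)),
        "z": np.full(n, z),
    })


class TestDamGeometry:
    def test_standard_geometry_layout(self, geometry):
        assert [b.hole for b in geometry.bays][:6] == [f"T{i:02d}" for i in range(1, 7)]
        assert [b.hole for b in geometry.bays][6:] == [f"B{i:02d}" for i in range(1, 8)]
        assert geometry.n_piers == 14
        spans = [(b.y_min, b.y_max) for b in geometry.bays]
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_north_south_numbering(self):
        geom = dams.standard_geometry(name="LMN-like", turbine_numbering="north-south",
                                      weir_bays=("B08",), n_spillbays=8)
        # physically first (southmost) turbine bay carries the highest label
        assert geom.bays[0].hole == "T06"
        assert geom.bays[5].hole == "T01"

    def test_pier_average_conventions(self, geometry):
        assert geometry.bay_for_pier_average(3.5).index == 3
        assert geometry.bay_for_pier_average(3.0).index == 2

    def test_nearest_bay_clamps(self, geometry):
        y_lo, y_hi = geometry.y_span
        assert geometry.nearest_bay(y_lo - 10.0).index == 1
        assert geometry.nearest_bay(y_hi + 10.0).index == len(geometry.bays)

    def test_weir_subroute(self, geometry):
        assert geometry.main_route_for("B01") == ("spillway", "spillway_weir")
        assert geometry.main_route_for("B03") == ("spillway", "regular_spillway")
        assert geometry.main_route_for("T02") == ("powerhouse", "turbine")


class TestRouteFromTrack:
    def test_last_point_in_spillbay(self, geometry):
        bay = geometry.bay_by_hole("B03")
        a = routing.route_from_track(traj_ending_at(10.0, bay.center), "ABCD", geometry)
        assert (a.main_route, a.subroute, a.hole) == ("spillway", "regular_spillway", "B03")

    def test_too_far_upstream_gives_none(self, geometry):
        traj = traj_ending_at(40.0, geometry.bay_by_hole("B03").center)
        assert routing.route_from_track(traj, "ABCD", geometry) is None

    def test_outside_pier_maps_to_nearest_bay(self, geometry):
        y_lo, _ = geometry.y_span
        a = routing.route_from_track(traj_ending_at(5.0, y_lo - 10.0), "ABCD", geometry)
        assert a.hole == geometry.bays[0].hole

    def test_beyond_side_margin_gives_none(self, geometry):
        y_lo, _ = geometry.y_span
        traj = traj_ending_at(5.0, y_lo - 26.0)
        assert routing.route_from_track(traj, "ABCD", geometry) is None

    def test_empty_trajectory_gives_none(self, geometry):
        empty = pd.DataFrame(columns=["time", "x", "y", "z"])
        assert routing.route_from_track(empty, "ABCD", geometry) is None


class TestRouteFromLastDetection:
    def pier_map(self, geometry):
        _, pier_of = __import__("damtrack").simulate.pier_array(geometry)
        return pier_of

    def test_half_integer_average(self, geometry):
        pier_of = self.pier_map(geometry)
        m = Message("ABCD", [("P03D", 0.000), ("P04D", 0.004), ("P05S", 0.010)])
        a = routing.route_from_last_detection([m], pier_of, geometry)
        assert a.hole == geometry.bays[2].hole  # piers 3,4 -> avg 3.5 -> bay 3

    def test_integer_average_tie_breaks_low(self, geometry):
        pier_of = self.pier_map(geometry)
        m = Message("ABCD", [("P02D", 0.000), ("P04D", 0.004)])
        a = routing.route_from_last_detection([m], pier_of, geometry)
        assert a.hole == geometry.bays[1].hole  # piers 2,4 -> avg 3.0 -> bay 2

    def test_single_pier_message_gives_none(self, geometry):
        pier_of = self.pier_map(geometry)
        m = Message("ABCD", [("P03D", 0.0), ("P03S", 0.002)])
        assert routing.route_from_last_detection([m], pier_of, geometry) is None

    def test_uses_last_multi_pier_message(self, geometry):
        pier_of = self.pier_map(geometry)
        early = Message("ABCD", [("P08D", 0.0), ("P09D", 0.004)])
        late = Message("ABCD", [("P03D", 100.0), ("P04D", 100.004)])
        a = routing.route_from_last_detection([early, late], pier_of, geometry)
        assert a.hole == geometry.bays[2].hole


class TestReconcile:
    def make(self, geometry, hole, method="track3d"):
        bay = geometry.bay_by_hole(hole)
        return routing._assignment_for_bay("ABCD", bay, geometry, method, 0.0)

    def test_identical_assignments_unflagged(self, geometry):
        r = routing.reconcile(self.make(geometry, "B03"),
                              self.make(geometry, "B03", "last_detection"), geometry)
        assert not r.review and r.hole == "B03"

    def test_two_bays_apart_not_flagged(self, geometry):
        r = routing.reconcile(self.make(geometry, "B02"),
                              self.make(geometry, "B04", "last_detection"), geometry)
        assert not r.review

    def test_three_bays_apart_flagged(self, geometry):
        r = routing.reconcile(self.make(geometry, "B02"),
                              self.make(geometry, "B05", "last_detection"), geometry)
        assert r.review and "two bays" in r.review_reason
        assert r.hole == "B02"  # default stays with the 3-D track method

    def test_main_route_difference_flagged(self, geometry):
        r = routing.reconcile(self.make(geometry, "T06"),
                              self.make(geometry, "B01", "last_detection"), geometry)
        assert r.review and "main routes differ" in r.review_reason

    def test_subroute_difference_flagged(self, geometry):
        r = routing.reconcile(self.make(geometry, "B01"),  # weir bay
                              self.make(geometry, "B02", "last_detection"), geometry)
        assert r.review and "subroutes differ" in r.review_reason

    def test_single_method_falls_through(self, geometry):
        r = routing.reconcile(None, self.make(geometry, "B03", "last_detection"), geometry)
        assert r.hole == "B03" and not r.review

    def test_both_missing_gives_none(self, geometry):
        assert routing.reconcile(None, None, geometry) is None


class TestPitJbs:
    def assignments(self, geometry):
        t = geometry.bay_by_hole("T02")
        b = geometry.bay_by_hole("B03")
        return [
            routing._assignment_for_bay("AAAA", t, geometry, "reconciled", 0.0),
            routing._assignment_for_bay("BBBB", t, geometry, "reconciled", 0.0),
            routing._assignment_for_bay("CCCC", b, geometry, "reconciled", 0.0),
        ]

    def test_jbs_and_turbine_assignment(self, geometry):
        pit = pd.DataFrame({"tag_id": ["AAAA", "CCCC"], "site": ["SYN-JBS", "SYN-JBS"]})
        out = routing.apply_pit_jbs(self.assignments(geometry), pit, {"SYN-JBS": "SYN"})
        by_tag = {a.tag_id: a for a in out}
        assert by_tag["AAAA"].subroute == "JBS"
        assert by_tag["BBBB"].subroute == "turbine"
        assert by_tag["CCCC"].subroute == "regular_spillway"  # spillway untouched

    def test_unmapped_site_warns_and_leaves_unchanged(self, geometry):
        pit = pd.DataFrame({"tag_id": ["AAAA"], "site": ["UNKNOWN"]})
        with pytest.warns(UserWarning, match="not mapped"):
            out = routing.apply_pit_jbs(self.assignments(geometry), pit, {"SYN-JBS": "SYN"})
        assert {a.tag_id: a.subroute for a in out}["AAAA"] == "turbine"


class TestOperationsQa:
    def ops(self, open_holes, t0=0.0, t1=1000.0):
        return pd.DataFrame(
            [(h, t0, t1) for h in open_holes], columns=["hole", "open_from", "open_to"])

    def test_closed_bay_flagged_with_nearest_open(self, geometry):
        bay = geometry.bay_by_hole("B02")
        a = routing._assignment_for_bay("ABCD", bay, geometry, "reconciled", 500.0)
        out = routing.operations_qa([a], self.ops(["B01", "B03"]), geometry)
        assert out[0].review and "closed" in out[0].review_reason
        assert "B01" in out[0].review_reason or "B03" in out[0].review_reason

    def test_all_open_no_flags(self, geometry):
        bay = geometry.bay_by_hole("B02")
        a = routing._assignment_for_bay("ABCD", bay, geometry, "reconciled", 500.0)
        out = routing.operations_qa([a], self.ops([b.hole for b in geometry.bays]), geometry)
        assert not out[0].review

    def test_missing_coverage_warns(self, geometry):
        bay = geometry.bay_by_hole("B02")
        a = routing._assignment_for_bay("ABCD", bay, geometry, "reconciled", 5000.0)
        out = routing.operations_qa([a], self.ops(["B02"]), geometry)
        assert out[0].review and "cover" in out[0].review_reason


class TestBayRecoverySimulation:
    def test_track_method_recovers_known_exit_bay(self, geometry):
        # simulated passages with dense near-dam detections and field-scale
        # position noise; the 3-D-track method must recover the true bay
        rng = np.random.default_rng(77)
        hits = 0
        runs = 100
        for _ in range(runs):
            bay = geometry.bays[rng.integers(len(geometry.bays))]
            traj = traj_ending_at(
                float(rng.uniform(1.0, 8.0)), bay.center + rng.uniform(-4.0, 4.0))
            traj[["x", "y"]] += rng.normal(0.0, 0.6, size=(len(traj), 2))
            traj = traj.sort_values("time").reset_index(drop=True)
            a = routing.route_from_track(traj, "ABCD", geometry)
            hits += a is not None and a.hole == bay.hole
        assert hits / runs >= 0.95
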