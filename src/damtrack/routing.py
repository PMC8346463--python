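"""Passage-route assignment: which opening a tagged fish used to pass the dam.

Two independent methods are computed and reconciled:

* the 3-D-track method takes the last cleaned, QA-trimmed track point; if it
  lies within a box spanning the dam plus 25 m on each side and extending
  30 m upstream of the face, the bay whose Y-interval contains the point is
  assigned (points beyond the outer piers go to the nearest bay);
* the last-detection method takes the last transmission heard on hydrophones
  of at least two distinct piers, averages the pier numbers of the first two
  such hydrophones in arrival order, and assigns the bay flanked by that
  average pier position.

The 3-D-track assignment is the default; when the methods disagree on main
route, on subroute, or by more than two bays, the case is flagged for manual
review rather than auto-resolved.  PIT detections inside the juvenile bypass
system (JBS) then refine powerhouse passages into turbine vs JBS subroutes,
and a final QA pass flags assignments to bays that dam operations show closed
at passage time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dams import Bay, DamGeometry
from .filters import Message

__all__ = [
    "RouteAssignment",
    "route_from_track",
    "route_from_last_detection",
    "reconcile",
    "apply_pit_jbs",
    "operations_qa",
    "assignments_to_records",
]


@dataclass
class RouteAssignment:
    tag_id: str
    method: str  # track3d | last_detection | reconciled
    main_route: str  # powerhouse | spillway | dam
    subroute: str
    hole: str
    array_name: str
    passage_time: float | None = None
    review: bool = False
    review_reason: str = ""

    def bay_index(self, geometry: DamGeometry) -> int | None:
        if self.hole in ("N/A", ""):
            return None
        return geometry.bay_by_hole(self.hole).index


def _assignment_for_bay(
    tag_id: str, bay: Bay, geometry: DamGeometry, method: str, passage_time: float | None
) -> RouteAssignment:
    main, sub = geometry.main_route_for(bay.hole)
    return RouteAssignment(
        tag_id=tag_id,
        method=method,
        main_route=main,
        subroute=sub,
        hole=bay.hole,
        array_name=geometry.name,
        passage_time=passage_time,
    )


def route_from_track(
    trajectory: pd.DataFrame,
    tag_id: str,
    geometry: DamGeometry,
    margin_side: float = 25.0,
    depth_upstream: float = 30.0,
) -> RouteAssignment | None:
    """Assign a route from the last cleaned 3-D track point, or None when the
    last point falls outside the assignment box."""
    if trajectory.empty:
        return None
    last = trajectory.iloc[-1]
    x, y = float(last["x"]), float(last["y"])
    y_lo, y_hi = geometry.y_span
    if not (0.0 <= x <= depth_upstream):
        return None
    if not (y_lo - margin_side <= y <= y_hi + margin_side):
        return None
    bay = geometry.bay_for_y(y) or geometry.nearest_bay(y)
    return _assignment_for_bay(tag_id, bay, geometry, "track3d", float(last["time"]))


def route_from_last_detection(
    messages: Sequence[Message],
    pier_of: Mapping[str, int],
    geometry: DamGeometry,
) -> RouteAssignment | None:
    """Assign a route from the last multi-pier transmission.

    The message's decodes are sorted by time and the pier numbers of the first
    two hydrophones on *different* piers are averaged; the bay flanked by that
    average pier position is assigned (integer averages tie-break to the
    lower-indexed bay).  Returns None when no message spans two piers.
    """
    best: Message | None = None
    for m in messages:
        piers = {pier_of[r] for r, _ in m.decodes if r in pier_of}
        if len(piers) >= 2 and (best is None or m.time > best.time):
            best = m
    if best is None:
        return None
    first_pier: int | None = None
    pier_pair: tuple[int, int] | None = None
    for r, _t in sorted(best.decodes, key=lambda rt: rt[1]):
        p = pier_of.get(r)
        if p is None:
            continue
        if first_pier is None:
            first_pier = p
        elif p != first_pier:
            pier_pair = (first_pier, p)
            break
    if pier_pair is None:
        return None
    avg = 0.5 * (pier_pair[0] + pier_pair[1])
    bay = geometry.bay_for_pier_average(avg)
    return _assignment_for_bay(best.tag_id, bay, geometry, "last_detection", best.time)


def reconcile(
    r_track: RouteAssignment | None,
    r_last: RouteAssignment | None,
    geometry: DamGeometry,
) -> RouteAssignment | None:
    """Merge the two methods: the 3-D-track assignment is the default.

    The result is flagged for manual review when the methods disagree on main
    route, on subroute, or assign holes more than two bays apart; flagged
    cases still carry the default assignment with the reason recorded.
    Returns None when neither method produced an assignment.
    """
    if r_track is None and r_last is None:
        return None
    base = r_track if r_track is not None else r_last
    assert base is not None
    out = RouteAssignment(
        tag_id=base.tag_id,
        method="reconciled",
        main_route=base.main_route,
        subroute=base.subroute,
        hole=base.hole,
        array_name=base.array_name,
        passage_time=base.passage_time,
    )
    if r_track is None or r_last is None:
        out.review_reason = "single-method assignment"
        return out
    reasons = []
    if r_track.main_route != r_last.main_route:
        reasons.append("main routes differ")
    if r_track.subroute != r_last.subroute:
        reasons.append("subroutes differ")
    bi_t = r_track.bay_index(geometry)
    bi_l = r_last.bay_index(geometry)
    if bi_t is not None and bi_l is not None and abs(bi_t - bi_l) > 2:
        reasons.append("holes more than two bays apart")
    if reasons:
        out.review = True
        out.review_reason = "; ".join(reasons)
    return out


def apply_pit_jbs(
    assignments: Sequence[RouteAssignment],
    pit_detections: pd.DataFrame,
    site_dam_map: Mapping[str, str],
    tag_to_pit: Mapping[str, str] | None = None,
) -> list[RouteAssignment]:
    """Refine powerhouse subroutes using PIT detections inside the JBS.

    A powerhouse fish whose PIT tag was read at the dam's juvenile bypass gets
    the JBS subroute; otherwise it keeps/receives turbine.  Spillway and
    'dam' assignments are untouched.  ``site_dam_map`` maps PIT site codes to
    dam array names; detections at unmapped sites are ignored with a warning.
    """
    import warnings

    jbs_tags_by_dam: dict[str, set[str]] = {}
    pit_to_tag = None
    if tag_to_pit is not None:
        pit_to_tag = {v: k for k, v in tag_to_pit.items()}
    for _, row in pit_detections.iterrows():
        dam = site_dam_map.get(str(row["site"]))
        if dam is None:
            warnings.warn(f"PIT site {row['site']!r} not mapped to a dam", stacklevel=2)
            continue
        tag = str(row["tag_id"])
        if pit_to_tag is not None and "pit_id" in pit_detections.columns:
            tag = pit_to_tag.get(str(row["pit_id"]), tag)
        jbs_tags_by_dam.setdefault(dam, set()).add(tag)
    out = []
    for a in assignments:
        b = RouteAssignment(**vars(a))
        if b.main_route == "powerhouse":
            in_jbs = b.tag_id in jbs_tags_by_dam.get(b.array_name, set())
            b.subroute = "JBS" if in_jbs else "turbine"
        out.append(b)
    return out


def operations_qa(
    assignments: Sequence[RouteAssignment],
    operations: pd.DataFrame,
    geometry: DamGeometry,
) -> list[RouteAssignment]:
    """Flag assignments to passage routes that were closed at passage time.

    ``operations`` has columns hole, open_from, open_to (epoch s), one row per
    open interval.  A closed-bay assignment is flagged with the nearest open
    bay suggested — never silently reassigned.  Missing coverage for the
    passage time yields a coverage warning flag.
    """
    out = []
    for a in assignments:
        b = RouteAssignment(**vars(a))
        if b.hole in ("N/A", "") or b.passage_time is None:
            out.append(b)
            continue
        t = b.passage_time
        if operations.empty or not (
            operations["open_from"].min() <= t <= operations["open_to"].max()
        ):
            b.review = True
            b.review_reason = (b.review_reason + "; " if b.review_reason else "") + (
                "operations table does not cover the passage time"
            )
            out.append(b)
            continue
        rows = operations[operations["hole"] == b.hole]
        covered = rows[(rows["open_from"] <= t) & (t <= rows["open_to"])]
        if covered.empty:
            open_now = operations[
                (operations["open_from"] <= t) & (t <= operations["open_to"])
            ]["hole"].unique()
            bay = geometry.bay_by_hole(b.hole)
            suggestion = ""
            if len(open_now):
                nearest = min(
                    open_now,
                    key=lambda h: abs(geometry.bay_by_hole(h).index - bay.index),
                )
                suggestion = f"; nearest open bay {nearest}"
            b.review = True
            b.review_reason = (b.review_reason + "; " if b.review_reason else "") + (
                f"assigned hole closed at passage time{suggestion}"
            )
        out.append(b)
    return out


def assignments_to_records(assignments: Iterable[RouteAssignment]):
    from .tables import RouteRecord

    return [
        RouteRecord(
            tag_id=a.tag_id,
            route=a.main_route,
            subroute=a.subroute,
            hole=a.hole,
            array_name=a.array_name,
        )
        for a in assignments
    ]
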