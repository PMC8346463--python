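"""False-positive filtering cascade and detection-event building.

Raw per-hydrophone decodes pass through a fixed sequence of filters before any
localization or route analysis:

cabled arrays
    multipath filter (per hydrophone) -> message grouping across hydrophones
    -> single-detection filter -> message PRI filter (which also builds
    detection events) -> mimic filter
autonomous receivers
    multipath filter -> single-node PRI filter (per receiver) -> mimic filter

Every filter only removes decodes — none invents data — and each is
idempotent.  The ping-rate-interval (PRI) logic exploits the tags' fixed
transmission lattice: a message is genuine evidence only when its spacing to
other accepted messages is a near-integer multiple of the nominal PRI.
Detection events summarize nearly continuous presence of one tag at one array;
a chronology check across arrays then flags histories that are impossible for
a live downstream migrant (upstream movement past a dam, detections before
release, or long stationary detections from a dropped tag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Message",
    "DetectionEvent",
    "multipath_filter",
    "group_messages",
    "single_detection_filter",
    "pri_event_filter",
    "single_node_pri_filter",
    "mimic_event_filter",
    "chronology_filter",
    "events_to_records",
]


@dataclass
class Message:
    """One suspected tag transmission grouped across receivers."""

    tag_id: str
    decodes: list[tuple[str, float]]  # (receiver, time), at most one per receiver

    @property
    def time(self) -> float:
        return min(t for _, t in self.decodes)

    @property
    def n_receivers(self) -> int:
        return len({r for r, _ in self.decodes})


@dataclass
class DetectionEvent:
    """Nearly continuous decodes of one tag at one array."""

    tag_id: str
    array: str
    messages: list[Message]
    receiver: str | None = None  # first receiver of the last message (cabled)

    @property
    def first(self) -> float:
        return min(m.time for m in self.messages)

    @property
    def last(self) -> float:
        return max(m.time for m in self.messages)

    @property
    def n_messages(self) -> int:
        return len(self.messages)

    def times(self) -> np.ndarray:
        return np.sort(np.array([m.time for m in self.messages]))


def multipath_filter(decodes: pd.DataFrame, window: float = 0.3) -> pd.DataFrame:
    """Drop same-tag decodes arriving strictly within ``window`` of the last
    kept decode on the same receiver.

    Greedy left-to-right per (receiver, tag): the first decode of a burst is
    taken as the direct path; later copies within the window are multipath
    reflections.  A decode exactly at ``window`` after the kept one survives.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if decodes.empty:
        return decodes.copy()
    df = decodes.sort_values("time", kind="stable")
    keep_idx = []
    for (_, _), grp in df.groupby(["receiver", "tag_id"], sort=False):
        last_kept = -np.inf
        for idx, t in zip(grp.index, grp["time"].to_numpy()):
            if t - last_kept < window:
                continue
            keep_idx.append(idx)
            last_kept = t
    return df[df.index.isin(keep_idx)].reset_index(drop=True)


def group_messages(decodes: pd.DataFrame, window: float) -> list[Message]:
    """Cluster decodes of each tag into messages by single-linkage in time.

    Decodes of one tag whose successive gaps are <= ``window`` belong to one
    message (one tag transmission heard on several hydrophones); a receiver
    appearing twice within a cluster keeps only its earliest decode.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    messages: list[Message] = []
    if decodes.empty:
        return messages
    df = decodes.sort_values("time", kind="stable")
    for tag, grp in df.groupby("tag_id", sort=False):
        times = grp["time"].to_numpy()
        receivers = grp["receiver"].to_numpy()
        start = 0
        for i in range(1, len(times) + 1):
            if i == len(times) or times[i] - times[i - 1] > window:
                seen: dict[str, float] = {}
                for r, t in zip(receivers[start:i], times[start:i]):
                    if r not in seen or t < seen[r]:
                        seen[r] = t
                messages.append(Message(tag_id=tag, decodes=sorted(seen.items(), key=lambda rt: rt[1])))
                start = i
    messages.sort(key=lambda m: m.time)
    return messages


def single_detection_filter(messages: Sequence[Message], source: str = "cabled") -> list[Message]:
    """Keep only messages heard by at least two distinct receivers.

    Valid for cabled arrays, whose hydrophone spacing guarantees multiple
    receptions of any in-range transmission; autonomous receivers are
    processed individually and must not use this filter.
    """
    if source != "cabled":
        raise ValueError("single-detection filter applies to cabled arrays only")
    return [m for m in messages if m.n_receivers >= 2]


def _on_lattice(dt: float, pri: float, tolerance: float, k_max: int) -> bool:
    if dt <= 0:
        return False
    k = round(dt / pri)
    return 1 <= k <= k_max and abs(dt - k * pri) <= tolerance


def _pri_scan(
    times: np.ndarray,
    pri: float,
    tolerance: float,
    min_messages: int,
    k_max: int,
    gap_close: float,
) -> tuple[list[list[int]], list[int]]:
    """Shared PRI-lattice event scan; returns (events as index lists, accepted)."""
    events: list[list[int]] = []
    current: list[int] = []
    pending: list[int] = []  # candidate seeds awaiting a lattice partner

    def close() -> None:
        nonlocal current
        if len(current) >= min_messages:
            events.append(current)
        current = []

    for i, t in enumerate(times):
        if current and t - times[current[-1]] > gap_close:
            close()
        if not current:
            pending = [j for j in pending if t - times[j] <= gap_close]
            seed = next(
                (j for j in pending if _on_lattice(t - times[j], pri, tolerance, k_max)),
                None,
            )
            if seed is not None:
                current = [seed, i]
                pending = []
            else:
                pending.append(i)
            continue
        if any(_on_lattice(t - times[j], pri, tolerance, k_max) for j in current):
            current.append(i)
    close()
    accepted = [i for ev in events for i in ev]
    return events, accepted


def pri_event_filter(
    messages: Sequence[Message],
    pri_nominal: float,
    tolerance: float = 0.2,
    min_messages: int = 4,
    k_max: int = 12,
    gap_close: float | None = None,
    array: str = "",
) -> tuple[list[Message], list[DetectionEvent]]:
    """Message PRI filter for one tag at a cabled array.

    A message is accepted when its spacing to an already-accepted message of
    the same event is within ``tolerance`` of k * PRI for some integer
    1 <= k <= ``k_max``; a silence longer than ``gap_close`` (default 30 PRI)
    ends the event, and events with fewer than ``min_messages`` accepted
    messages are discarded entirely.  Returns (accepted messages, events).
    """
    if pri_nominal <= 0:
        raise ValueError("PRI must be positive")
    if tolerance >= pri_nominal / 2:
        raise ValueError("tolerance must be below half the PRI")
    if gap_close is None:
        gap_close = 30 * pri_nominal
    msgs = sorted(messages, key=lambda m: m.time)
    times = np.array([m.time for m in msgs])
    idx_events, accepted = _pri_scan(times, pri_nominal, tolerance, min_messages, k_max, gap_close)
    events = []
    for ev in idx_events:
        members = [msgs[i] for i in ev]
        last_msg = max(members, key=lambda m: m.time)
        first_receiver = min(last_msg.decodes, key=lambda rt: rt[1])[0]
        events.append(
            DetectionEvent(
                tag_id=members[0].tag_id,
                array=array,
                messages=members,
                receiver=first_receiver,
            )
        )
    return [msgs[i] for i in sorted(accepted)], events


def single_node_pri_filter(
    decodes: pd.DataFrame,
    pri_nominal: float,
    tolerance: float = 0.2,
    min_messages: int = 4,
    k_max: int = 12,
    gap_close: float | None = None,
) -> list[DetectionEvent]:
    """PRI filter for one autonomous receiver: identical lattice logic applied
    to single-receiver decode times, one event stream per (node, tag)."""
    if gap_close is None:
        gap_close = 30 * pri_nominal
    if tolerance >= pri_nominal / 2:
        raise ValueError("tolerance must be below half the PRI")
    events: list[DetectionEvent] = []
    if decodes.empty:
        return events
    df = decodes.sort_values("time", kind="stable")
    for (node, tag), grp in df.groupby(["receiver", "tag_id"], sort=False):
        times = grp["time"].to_numpy()
        idx_events, _ = _pri_scan(times, pri_nominal, tolerance, min_messages, k_max, gap_close)
        for ev in idx_events:
            msgs = [Message(tag_id=tag, decodes=[(node, float(times[i]))]) for i in ev]
            events.append(DetectionEvent(tag_id=tag, array=node, messages=msgs, receiver=node))
    events.sort(key=lambda e: e.first)
    return events


def _median_track_separation(
    ev_a: DetectionEvent,
    ev_b: DetectionEvent,
    tracks: Mapping[str, pd.DataFrame],
) -> float | None:
    ta = tracks.get(ev_a.tag_id)
    tb = tracks.get(ev_b.tag_id)
    if ta is None or tb is None or ta.empty or tb.empty:
        return None
    t0 = max(ev_a.first, ev_b.first)
    t1 = min(ev_a.last, ev_b.last)
    if t1 < t0:
        return None
    ts = np.linspace(t0, t1, 20)
    pa = np.column_stack([np.interp(ts, ta["time"], ta[c]) for c in ("x", "y", "z")])
    pb = np.column_stack([np.interp(ts, tb["time"], tb[c]) for c in ("x", "y", "z")])
    return float(np.median(np.linalg.norm(pa - pb, axis=1)))


def mimic_event_filter(
    events: Sequence[DetectionEvent],
    mimic_table: Mapping[str, set[str]],
    concurrency_tolerance: float = 0.025,
    min_concurrent_fraction: float = 0.8,
    colocation_threshold: float = 50.0,
    tracks: Mapping[str, pd.DataFrame] | None = None,
    tagged_ids: set[str] | None = None,
) -> tuple[list[DetectionEvent], list[tuple[DetectionEvent, str]]]:
    """Remove events attributable to mimic tag-codes of a concurrent event.

    Two overlapping events of tag-codes in a mimic relation are compared: if
    the smaller event's message times each match the larger's within
    ``concurrency_tolerance`` for at least ``min_concurrent_fraction`` of its
    messages, and (when 3-D tracks are supplied) the tags appear co-located
    (median separation below ``colocation_threshold``), the event with fewer
    messages is removed.  Ties keep the tag present in the tagged-fish list.
    """
    removed: list[tuple[DetectionEvent, str]] = []
    dropped: set[int] = set()
    evs = list(events)
    for i, ev_a in enumerate(evs):
        for j in range(i + 1, len(evs)):
            ev_b = evs[j]
            if i in dropped or j in dropped:
                continue
            if ev_b.tag_id not in mimic_table.get(ev_a.tag_id, set()):
                continue
            if ev_a.last < ev_b.first or ev_b.last < ev_a.first:
                continue
            # victim = suspected mimic (fewer messages)
            vi, si = (i, j) if ev_a.n_messages < ev_b.n_messages else (j, i)
            if evs[vi].n_messages == evs[si].n_messages and tagged_ids is not None:
                if evs[vi].tag_id in tagged_ids and evs[si].tag_id not in tagged_ids:
                    vi, si = si, vi
            victim, keeper = evs[vi], evs[si]
            vt = victim.times()
            kt = keeper.times()
            near = np.min(np.abs(vt[:, None] - kt[None, :]), axis=1) <= concurrency_tolerance
            if near.mean() < min_concurrent_fraction:
                continue
            if tracks is not None:
                sep = _median_track_separation(victim, keeper, tracks)
                if sep is not None and sep >= colocation_threshold:
                    continue
            dropped.add(vi)
            removed.append((victim, f"mimic of {keeper.tag_id}"))
    kept = [e for k, e in enumerate(evs) if k not in dropped]
    return kept, removed


def chronology_filter(
    events: Sequence[DetectionEvent],
    array_rkm: Mapping[str, float],
    release_times: Mapping[str, float] | None = None,
    dropped_tag_duration: float = 24 * 3600.0,
) -> tuple[list[DetectionEvent], list[tuple[DetectionEvent, str]]]:
    """Flag event histories impossible for a live downstream migrant.

    Migration runs toward the river mouth (decreasing river kilometer), so an
    event upstream of the farthest-downstream array already visited is
    anomalous, as are events before the tag's release and very long stationary
    events (a dropped tag lying near one receiver).  Flagged events are
    excluded from the returned history.
    """
    flags: list[tuple[DetectionEvent, str]] = []
    kept: list[DetectionEvent] = []
    by_tag: dict[str, list[DetectionEvent]] = {}
    for e in sorted(events, key=lambda e: e.first):
        by_tag.setdefault(e.tag_id, []).append(e)
    for tag, evs in by_tag.items():
        release = release_times.get(tag) if release_times else None
        min_rkm = np.inf
        for e in evs:
            rkm = array_rkm.get(e.array)
            if release is not None and e.first < release:
                flags.append((e, "before release"))
                continue
            if rkm is not None and rkm > min_rkm:
                flags.append((e, "upstream/out-of-sequence movement"))
                continue
            if e.last - e.first > dropped_tag_duration:
                flags.append((e, "possible dropped tag (stationary long-duration event)"))
                continue
            if rkm is not None:
                min_rkm = min(min_rkm, rkm)
            kept.append(e)
    kept.sort(key=lambda e: e.first)
    return kept, flags


def events_to_records(events: Sequence[DetectionEvent], cabled: bool = True):
    """Convert events to the event-data record schema (per-tag Event_ID
    ordered by first detection time)."""
    from .tables import AutonomousEventRecord, CabledEventRecord

    records = []
    counters: dict[str, int] = {}
    for e in sorted(events, key=lambda e: (e.tag_id, e.first)):
        counters[e.tag_id] = counters.get(e.tag_id, 0) + 1
        if cabled:
            records.append(
                CabledEventRecord(
                    phone_name=e.receiver or "",
                    tag_id=e.tag_id,
                    event_id=counters[e.tag_id],
                    first_datetime=e.first,
                    last_datetime=e.last,
                    n_messages=e.n_messages,
                )
            )
        else:
            records.append(
                AutonomousEventRecord(
                    node_id=e.array,
                    tag_id=e.tag_id,
                    first_datetime=e.first,
                    last_datetime=e.last,
                    n_messages=e.n_messages,
                )
            )
    return records
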