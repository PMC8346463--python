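"""Post-localization trajectory cleaning and quality-assurance trimming.

Raw 3-D tracks contain occasional gross outliers from mis-associated or
noise-contaminated TDOA sets.  Cleaning removes points that are spatially
isolated from both surviving temporal neighbors (> 45 m by default), splits
the track at long silences (> 10 min), and removes points implying swimming
speeds beyond what the studied fish can sustain (~2 m/s), iterating to a
fixed point so the result does not depend on scan order.  QA trimming then
restricts a track to the interval between the tag's release and the earliest
downstream evidence (PIT detection or autonomous-array event), outside of
which any apparent position at the dam is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CleaningConfig", "clean_trajectory", "qa_trim"]


@dataclass
class CleaningConfig:
    max_jump: float = 45.0  # m, spatial isolation threshold
    max_gap: float = 600.0  # s, temporal split threshold
    max_speed: float = 2.0  # m/s, plausible sustained speed for study fish
    min_fragment: int = 3  # points; shorter fragments after a split are dropped

    def __post_init__(self) -> None:
        if min(self.max_jump, self.max_gap, self.max_speed) <= 0:
            raise ValueError("all cleaning thresholds must be positive")


def _neighbor_metrics(t: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance and implied speed to the previous/next surviving point."""
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    dt = np.diff(t)
    v = d / np.maximum(dt, 1e-9)
    return d, v


def clean_trajectory(
    points: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove outlier points from a time-ordered track (columns time, x, y, z).

    A point is an outlier when it is farther than ``max_jump`` from *both*
    surviving temporal neighbors, or implies a speed above ``max_speed`` to
    both neighbors (requiring violation on both sides avoids deleting the
    innocent neighbor of a bad point); an endpoint is judged by its single
    neighbor.  Gaps longer than ``max_gap`` split the track, and fragments
    shorter than ``min_fragment`` points are dropped.  Rules are applied
    repeatedly until nothing changes, so the operation is a fixed point.

    Returns (cleaned points, removal log) where the log has columns
    ``time`` and ``rule``.
    """
    cfg = config or CleaningConfig()
    df = points.reset_index(drop=True)
    if not df["time"].is_monotonic_increasing:
        raise ValueError("points must be time-ordered")
    removed: list[tuple[float, str]] = []

    def drop_rule(sub: pd.DataFrame, metric: str, threshold: float, rule: str) -> pd.DataFrame:
        while len(sub) >= 2:
            t = sub["time"].to_numpy()
            p = sub[["x", "y", "z"]].to_numpy()
            d, v = _neighbor_metrics(t, p)
            m = d if metric == "distance" else v
            n = len(sub)
            bad = np.zeros(n, dtype=bool)
            bad[0] = m[0] > threshold
            bad[-1] = m[-1] > threshold
            if n > 2:
                bad[1:-1] = (m[:-1] > threshold) & (m[1:] > threshold)
            if not bad.any():
                break
            for tt in sub["time"].to_numpy()[bad]:
                removed.append((float(tt), rule))
            sub = sub[~bad]
        return sub

    prev_len = -1
    while len(df) != prev_len:
        prev_len = len(df)
        # split at long gaps, dropping undersized fragments
        t = df["time"].to_numpy()
        fragments: list[pd.DataFrame] = []
        if len(df):
            cuts = np.flatnonzero(np.diff(t) > cfg.max_gap) + 1
            for seg in np.split(np.arange(len(df)), cuts):
                frag = df.iloc[seg]
                if len(frag) < cfg.min_fragment:
                    for tt in frag["time"].to_numpy():
                        removed.append((float(tt), "short fragment after gap split"))
                else:
                    fragments.append(frag)
        cleaned = []
        for frag in fragments:
            frag = drop_rule(frag, "distance", cfg.max_jump, "spatial jump")
            frag = drop_rule(frag, "speed", cfg.max_speed, "implied speed")
            cleaned.append(frag)
        df = (
            pd.concat(cleaned).reset_index(drop=True)
            if cleaned
            else df.iloc[0:0].reset_index(drop=True)
        )
    log = pd.DataFrame(removed, columns=["time", "rule"])
    return df, log


def qa_trim(
    points: pd.DataFrame,
    release_time: float | None,
    downstream_times: Iterable[float] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a track to [release, earliest downstream evidence].

    ``downstream_times`` are instants proving the fish had left the dam (PIT
    detections downstream, autonomous-array events).  With no downstream
    evidence only the lower bound applies.  A missing release time flags all
    points rather than silently keeping them.

    Returns (kept points, flagged/removed points with a ``rule`` column).
    """
    df = points.reset_index(drop=True)
    if release_time is None:
        flagged = df.copy()
        flagged["rule"] = "missing release time"
        return df.iloc[0:0], flagged
    upper = min(downstream_times, default=np.inf)
    t = df["time"].to_numpy()
    before = t < release_time
    after = t > upper
    flagged = df[before | after].copy()
    flagged["rule"] = np.where(before[before | after], "before release", "after downstream evidence")
    return df[~(before | after)].reset_index(drop=True), flagged
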