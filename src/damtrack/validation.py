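"""GPS-referenced accuracy metrics and efficiency tables.

During a controlled survey a GPS-referenced tag is towed through the array
and the acoustic 3-D track is compared against the GPS benchmark.  For each
tracked point the reference position is linearly interpolated from the GPS
record at the acoustic fix time, and per-axis absolute differences

    dx_i = |x_i^3D - x_i^GPS|   (likewise dy_i, dz_i)

are summarized by their median and root-mean-square, RMS_x =
sqrt(mean(dx_i^2)).  Detection efficiency is valid detections over
transmissions; tracking efficiency is successful 3-D fixes over
transmissions.  Results are tabulated in 10 m bins of distance from the dam
face (the reference X coordinate); bins are half-open [k*10, (k+1)*10) and
labelled by their upper edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "error_stats",
    "efficiencies",
    "distance_binned_table",
    "match_times",
]

AXES = ("x", "y", "z")


def _interp_reference(gps: pd.DataFrame, times: np.ndarray) -> pd.DataFrame:
    ref = {"time": times}
    for c in AXES:
        ref[c] = np.interp(times, gps["time"].to_numpy(), gps[c].to_numpy())
    return pd.DataFrame(ref)


def error_stats(
    tracked: pd.DataFrame, gps: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Per-point absolute errors against the interpolated GPS reference.

    Returns (validation points, per-axis medians, per-axis RMS).  The
    validation table carries the tracked and reference coordinates plus
    ``dx, dy, dz``.  Tracked points outside the GPS time span are excluded
    with a warning (the reference cannot be interpolated there).  The median
    of an even-count sample is the mean of the two middle values.
    """
    if not gps["time"].is_monotonic_increasing:
        raise ValueError("GPS track must be strictly time-ordered")
    t = tracked["time"].to_numpy()
    span = (gps["time"].iloc[0], gps["time"].iloc[-1])
    inside = (t >= span[0]) & (t <= span[1])
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} tracked point(s) outside the GPS span excluded",
            stacklevel=2,
        )
    trk = tracked[inside].reset_index(drop=True)
    ref = _interp_reference(gps, trk["time"].to_numpy())
    out = pd.DataFrame({"time": trk["time"]})
    for c in AXES:
        out[f"{c}_3d"] = trk[c].to_numpy()
        out[f"{c}_gps"] = ref[c].to_numpy()
        out[f"d{c}"] = np.abs(trk[c].to_numpy() - ref[c].to_numpy())
    medians = {c: float(np.median(out[f"d{c}"])) if len(out) else np.nan for c in AXES}
    rms = {
        c: float(np.sqrt(np.mean(out[f"d{c}"] ** 2))) if len(out) else np.nan
        for c in AXES
    }
    return out, medians, rms


def match_times(
    emissions: np.ndarray, observed: np.ndarray, tolerance: float
) -> np.ndarray:
    """Boolean mask over emissions: does any observed time fall within
    ``tolerance``?  (Observation times include propagation delay, so the
    tolerance must cover max range / c plus timing noise.)"""
    emissions = np.asarray(emissions, dtype=float)
    observed = np.sort(np.asarray(observed, dtype=float))
    if observed.size == 0:
        return np.zeros(emissions.size, dtype=bool)
    idx = np.searchsorted(observed, emissions)
    left = observed[np.clip(idx - 1, 0, observed.size - 1)]
    right = observed[np.clip(idx, 0, observed.size - 1)]
    return np.minimum(np.abs(emissions - left), np.abs(right - emissions)) <= tolerance


def efficiencies(
    emissions: np.ndarray,
    message_times: np.ndarray,
    tracked_times: np.ndarray,
    tolerance: float = 0.5,
) -> tuple[float, float]:
    """(detection efficiency, tracking efficiency) for a known emission list.

    Detection efficiency = transmissions with a matching valid message /
    transmissions; tracking efficiency = transmissions with a successful 3-D
    fix / transmissions.  Matching pairs each emission with the nearest
    observed time within ``tolerance``.
    """
    emissions = np.asarray(emissions, dtype=float)
    if emissions.size == 0:
        raise ValueError("at least one transmission is required")
    det = float(match_times(emissions, message_times, tolerance).mean())
    trk = float(match_times(emissions, tracked_times, tolerance).mean())
    return det, trk


def distance_binned_table(
    validation_points: pd.DataFrame,
    emissions: np.ndarray,
    emission_distances: np.ndarray,
    message_times: np.ndarray,
    tracked_times: np.ndarray,
    bin_width: float = 10.0,
    max_distance: float | None = None,
    tolerance: float = 0.5,
) -> pd.DataFrame:
    """Per-distance-bin efficiencies and error statistics.

    Distance from the dam is the reference X coordinate: validation points are
    binned by ``x_gps`` and emissions by ``emission_distances`` (the reference
    X at emission time), so efficiency denominators and error statistics refer
    to the same physical bins.  Bin label = upper bin edge in metres.
    """
    emissions = np.asarray(emissions, dtype=float)
    emission_distances = np.asarray(emission_distances, dtype=float)
    if max_distance is None:
        max_distance = float(emission_distances.max()) if emission_distances.size else 0.0
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    det_mask = match_times(emissions, message_times, tolerance)
    trk_mask = match_times(emissions, tracked_times, tolerance)
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        in_bin_e = (emission_distances >= lo) & (emission_distances < hi)
        n_trans = int(in_bin_e.sum())
        vp = validation_points[
            (validation_points["x_gps"] >= lo) & (validation_points["x_gps"] < hi)
        ]
        row = {
            "distance_m": hi,
            "n_transmissions": n_trans,
            "detection_efficiency": float(det_mask[in_bin_e].mean()) if n_trans else np.nan,
            "tracking_efficiency": float(trk_mask[in_bin_e].mean()) if n_trans else np.nan,
            "n_points": len(vp),
        }
        for c in AXES:
            row[f"median_d{c}"] = float(np.median(vp[f"d{c}"])) if len(vp) else np.nan
            row[f"rms_d{c}"] = float(np.sqrt(np.mean(vp[f"d{c}"] ** 2))) if len(vp) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
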