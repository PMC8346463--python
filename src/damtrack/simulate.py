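"""Synthetic telemetry: fish tracks, tag transmissions, decodes, USV surveys.

This generator reproduces the statistical structure the processing pipeline
assumes, so every stage can be exercised end-to-end without field data:

* tags transmit at a nominal ping-rate interval (4.2 s for study fish, 3 s for
  the survey tag) with small Gaussian jitter;
* signals propagate at the freshwater sound speed, arrive with Gaussian timing
  noise, and are detected with a range-dependent probability (logistic decay,
  ~0.99 at 140 m by default, matching the scale of field efficiencies);
* multipath reflections produce duplicate decodes a short positive lag
  (< ~0.3 s) after the direct arrival;
* environmental noise produces Poisson false-positive decodes whose embedded
  id fields passed the 8-bit CRC by chance (rate 1/256 for random words);
* occasional bit corruption converts a real transmission into a "mimic"
  tag-code with a still-valid CRC;
* cabled receivers share one clock (GPS-disciplined), autonomous receivers
  each carry an independent constant offset;
* a USV-style survey tows a GPS-referenced tag along per-bay transects out to
  150 m from the dam face at 0.28 m/s.

Fish movement is a correlated random walk; no hydrodynamics or behavioral
response to structures is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import tagcodes
from .dams import DamGeometry
from .localize import DamFrame, GeoAffine, sound_speed

__all__ = [
    "PropagationModel",
    "SurveyResult",
    "pier_array",
    "simulate_fish_track",
    "simulate_transmissions",
    "propagate_to_decodes",
    "inject_noise",
    "simulate_usv_survey",
    "hydrophone_config_records",
]

DECODE_COLUMNS = ["receiver", "tag_id", "time", "source", "origin", "emission_index"]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class PropagationModel:
    """Acoustic channel between tags and hydrophones.

    ``detection_*`` parametrize a logistic range-detection curve
    p(r) = p_max / (1 + exp((r - r50) / scale)), monotone non-increasing with
    p(140 m) ~ 0.99 at the defaults.
    """

    c: float = field(default_factory=lambda: sound_speed(18.0))
    sigma_t: float = 1e-5  # arrival-time noise sd, s
    detection_p_max: float = 0.999
    detection_r50: float = 250.0  # m, range of half-maximum detection
    detection_scale: float = 25.0  # m, logistic width
    p_multipath: float = 0.2
    multipath_lag: tuple[float, float] = (0.01, 0.3)  # s, uniform support
    lambda_fp: float = 0.0  # false-positive decodes / s / hydrophone
    p_mimic: float = 0.0
    clock_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("sound speed must be positive")
        if self.sigma_t < 0:
            raise ValueError("timing noise sd must be >= 0")
        if not 0 <= self.detection_p_max <= 1:
            raise ValueError("detection p_max must be in [0, 1]")
        if not 0 < self.multipath_lag[0] <= self.multipath_lag[1]:
            raise ValueError("multipath lags must be strictly positive and ordered")
        if self.lambda_fp < 0 or not 0 <= self.p_mimic <= 1:
            raise ValueError("noise rates must be non-negative")

    def detection_probability(self, rng_range) -> np.ndarray:
        r = np.asarray(rng_range, dtype=float)
        return self.detection_p_max / (1.0 + np.exp((r - self.detection_r50) / self.detection_scale))


def pier_array(
    geometry: DamGeometry,
    piers: Sequence[int] | None = None,
    shallow: tuple[float, float] = (0.3, -2.0),
    deep: tuple[float, float] = (1.5, -12.0),
) -> tuple[dict[str, tuple[float, float, float]], dict[str, int]]:
    """Hydrophone positions for a pier-mounted cabled array.

    Each pier nose carries a shallow and a deep phone; the pier slopes
    upstream, so the deep phone sits slightly further into the forebay
    (larger X).  Returns (positions, phone -> pier_id).
    """
    piers = list(piers) if piers is not None else list(range(1, geometry.n_piers + 1))
    positions: dict[str, tuple[float, float, float]] = {}
    pier_of: dict[str, int] = {}
    for p in piers:
        y = geometry.pier_y(p)
        for label, (x, z) in (("S", shallow), ("D", deep)):
            name = f"P{p:02d}{label}"
            positions[name] = (x, y, z)
            pier_of[name] = p
    return positions, pier_of


def simulate_fish_track(
    seed,
    start: Sequence[float] = (150.0, 100.0, -5.0),
    mean_speed: float = 0.5,
    speed_sd: float = 0.1,
    max_speed: float = 1.5,
    heading: float = 180.0,
    persistence: float = 0.95,
    turn_sd: float = 0.5,  # rad per step at persistence 0
    vertical_sd: float = 0.05,
    duration: float = 600.0,
    timestep: float = 1.0,
    z_range: tuple[float, float] = (-25.0, -0.5),
) -> pd.DataFrame:
    """Correlated-random-walk trajectory; columns time, x, y, z.

    ``heading`` is degrees in the XY plane (0 = +X, CCW); ``persistence`` in
    [0, 1] scales down the per-step heading noise, with 1 giving a straight
    line.  Per-step displacement never exceeds ``max_speed * timestep``.
    """
    if timestep <= 0:
        raise ValueError("timestep must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 <= persistence <= 1:
        raise ValueError("persistence must be in [0, 1]")
    rng = _rng(seed)
    n = int(np.floor(duration / timestep)) + 1
    times = np.arange(n) * timestep
    pos = np.empty((n, 3))
    pos[0] = start
    theta = np.deg2rad(heading)
    sigma_turn = turn_sd * (1.0 - persistence)
    for i in range(1, n):
        theta += sigma_turn * rng.standard_normal()
        speed = np.clip(mean_speed + speed_sd * rng.standard_normal(), 0.0, max_speed)
        dz_rate = vertical_sd * rng.standard_normal()
        step = np.array([np.cos(theta) * speed, np.sin(theta) * speed, dz_rate]) * timestep
        norm = float(np.linalg.norm(step))
        if norm > max_speed * timestep and norm > 0:
            step *= max_speed * timestep / norm
        pos[i] = pos[i - 1] + step
        pos[i, 2] = np.clip(pos[i, 2], *z_range)
    return pd.DataFrame({"time": times, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})


def simulate_transmissions(
    seed,
    pri_nominal: float,
    jitter_sd: float = 0.0,
    duration: float = 600.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Emission times of one tag: intervals ~ Normal(pri_nominal, jitter_sd)."""
    if pri_nominal <= 0:
        raise ValueError("PRI must be positive")
    if jitter_sd >= pri_nominal / 2:
        raise ValueError("jitter sd must be below half the PRI to keep the lattice")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    n_max = int(np.ceil(duration / pri_nominal)) + 10
    intervals = pri_nominal + jitter_sd * rng.standard_normal(n_max)
    intervals = np.clip(intervals, pri_nominal / 10, None)
    times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    return times[times < t0 + duration]


def _interp_track(track: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    out = np.empty((times.size, 3))
    for k, col in enumerate(("x", "y", "z")):
        out[:, k] = np.interp(times, track["time"].to_numpy(), track[col].to_numpy())
    return out


def propagate_to_decodes(
    track: pd.DataFrame,
    emissions: np.ndarray,
    hydrophones: dict[str, Sequence[float]],
    model: PropagationModel,
    seed,
    tag_id: str,
    source: str = "cabled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward model: emissions -> per-hydrophone decodes plus a truth table.

    Decode time = emission + range/c + N(0, sigma_t) (+ the receiver's clock
    offset, if any); detection is Bernoulli in range; detected decodes spawn a
    multipath echo with probability ``p_multipath`` at a positive uniform lag.
    """
    if not hydrophones:
        raise ValueError("at least one hydrophone is required")
    rng = _rng(seed)
    emissions = np.asarray(emissions, dtype=float)
    src = _interp_track(track, emissions)
    rows = []
    truth_rows = []
    for name, p in hydrophones.items():
        p = np.asarray(p, dtype=float)
        ranges = np.linalg.norm(src - p[None, :], axis=1)
        arrivals = emissions + ranges / model.c
        detected = rng.random(emissions.size) < model.detection_probability(ranges)
        offset = model.clock_offsets.get(name, 0.0)
        noisy = arrivals + model.sigma_t * rng.standard_normal(emissions.size) + offset
        for i in np.flatnonzero(detected):
            rows.append((name, tag_id, noisy[i], source, "direct", i))
            if rng.random() < model.p_multipath:
                lag = rng.uniform(*model.multipath_lag)
                rows.append((name, tag_id, noisy[i] + lag, source, "multipath", i))
        for i in range(emissions.size):
            truth_rows.append(
                (tag_id, i, emissions[i], src[i, 0], src[i, 1], src[i, 2], name,
                 arrivals[i], bool(detected[i]))
            )
    decodes = pd.DataFrame(rows, columns=DECODE_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["tag_id", "emission_index", "emission_time", "x", "y", "z",
                 "receiver", "true_arrival", "detected"],
    )
    return decodes.sort_values("time", kind="stable").reset_index(drop=True), truth


def inject_noise(
    decodes: pd.DataFrame,
    model: PropagationModel,
    seed,
    time_span: tuple[float, float] | None = None,
    receivers: Iterable[str] | None = None,
    mimic_table: dict[str, set[str]] | None = None,
    source: str = "cabled",
) -> pd.DataFrame:
    """Add false-positive decodes and mimic corruption to a decode table.

    False positives arrive as a Poisson process of rate ``lambda_fp`` per
    receiver with id fields drawn from random words that happened to pass CRC
    validation; with probability ``p_mimic`` a true decode's id is replaced by
    one of its mimic codes (when the mimic table offers one).
    """
    rng = _rng(seed)
    out = decodes.copy()
    if model.p_mimic > 0 and mimic_table:
        hit = rng.random(len(out)) < model.p_mimic
        for idx in np.flatnonzero(hit):
            tid = out.iat[idx, out.columns.get_loc("tag_id")]
            mimics = sorted(mimic_table.get(tid, ()))
            if mimics:
                out.iat[idx, out.columns.get_loc("tag_id")] = mimics[rng.integers(len(mimics))]
                out.iat[idx, out.columns.get_loc("origin")] = "mimic"
    if model.lambda_fp > 0:
        if time_span is None:
            if len(out) == 0:
                raise ValueError("time_span required when the decode table is empty")
            time_span = (float(out["time"].min()), float(out["time"].max()))
        if receivers is None:
            receivers = sorted(out["receiver"].unique())
        t0, t1 = time_span
        rows = []
        for rec in receivers:
            n = rng.poisson(model.lambda_fp * (t1 - t0))
            if n == 0:
                continue
            times = rng.uniform(t0, t1, size=n)
            ids = tagcodes.random_valid_ids(n, rng)
            for t, i in zip(times, ids):
                rows.append((rec, tagcodes.format_tag_id(int(i)), t, source,
                             "false_positive", -1))
        if rows:
            out = pd.concat([out, pd.DataFrame(rows, columns=DECODE_COLUMNS)])
    return out.sort_values("time", kind="stable").reset_index(drop=True)


@dataclass
class SurveyResult:
    """Outputs of a simulated GPS-referenced USV survey."""

    tag_id: str
    track: pd.DataFrame  # dense truth positions (time, x, y, z)
    gps: pd.DataFrame  # GPS reference samples (time, x, y, z)
    emissions: np.ndarray
    decodes: pd.DataFrame
    truth: pd.DataFrame
    model: PropagationModel


def simulate_usv_survey(
    geometry: DamGeometry,
    hydrophones: dict[str, Sequence[float]],
    model: PropagationModel,
    seed,
    bays: Sequence[str] | None = None,
    max_range: float = 150.0,
    speed: float = 0.28,
    pri: float = 3.0,
    pri_jitter_sd: float = 0.01,
    tag_depth: float = 3.0,
    start_x: float = 5.0,
    gps_rate_hz: float = 1.0,
    gps_noise_sd: float = 0.0,
    tag_id: str = "0BB8",
) -> SurveyResult:
    """Tow a 3 s-PRI tag out to ``max_range`` and back in front of each bay.

    The towed tag sits ``tag_depth`` m below the surface; a survey-grade GPS
    samples the reference position at ``gps_rate_hz`` with optional noise.
    Transit legs between bay lines run parallel to the dam at ``start_x``.
    """
    if not hydrophones:
        raise ValueError("array must be nonempty")
    rng = _rng(seed)
    bay_list = [geometry.bay_by_hole(h) for h in bays] if bays else list(geometry.bays)
    z = -abs(tag_depth)
    waypoints = []
    for bay in bay_list:
        yc = bay.center
        waypoints += [(start_x, yc), (max_range, yc), (start_x, yc)]
    # densify the waypoint path at constant speed
    times = [0.0]
    points = [waypoints[0]]
    for (x0, y0), (x1, y1) in zip(waypoints, waypoints[1:]):
        seg = float(np.hypot(x1 - x0, y1 - y0))
        if seg == 0.0:
            continue
        times.append(times[-1] + seg / speed)
        points.append((x1, y1))
    t_knots = np.asarray(times)
    xy = np.asarray(points, dtype=float)
    duration = float(t_knots[-1])
    dense_t = np.arange(0.0, duration, 1.0)
    track = pd.DataFrame(
        {
            "time": dense_t,
            "x": np.interp(dense_t, t_knots, xy[:, 0]),
            "y": np.interp(dense_t, t_knots, xy[:, 1]),
            "z": np.full(dense_t.size, z),
        }
    )
    gps_t = np.arange(0.0, duration, 1.0 / gps_rate_hz)
    gps = pd.DataFrame(
        {
            "time": gps_t,
            "x": np.interp(gps_t, t_knots, xy[:, 0]) + gps_noise_sd * rng.standard_normal(gps_t.size),
            "y": np.interp(gps_t, t_knots, xy[:, 1]) + gps_noise_sd * rng.standard_normal(gps_t.size),
            "z": z + gps_noise_sd * rng.standard_normal(gps_t.size),
        }
    )
    emissions = simulate_transmissions(rng, pri, pri_jitter_sd, duration)
    decodes, truth = propagate_to_decodes(track, emissions, hydrophones, model, rng, tag_id)
    return SurveyResult(
        tag_id=tag_id, track=track, gps=gps, emissions=emissions,
        decodes=decodes, truth=truth, model=model,
    )


def hydrophone_config_records(
    geometry: DamGeometry,
    positions: dict[str, tuple[float, float, float]],
    pier_of: dict[str, int],
    frame: DamFrame,
    geo: GeoAffine | None = None,
):
    """Render an array as hydrophone-configuration records (the deployment
    schema), so simulated arrays feed the same readers as deposited data."""
    from .tables import HydrophoneConfig

    records = []
    for i, (name, (x, y, z)) in enumerate(sorted(positions.items()), start=1):
        e, n, el = frame.to_geo(x, y, z)
        lon, lat = geo(e, n) if geo is not None else (0.0, 0.0)
        records.append(
            HydrophoneConfig(
                sys_index=(i + 3) // 4,
                sys_name=f"PS{(i + 3) // 4}",
                location=name,
                node_position=name[-1],
                channel=(i - 1) % 4 + 1,
                phone_id=i,
                pier_id=pier_of[name],
                phone_name=name,
                latitude=float(lat),
                longitude=float(lon),
                easting=float(e),
                northing=float(n),
                elevation=float(el),
                x=x,
                y=y,
                z=z,
            )
        )
    return records
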