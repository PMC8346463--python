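"""End-to-end pipeline: simulate -> filter -> localize -> clean -> route -> validate.

Each stage reads/writes plain CSV artifacts in an output directory using the
data-record schemas where one exists, so any stage can be rerun or replaced by
deposited field data.  Per-stage decode/message counts are logged: the filter
cascade must only ever shrink the data, and the log makes that auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import dams, filters, localize, routing, simulate, tables, tagcodes, trajectory, validation

log = logging.getLogger("damtrack")

__all__ = ["PipelineConfig", "run_simulate", "run_filter", "run_track", "run_route", "run_validate", "run_all"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with their default values.

    Defaults mirror the study conditions: 4.2 s tag PRI, 0.3 s multipath
    window, 45 m / 10 min / 2 m/s trajectory thresholds, 25 m side margin and
    30 m upstream depth for route assignment, 3 s survey-tag PRI at 0.28 m/s,
    10 m validation bins.
    """

    seed: int = 1
    out_dir: str = "out"
    # simulation
    n_fish: int = 3
    duration: float = 900.0
    pri: float = 4.2
    pri_jitter_sd: float = 0.05
    sigma_t: float = 1e-5
    p_multipath: float = 0.2
    lambda_fp: float = 0.005
    p_mimic: float = 0.0
    temperature_c: float = 18.0
    # dam geometry
    dam_name: str = "SYN"
    n_turbines: int = 6
    n_spillbays: int = 7
    weir_bays: tuple[str, ...] = ("B01",)
    # filters
    multipath_window: float = 0.3
    grouping_window: float | None = None  # default: aperture/c + 3 sigma_t
    pri_tolerance: float = 0.2
    min_messages: int = 4
    k_max: int = 12
    gap_close: float | None = None
    mimic_max_weight: int = 4
    # trajectory cleaning
    max_jump: float = 45.0
    max_gap: float = 600.0
    max_speed: float = 2.0
    # routing
    margin_side: float = 25.0
    depth_upstream: float = 30.0
    # validation survey
    survey_bays: tuple[str, ...] = ("T03", "B02")
    survey_pri: float = 3.0
    survey_speed: float = 0.28
    survey_max_range: float = 150.0
    bin_width: float = 10.0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict[str, Any] = {}
        for key, value in raw.items():
            if isinstance(value, Mapping):
                flat.update(value)
            else:
                flat[key] = value
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("weir_bays", "survey_bays"):
            if key in flat:
                flat[key] = tuple(flat[key])
        return cls(**flat)

    def geometry(self) -> dams.DamGeometry:
        return dams.standard_geometry(
            name=self.dam_name,
            n_turbines=self.n_turbines,
            n_spillbays=self.n_spillbays,
            weir_bays=self.weir_bays,
        )

    def model(self, **overrides) -> simulate.PropagationModel:
        kwargs = dict(
            c=localize.sound_speed(self.temperature_c),
            sigma_t=self.sigma_t,
            p_multipath=self.p_multipath,
            lambda_fp=self.lambda_fp,
            p_mimic=self.p_mimic,
        )
        kwargs.update(overrides)
        return simulate.PropagationModel(**kwargs)

    def localization(self, positions: Mapping[str, tuple[float, float, float]]) -> localize.LocalizationConfig:
        pos = np.array(list(positions.values()))
        y_lo, y_hi = float(pos[:, 1].min()), float(pos[:, 1].max())
        return localize.LocalizationConfig(
            temperature_c=self.temperature_c,
            bounds=(
                (0.0, self.survey_max_range + 30.0),
                (y_lo - 40.0, y_hi + 40.0),
                (-30.0, 0.0),
            ),
        )

    def grouping_window_for(self, positions: Mapping[str, tuple[float, float, float]]) -> float:
        if self.grouping_window is not None:
            return self.grouping_window
        pos = np.array(list(positions.values()))
        aperture = max(
            float(np.linalg.norm(a - b)) for a in pos for b in pos
        )
        return aperture / localize.sound_speed(self.temperature_c) + 3 * self.sigma_t


def _frame() -> localize.DamFrame:
    # synthetic state-plane placement of the dam-local origin
    return localize.DamFrame(
        origin_easting=400_000.0, origin_northing=150_000.0,
        origin_elevation=150.0, theta=np.deg2rad(30.0),
    )


def _arrivals_span(decodes: pd.DataFrame) -> tuple[float, float]:
    return float(decodes["time"].min()), float(decodes["time"].max())


def run_simulate(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    """Generate array metadata, tagged fish, and raw decode tables."""
    rng = np.random.default_rng(cfg.seed)
    geometry = cfg.geometry()
    positions, pier_of = simulate.pier_array(geometry)
    frame = _frame()
    model = cfg.model()

    hydro_records = simulate.hydrophone_config_records(geometry, positions, pier_of, frame)
    tables.write_table(hydro_records, out / f"{cfg.dam_name}_Hydrophone_Configuration.csv", "hydrophone_config")

    y_lo, y_hi = geometry.y_span
    fish = []
    all_decodes = []
    truth_tracks = {}
    t_base = 1_372_000_000.0  # fixed epoch anchor for readable datetimes
    for k in range(cfg.n_fish):
        tag_id = tagcodes.format_tag_id(int(rng.integers(0, 1 << 16)))
        release = t_base - 3600.0
        fish.append(
            tables.TaggedFish(
                tag_id=tag_id,
                pit_id=f"PIT{k:05d}",
                release_date=release,
                pri=cfg.pri,
                tagging_date=release - 7200.0,
                fork_length_mm=float(rng.uniform(95, 143)),
                weight_g=float(rng.uniform(7.5, 29.3)),
            )
        )
        start_y = float(rng.uniform(y_lo + 10, y_hi - 10))
        track = simulate.simulate_fish_track(
            rng,
            start=(min(cfg.duration * 0.4, 140.0), start_y, -6.0),
            heading=180.0,
            persistence=0.97,
            mean_speed=0.45,
            duration=cfg.duration,
        )
        track["time"] += t_base
        truth_tracks[tag_id] = track
        emissions = simulate.simulate_transmissions(rng, cfg.pri, cfg.pri_jitter_sd, cfg.duration, t0=t_base)
        decodes, _ = simulate.propagate_to_decodes(track, emissions, positions, model, rng, tag_id)
        all_decodes.append(decodes)
    decodes = pd.concat(all_decodes).sort_values("time").reset_index(drop=True)
    mimics = tagcodes.mimic_table([tagcodes.parse_tag_id(f.tag_id) for f in fish], cfg.mimic_max_weight)
    mimic_hex = {
        tagcodes.format_tag_id(k): {tagcodes.format_tag_id(v) for v in vs}
        for k, vs in mimics.items()
    }
    decodes = simulate.inject_noise(
        decodes, model, rng, time_span=_arrivals_span(decodes),
        receivers=positions, mimic_table=mimic_hex,
    )
    tables.write_table(fish, out / "Tagged_Fish_List.csv", "tagged_fish")
    decodes.to_csv(out / "raw_decodes.csv", index=False)
    for tag, track in truth_tracks.items():
        track.to_csv(out / f"truth_track_{tag}.csv", index=False)
    log.info("simulate: %d fish, %d raw decodes", cfg.n_fish, len(decodes))
    return {"n_fish": cfg.n_fish, "n_decodes": len(decodes)}


def run_filter(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    """Cabled filter cascade: multipath -> group -> single-detection -> PRI -> mimic."""
    decodes = pd.read_csv(out / "raw_decodes.csv", dtype={"tag_id": str})
    geometry = cfg.geometry()
    positions, _ = simulate.pier_array(geometry)
    counts = {"raw": len(decodes)}
    mp = filters.multipath_filter(decodes, cfg.multipath_window)
    counts["multipath"] = len(mp)
    window = cfg.grouping_window_for(positions)
    messages = filters.group_messages(mp, window)
    counts["messages"] = len(messages)
    multi = filters.single_detection_filter(messages)
    counts["single_detection"] = len(multi)
    fish = tables.read_table(out / "Tagged_Fish_List.csv", "tagged_fish")
    accepted_all = []
    events_all = []
    by_tag: dict[str, list[filters.Message]] = {}
    for m in multi:
        by_tag.setdefault(m.tag_id, []).append(m)
    for tag, msgs in by_tag.items():
        accepted, events = filters.pri_event_filter(
            msgs, cfg.pri, cfg.pri_tolerance, cfg.min_messages, cfg.k_max,
            cfg.gap_close, array=cfg.dam_name,
        )
        accepted_all.extend(accepted)
        events_all.extend(events)
    counts["pri_accepted"] = len(accepted_all)
    mimics = tagcodes.mimic_table([tagcodes.parse_tag_id(f.tag_id) for f in fish], cfg.mimic_max_weight)
    mimic_hex = {
        tagcodes.format_tag_id(k): {tagcodes.format_tag_id(v) for v in vs}
        for k, vs in mimics.items()
    }
    events_kept, _removed = filters.mimic_event_filter(
        events_all, mimic_hex, tagged_ids={f.tag_id for f in fish}
    )
    counts["events"] = len(events_kept)
    tables.write_table(
        filters.events_to_records(events_kept, cabled=True),
        out / f"{cfg.dam_name}_Event_Data.csv",
        "cabled_events",
    )
    rows = []
    for e in events_kept:
        for m in e.messages:
            for r, t in m.decodes:
                rows.append((m.tag_id, r, t))
    pd.DataFrame(rows, columns=["tag_id", "receiver", "time"]).to_csv(
        out / "accepted_decodes.csv", index=False
    )
    log.info("filter: counts %s", counts)
    return counts


def run_track(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    """Localize accepted messages and clean the resulting trajectories."""
    geometry = cfg.geometry()
    positions, _ = simulate.pier_array(geometry)
    frame = _frame()
    lcfg = cfg.localization(positions)
    df = pd.read_csv(out / "accepted_decodes.csv", dtype={"tag_id": str})
    window = cfg.grouping_window_for(positions)
    messages = filters.group_messages(
        df.assign(source="cabled", origin="accepted", emission_index=-1), window
    )
    by_tag: dict[str, list[filters.Message]] = {}
    for m in messages:
        by_tag.setdefault(m.tag_id, []).append(m)
    fish = {f.tag_id: f for f in tables.read_table(out / "Tagged_Fish_List.csv", "tagged_fish")}
    ccfg = trajectory.CleaningConfig(cfg.max_jump, cfg.max_gap, cfg.max_speed)
    track_records = []
    n_points = 0
    for tag, msgs in sorted(by_tag.items()):
        result = localize.track_tag(msgs, positions, lcfg, frame=frame)
        pts = pd.DataFrame(
            [(p.time, p.x, p.y, p.z, p.easting, p.northing, p.elevation) for p in result.points],
            columns=["time", "x", "y", "z", "easting", "northing", "elevation"],
        )
        cleaned, _log = trajectory.clean_trajectory(pts, ccfg)
        release = fish[tag].release_date if tag in fish else None
        trimmed, _flags = trajectory.qa_trim(cleaned, release)
        n_points += len(trimmed)
        for _, row in trimmed.iterrows():
            e, n, el = frame.to_geo(row["x"], row["y"], row["z"])
            track_records.append(
                tables.TrackRecord(
                    tag_id=tag, time=row["time"], latitude=None, longitude=None,
                    easting=float(e), northing=float(n), elevation=float(el),
                    x=float(row["x"]), y=float(row["y"]), z=float(row["z"]),
                )
            )
    tables.write_table(track_records, out / f"{cfg.dam_name}_3D_Tracks.csv", "tracks_3d")
    log.info("track: %d cleaned track points", n_points)
    return {"n_track_points": n_points}


def run_route(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    """Assign and reconcile passage routes; write the route table."""
    geometry = cfg.geometry()
    positions, pier_of = simulate.pier_array(geometry)
    window = cfg.grouping_window_for(positions)
    tracks = tables.read_table(out / f"{cfg.dam_name}_3D_Tracks.csv", "tracks_3d")
    df = pd.read_csv(out / "accepted_decodes.csv", dtype={"tag_id": str})
    messages = filters.group_messages(
        df.assign(source="cabled", origin="accepted", emission_index=-1), window
    )
    by_tag: dict[str, list[filters.Message]] = {}
    for m in messages:
        by_tag.setdefault(m.tag_id, []).append(m)
    track_by_tag: dict[str, list[tables.TrackRecord]] = {}
    for r in tracks:
        track_by_tag.setdefault(r.tag_id, []).append(r)
    assignments = []
    for tag in sorted(set(by_tag) | set(track_by_tag)):
        traj = pd.DataFrame(
            [(r.time, r.x, r.y, r.z) for r in track_by_tag.get(tag, [])],
            columns=["time", "x", "y", "z"],
        ).sort_values("time")
        r_track = routing.route_from_track(traj, tag, geometry, cfg.margin_side, cfg.depth_upstream)
        r_last = routing.route_from_last_detection(by_tag.get(tag, []), pier_of, geometry)
        final = routing.reconcile(r_track, r_last, geometry)
        if final is not None:
            assignments.append(final)
    tables.write_table(
        routing.assignments_to_records(assignments),
        out / f"{cfg.dam_name}_Passage_Routes.csv",
        "passage_routes",
    )
    n_review = sum(a.review for a in assignments)
    log.info("route: %d assignments, %d flagged for review", len(assignments), n_review)
    return {"n_assignments": len(assignments), "n_review": n_review}


def run_validate(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    """Simulated GPS-referenced survey and the binned accuracy table."""
    rng_seed = cfg.seed + 1000
    geometry = cfg.geometry()
    positions, _ = simulate.pier_array(geometry)
    model = cfg.model(lambda_fp=0.0, p_mimic=0.0)
    survey = simulate.simulate_usv_survey(
        geometry, positions, model, rng_seed,
        bays=list(cfg.survey_bays), max_range=cfg.survey_max_range,
        speed=cfg.survey_speed, pri=cfg.survey_pri,
    )
    lcfg = cfg.localization(positions)
    window = cfg.grouping_window_for(positions)
    mp = filters.multipath_filter(survey.decodes, cfg.multipath_window)
    messages = filters.group_messages(mp, window)
    messages = filters.single_detection_filter(messages)
    result = localize.track_tag(messages, positions, lcfg)
    tracked = pd.DataFrame(
        [(p.time, p.x, p.y, p.z) for p in result.points],
        columns=["time", "x", "y", "z"],
    )
    vp, medians, rms = validation.error_stats(tracked, survey.gps)
    ref_x = np.interp(survey.emissions, survey.track["time"], survey.track["x"])
    table = validation.distance_binned_table(
        vp, survey.emissions, ref_x,
        np.array([m.time for m in messages]), tracked["time"].to_numpy(),
        bin_width=cfg.bin_width, max_distance=cfg.survey_max_range,
    )
    table.to_csv(out / "survey_accuracy_table.csv", index=False)
    log.info("validate: medians %s rms %s", medians, rms)
    return {"medians": medians, "rms": rms, "n_bins": len(table)}


STAGES = {
    "simulate": run_simulate,
    "filter": run_filter,
    "track": run_track,
    "route": run_route,
    "validate": run_validate,
}


def run_all(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    summary = {}
    for name in ("simulate", "filter", "track", "route", "validate"):
        summary[name] = STAGES[name](cfg, out)
    return summary
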