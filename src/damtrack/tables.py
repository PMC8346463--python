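"""Typed readers/writers for the study's CSV data-record schemas.

Each deposited file is a plain comma-separated table with a printed header.
This module registers every schema (hydrophone configuration, autonomous
deployments, tagged fish, PIT detections, cabled/autonomous detection events,
3-D tracks, passage routes), parses rows into typed records, validates the
record-level invariants, and writes records back out so that
``read_table(write_table(records))`` is the identity.

Datetimes are ISO-8601-like in the files and plain UTC epoch seconds
internally; files without an explicit offset are interpreted at a configurable
constant offset (default UTC).  Header matching tolerates whitespace,
underscore and dash variants but emits the printed form verbatim.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Any, Callable, Sequence

import pandas as pd

from . import dams

__all__ = [
    "SchemaError",
    "RecordError",
    "HydrophoneConfig",
    "AutonomousDeployment",
    "TaggedFish",
    "PitDetection",
    "CabledEventRecord",
    "AutonomousEventRecord",
    "TrackRecord",
    "RouteRecord",
    "SCHEMAS",
    "FILENAME_SCHEMAS",
    "schema_for_filename",
    "read_table",
    "write_table",
    "parse_datetime",
    "format_datetime",
]


class SchemaError(ValueError):
    """Header does not match the registered schema."""


class RecordError(ValueError):
    """A row or record violates the schema's types or invariants."""


# ---------------------------------------------------------------------------
# datetime handling

_DT_FORMATS = (
    "%Y-%m-%d %H:%M:%S.%f",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%dT%H:%M:%S.%f",
    "%Y-%m-%dT%H:%M:%S",
    "%m/%d/%Y %H:%M:%S",
    "%m/%d/%Y %H:%M",
)

#: Format string actually used by the most recent successful parse, for logging.
last_datetime_format: str | None = None


def parse_datetime(text: str, utc_offset_hours: float = 0.0) -> float:
    """Parse a timestamp string to UTC epoch seconds.

    A small set of common formats is accepted; strings without an explicit
    offset are taken to be at ``utc_offset_hours`` relative to UTC.
    """
    global last_datetime_format
    text = text.strip()
    for fmt in _DT_FORMATS:
        try:
            dt = datetime.strptime(text, fmt)
        except ValueError:
            continue
        last_datetime_format = fmt
        dt = dt.replace(tzinfo=timezone(timedelta(hours=utc_offset_hours)))
        return dt.timestamp()
    raise ValueError(f"unrecognized datetime {text!r}")


def format_datetime(epoch_s: float) -> str:
    dt = datetime.fromtimestamp(epoch_s, tz=timezone.utc)
    return dt.strftime("%Y-%m-%d %H:%M:%S.%f")


# ---------------------------------------------------------------------------
# record types

@dataclass
class HydrophoneConfig:
    sys_index: int
    sys_name: str
    location: str
    node_position: str
    channel: int
    phone_id: int
    pier_id: int
    phone_name: str
    latitude: float
    longitude: float
    easting: float
    northing: float
    elevation: float
    x: float
    y: float
    z: float

    def check(self) -> None:
        if self.pier_id < 0:
            raise RecordError("pier_id must be >= 0")
        if self.node_position not in ("D", "S"):
            raise RecordError("node_position must be 'D' (deep) or 'S' (shallow)")
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise RecordError("dam-local coordinates must be finite")


@dataclass
class AutonomousDeployment:
    node_id: str
    node_sn: str
    latitude: float
    longitude: float
    river_km: float
    depth: float
    deploy_date: float
    recovery_date: float
    location_id: str
    start_sample: float
    end_sample: float
    comments: str = ""

    def check(self) -> None:
        if not self.deploy_date < self.recovery_date:
            raise RecordError("deploy date must precede recovery date")
        if self.start_sample < self.deploy_date:
            raise RecordError("sampling cannot start before deployment")


@dataclass
class TaggedFish:
    tag_id: str
    pit_id: str
    release_date: float
    pri: float
    tagging_date: float
    fork_length_mm: float
    weight_g: float

    def check(self) -> None:
        if self.pri <= 0:
            raise RecordError("PRI must be positive")
        if self.tagging_date > self.release_date:
            raise RecordError("tagging must not postdate release")


@dataclass
class PitDetection:
    tag_id: str
    pit_id: str
    first_datetime: float
    last_datetime: float
    site: str
    site_description: str
    site_basin: str
    site_subbasin: str
    site_type: str
    site_latitude: float
    site_longitude: float
    site_rkm: float
    fish_characteristics: str
    pit_tagging_date: float
    fork_length_mm: float
    weight_g: float

    def check(self) -> None:
        if self.first_datetime > self.last_datetime:
            raise RecordError("first PIT detection must not postdate last")


@dataclass
class CabledEventRecord:
    phone_name: str
    tag_id: str
    event_id: int
    first_datetime: float
    last_datetime: float
    n_messages: int

    def check(self) -> None:
        if self.first_datetime > self.last_datetime:
            raise RecordError("event start must not postdate event end")
        if self.n_messages < 1:
            raise RecordError("event must contain at least one message")


@dataclass
class AutonomousEventRecord:
    node_id: str
    tag_id: str
    first_datetime: float
    last_datetime: float
    n_messages: int

    def check(self) -> None:
        if self.first_datetime > self.last_datetime:
            raise RecordError("event start must not postdate event end")
        if self.n_messages < 1:
            raise RecordError("event must contain at least one message")


@dataclass
class TrackRecord:
    tag_id: str
    time: float
    latitude: float | None
    longitude: float | None
    easting: float
    northing: float
    elevation: float
    x: float
    y: float
    z: float

    def check(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise RecordError("dam-local coordinates must be finite")


@dataclass
class RouteRecord:
    tag_id: str
    route: str
    subroute: str
    hole: str
    array_name: str

    def check(self) -> None:
        if not dams.valid_route(self.array_name, self.route, self.subroute, self.hole):
            raise RecordError(
                f"invalid route taxonomy {self.route}/{self.subroute}/{self.hole}"
                f" at {self.array_name}"
            )


# ---------------------------------------------------------------------------
# schema registry

@dataclass(frozen=True)
class Column:
    name: str  # printed header
    kind: str  # str | int | float | float? | datetime


@dataclass(frozen=True)
class Schema:
    name: str
    record_cls: type
    columns: tuple[Column, ...]

    def attrs(self) -> list[str]:
        return [f.name for f in dataclasses.fields(self.record_cls)]


_EAST = "Easting_(m; NAD83 - WA South)"
_NORTH = "Northing_(m; NAD83 - WA South)"

SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in (
        Schema(
            "hydrophone_config",
            HydrophoneConfig,
            (
                Column("Sys_#", "int"),
                Column("Sys_Name", "str"),
                Column("Location", "str"),
                Column("Node_Position", "str"),
                Column("Channel", "int"),
                Column("Phone_ID", "int"),
                Column("Pier_ID", "int"),
                Column("Phone_Name", "str"),
                Column("Latitude_(NAD83)", "float"),
                Column("Longitude_(NAD83)", "float"),
                Column(_EAST, "float"),
                Column(_NORTH, "float"),
                Column("Elevation_(m AMSL)", "float"),
                Column("X_(m)", "float"),
                Column("Y_(m)", "float"),
                Column("Z_(m)", "float"),
            ),
        ),
        Schema(
            "autonomous_deployment",
            AutonomousDeployment,
            (
                Column("Node_ID", "str"),
                Column("Node_SN", "str"),
                Column("Latitude_(NAD83)", "float"),
                Column("Longitude_(NAD83)", "float"),
                Column("River Kilometer", "float"),
                Column("Depth_(m)", "float"),
                Column("Deploy_Date", "datetime"),
                Column("Recovery_Date", "datetime"),
                Column("Location_ID", "str"),
                Column("Start_Sample", "datetime"),
                Column("End_Sample", "datetime"),
                Column("Comments", "str"),
            ),
        ),
        Schema(
            "tagged_fish",
            TaggedFish,
            (
                Column("Tag_ID", "str"),
                Column("PIT_ID", "str"),
                Column("Tag_Release_Date", "datetime"),
                Column("PRI", "float"),
                Column("Fish_Tagging_Date", "datetime"),
                Column("Fish_Length_at_Tagging_(mm)", "float"),
                Column("Fish_Weight_at_Tagging_(g)", "float"),
            ),
        ),
        Schema(
            "pit_detections",
            PitDetection,
            (
                Column("Tag_ID", "str"),
                Column("PIT_ID", "str"),
                Column("First_PIT_Datetime", "datetime"),
                Column("Last_PIT_Datetime", "datetime"),
                Column("PIT_Site", "str"),
                Column("PIT_Site_Description", "str"),
                Column("PIT_Site_Basin", "str"),
                Column("PIT_Site_Subbasin", "str"),
                Column("PIT_Site_Type", "str"),
                Column("PIT_Site_Latitude_(NAD83)", "float"),
                Column("PIT_Site_Longitude_(NAD83)", "float"),
                Column("PIT_Site_RKM", "float"),
                Column("Fish_Characteristics_at_Tagging", "str"),
                Column("PIT_Tagging_Date", "datetime"),
                Column("Fish_Length_at_Tagging_(mm)", "float"),
                Column("Fish_Weight_at_Tagging_(g)", "float"),
            ),
        ),
        Schema(
            "cabled_events",
            CabledEventRecord,
            (
                Column("Phone_Name", "str"),
                Column("Tag_ID", "str"),
                Column("Event_ID", "int"),
                Column("First_Computed_Datetime", "datetime"),
                Column("Last_Computed_Datetime", "datetime"),
                Column("Number_Messages", "int"),
            ),
        ),
        Schema(
            "autonomous_events",
            AutonomousEventRecord,
            (
                Column("Node_ID", "str"),
                Column("Tag_ID", "str"),
                Column("First_Computed_Datetime", "datetime"),
                Column("Last_Computed_Datetime", "datetime"),
                Column("Number_Messages", "int"),
            ),
        ),
        Schema(
            "tracks_3d",
            TrackRecord,
            (
                Column("Tag_ID", "str"),
                Column("Time", "datetime"),
                Column("Latitude_(NAD83)", "float?"),
                Column("Longitude_(NAD83)", "float?"),
                Column(_EAST, "float"),
                Column(_NORTH, "float"),
                Column("Elevation_(m AMSL)", "float"),
                Column("X_(m)", "float"),
                Column("Y_(m)", "float"),
                Column("Z_(m)", "float"),
            ),
        ),
        Schema(
            "passage_routes",
            RouteRecord,
            (
                Column("Tag_ID", "str"),
                Column("Route", "str"),
                Column("Subroute", "str"),
                Column("Passage_Hole", "str"),
                Column("Array_Name", "str"),
            ),
        ),
    )
}

#: Every printed data-record filename mapped to its schema.
FILENAME_SCHEMAS: dict[str, str] = {
    "Autonomous_Receiver_Deployment_Data.csv": "autonomous_deployment",
    "LGS_Hydrophone_Configuration.csv": "hydrophone_config",
    "LMN_Hydrophone_Configuration.csv": "hydrophone_config",
    "Tagged_Fish_List.csv": "tagged_fish",
    "PIT_Detection_Data.csv": "pit_detections",
    "LGS_Event_Data.csv": "cabled_events",
    "LMN_Event_Data.csv": "cabled_events",
    "Autonomous_Receiver_Event_Data.csv": "autonomous_events",
    "LGS_3D_Tracks.csv": "tracks_3d",
    "LMN_3D_Tracks.csv": "tracks_3d",
    "LGS_Passage_Routes.csv": "passage_routes",
    "LMN_Passage_Routes.csv": "passage_routes",
}


def schema_for_filename(path: str | Path) -> Schema:
    name = Path(path).name
    try:
        return SCHEMAS[FILENAME_SCHEMAS[name]]
    except KeyError:
        raise SchemaError(f"no schema registered for filename {name!r}") from None


def _normalize(header: str) -> str:
    h = header.strip().lower()
    h = h.replace("–", "-").replace("—", "-")  # en/em dash variants
    h = re.sub(r"[\s_]+", "_", h)
    return h


def _parse_cell(text: str, kind: str, utc_offset_hours: float) -> Any:
    text = text.strip()
    if kind == "str":
        return text
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    if kind == "float?":
        return float(text) if text else None
    if kind == "datetime":
        return parse_datetime(text, utc_offset_hours)
    raise AssertionError(f"unknown column kind {kind}")


def _format_cell(value: Any, kind: str) -> str:
    if kind == "datetime":
        return format_datetime(value)
    if value is None:
        return ""
    if kind == "float" or kind == "float?":
        return repr(float(value))
    return str(value)


def read_table(
    path: str | Path,
    schema_name: str | None = None,
    utc_offset_hours: float = 0.0,
) -> list[Any]:
    """Read a CSV data-record file into a list of typed, validated records.

    ``schema_name`` defaults to the schema registered for the file's name.
    Raises :class:`SchemaError` for a header mismatch (naming the offending
    column) and :class:`RecordError` for an unparseable or invalid row
    (naming the line).
    """
    path = Path(path)
    schema = SCHEMAS[schema_name] if schema_name else schema_for_filename(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    by_norm = {_normalize(c.name): c for c in schema.columns}
    col_map: dict[str, Column] = {}
    for raw in df.columns:
        col = by_norm.get(_normalize(str(raw)))
        if col is None:
            raise SchemaError(f"unexpected column {raw!r} for schema {schema.name!r}")
        col_map[col.name] = raw
    missing = [c.name for c in schema.columns if c.name not in col_map]
    if missing:
        raise SchemaError(f"missing column {missing[0]!r} for schema {schema.name!r}")

    attrs = schema.attrs()
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = dict(zip(df.columns, row))
        kwargs = {}
        for col, attr in zip(schema.columns, attrs):
            raw = values[col_map[col.name]]
            try:
                kwargs[attr] = _parse_cell(str(raw), col.kind, utc_offset_hours)
            except ValueError as exc:
                raise RecordError(
                    f"{path.name} line {i + 2}, column {col.name!r}: {exc}"
                ) from exc
        rec = schema.record_cls(**kwargs)
        try:
            rec.check()
        except RecordError as exc:
            raise RecordError(f"{path.name} line {i + 2}: {exc}") from exc
        records.append(rec)
    return records


def write_table(records: Sequence[Any], path: str | Path, schema_name: str) -> Path:
    """Write validated records as an RFC-4180 CSV with the printed header."""
    schema = SCHEMAS[schema_name]
    attrs = schema.attrs()
    rows = []
    for i, rec in enumerate(records):
        if not isinstance(rec, schema.record_cls):
            raise RecordError(f"record {i} is not a {schema.record_cls.__name__}")
        try:
            rec.check()
        except RecordError as exc:
            raise RecordError(f"record {i}: {exc}") from exc
        rows.append(
            [_format_cell(getattr(rec, a), c.kind) for a, c in zip(attrs, schema.columns)]
        )
    df = pd.DataFrame(rows, columns=[c.name for c in schema.columns])
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\r\n")
    return path
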