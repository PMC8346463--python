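"""TDOA-based 3-D source localization in dam-local coordinates.

A tag transmission received on four or more time-synchronized hydrophones
yields time differences of arrival (TDOA) relative to the earliest receiver.
With hydrophone positions h_i and sound speed c, the source position p is the
minimizer of the hyperbolic residual objective

    sum_i ( dt_i - (||p - h_i|| - ||p - h_ref||) / c )^2 ,

solved here by damped nonlinear least squares started from the best points of
a coarse grid over the search box.  A brute-force lattice oracle over the same
objective is provided for verification.

Sound speed is computed from water temperature with the fifth-order freshwater
polynomial of Marczak (1997), valid on 0-40 degC.

The dam-local frame has X pointing upstream into the forebay, Y parallel to
the dam face, and Z up; :class:`DamFrame` is the rigid transform between that
frame and (easting, northing, elevation), and can be fitted from the dual
coordinates printed in a hydrophone-configuration table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "sound_speed",
    "DamFrame",
    "TdoaSet",
    "LocalizationConfig",
    "LocalizedPoint",
    "message_tdoas",
    "solve_position",
    "grid_oracle",
    "track_tag",
    "GeoAffine",
]

# Marczak (1997) pure-water sound speed coefficients, c in m/s, T in degC.
_MARCZAK = (
    1.402385e3,
    5.038813,
    -5.799136e-2,
    3.287156e-4,
    -1.398845e-6,
    2.787860e-9,
)


def sound_speed(temperature_c: float) -> float:
    """Freshwater sound speed (m/s) at ``temperature_c`` (degC), 0-40 range."""
    t = float(temperature_c)
    if not 0.0 <= t <= 40.0:
        raise ValueError("temperature must be within 0-40 degC")
    return float(sum(a * t**k for k, a in enumerate(_MARCZAK)))


@dataclass(frozen=True)
class DamFrame:
    """Rigid transform between (easting, northing, elevation) and dam-local XYZ.

    ``theta`` is the rotation about the vertical axis taking east/north offsets
    from the origin into local (x, y); elevation maps to z by translation only.
    """

    origin_easting: float
    origin_northing: float
    origin_elevation: float
    theta: float  # radians

    def to_local(self, easting, northing, elevation):
        c, s = math.cos(self.theta), math.sin(self.theta)
        de = np.asarray(easting, dtype=float) - self.origin_easting
        dn = np.asarray(northing, dtype=float) - self.origin_northing
        x = c * de + s * dn
        y = -s * de + c * dn
        z = np.asarray(elevation, dtype=float) - self.origin_elevation
        return x, y, z

    def to_geo(self, x, y, z):
        c, s = math.cos(self.theta), math.sin(self.theta)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        easting = self.origin_easting + c * x - s * y
        northing = self.origin_northing + s * x + c * y
        elevation = np.asarray(z, dtype=float) + self.origin_elevation
        return easting, northing, elevation

    @classmethod
    def fit(
        cls,
        easting: Sequence[float],
        northing: Sequence[float],
        elevation: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        z: Sequence[float],
    ) -> "DamFrame":
        """Least-squares rigid fit from dual coordinates (e.g. a hydrophone
        configuration table that prints both systems)."""
        e = np.asarray(easting, float)
        n = np.asarray(northing, float)
        xl = np.asarray(x, float)
        yl = np.asarray(y, float)
        if e.size < 2:
            raise ValueError("need at least two points to fit a frame")
        ec, nc = e - e.mean(), n - n.mean()
        xc, yc = xl - xl.mean(), yl - yl.mean()
        # 2-D Procrustes rotation: theta maximizing alignment of EN with xy.
        num = float(np.sum(ec * yc - nc * xc))
        den = float(np.sum(ec * xc + nc * yc))
        theta = math.atan2(-num, den)
        c, s = math.cos(theta), math.sin(theta)
        # origin such that forward transform reproduces the local centroid
        oe = e.mean() - (c * xl.mean() - s * yl.mean())
        on = n.mean() - (s * xl.mean() + c * yl.mean())
        oz = float(np.mean(np.asarray(elevation, float) - np.asarray(z, float)))
        return cls(oe, on, oz, theta)


@dataclass(frozen=True)
class GeoAffine:
    """Affine map (easting, northing) -> (longitude, latitude).

    Fitted from control columns of a configuration table; a desk-scale
    stand-in for proper geodesy, adequate over the ~1 km extent of a dam
    forebay.
    """

    coeff_lon: tuple[float, float, float]
    coeff_lat: tuple[float, float, float]

    @classmethod
    def fit(cls, easting, northing, longitude, latitude) -> "GeoAffine":
        e = np.asarray(easting, float)
        n = np.asarray(northing, float)
        if e.size < 3:
            raise ValueError("need at least three control points")
        a = np.column_stack([e, n, np.ones_like(e)])
        lon, *_ = np.linalg.lstsq(a, np.asarray(longitude, float), rcond=None)
        lat, *_ = np.linalg.lstsq(a, np.asarray(latitude, float), rcond=None)
        return cls(tuple(lon), tuple(lat))

    def __call__(self, easting, northing):
        e = np.asarray(easting, float)
        n = np.asarray(northing, float)
        a, b, c0 = self.coeff_lon
        d, f, g = self.coeff_lat
        return a * e + b * n + c0, d * e + f * n + g


@dataclass
class TdoaSet:
    """Arrival-time differences of one message relative to its reference."""

    tag_id: str
    time: float  # earliest (reference) arrival time
    receivers: tuple[str, ...]
    positions: np.ndarray  # (n, 3) dam-local m
    dt: np.ndarray  # (n,) s, dt[ref_index] == 0
    ref_index: int
    feasible: bool = True

    @property
    def n_receivers(self) -> int:
        return len(self.receivers)


@dataclass
class LocalizationConfig:
    """Sound speed, search box and solver settings for position estimation."""

    c: float | None = None
    temperature_c: float = 18.0
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] | None = None
    grid_shape: tuple[int, int, int] = (9, 11, 5)
    n_starts: int = 3
    max_iterations: int = 100
    gtol: float = 1e-14
    max_residual_rms: float | None = None  # s; None = no gate
    coplanarity_tol: float = 0.02

    @property
    def sound_speed(self) -> float:
        return self.c if self.c is not None else sound_speed(self.temperature_c)

    def box_for(self, positions: np.ndarray) -> np.ndarray:
        """Search box: configured bounds, or the receiver hull padded upstream."""
        if self.bounds is not None:
            return np.asarray(self.bounds, dtype=float)
        lo = positions.min(axis=0)
        hi = positions.max(axis=0)
        return np.array(
            [
                [lo[0] - 10.0, hi[0] + 200.0],  # forebay extends upstream in +X
                [lo[1] - 60.0, hi[1] + 60.0],
                [lo[2] - 30.0, hi[2] + 15.0],
            ]
        )


@dataclass
class LocalizedPoint:
    """One solved tag position with solver diagnostics."""

    tag_id: str
    time: float
    x: float
    y: float
    z: float
    residual_rms: float  # s
    n_receivers: int
    converged: bool
    at_bounds: bool = False
    easting: float | None = None
    northing: float | None = None
    elevation: float | None = None

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def message_tdoas(
    message: Any,
    positions: dict[str, Sequence[float]],
    c: float,
    slack_s: float = 1e-3,
) -> TdoaSet | None:
    """Build the TDOA set of a message, or None when it is not localizable.

    The reference receiver is the earliest arrival.  A TDOA whose magnitude
    exceeds the array aperture divided by c (plus ``slack_s``) cannot arise
    from any real source position and marks the set infeasible.
    """
    pairs = [(r, t) for r, t in message.decodes if r in positions]
    if len({r for r, _ in pairs}) < 4:
        return None
    pairs.sort(key=lambda rt: rt[1])
    receivers = tuple(r for r, _ in pairs)
    times = np.array([t for _, t in pairs])
    pos = np.array([positions[r] for r in receivers], dtype=float)
    dt = times - times[0]
    aperture = max(
        float(np.linalg.norm(a - b)) for a in pos for b in pos
    )
    feasible = bool(np.all(np.abs(dt) <= aperture / c + slack_s))
    return TdoaSet(
        tag_id=message.tag_id,
        time=float(times[0]),
        receivers=receivers,
        positions=pos,
        dt=dt,
        ref_index=0,
        feasible=feasible,
    )


def _objective_grid(points: np.ndarray, tdoas: TdoaSet, c: float) -> np.ndarray:
    """Sum-of-squares objective at an (m, 3) array of candidate points."""
    d = np.linalg.norm(points[:, None, :] - tdoas.positions[None, :, :], axis=2)
    pred = (d - d[:, [tdoas.ref_index]]) / c
    resid = tdoas.dt[None, :] - pred
    return np.sum(resid**2, axis=1)


def _check_coplanarity(positions: np.ndarray, tol: float) -> bool:
    centered = positions - positions.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return bool(sv[-1] < tol * sv[0])


def solve_position(tdoas: TdoaSet, config: LocalizationConfig) -> LocalizedPoint:
    """Estimate the source position of one TDOA set.

    Damped Gauss-Newton (scipy ``least_squares``, trust-region reflective with
    the search box as bounds) from the best ``n_starts`` nodes of a coarse
    grid.  Deterministic given inputs.  Near-coplanar receiver geometries
    (all hydrophones close to one plane, as on a single pier line) are allowed
    but trigger a warning: the out-of-plane coordinate is weakly constrained.
    """
    c = config.sound_speed
    if _check_coplanarity(tdoas.positions, config.coplanarity_tol):
        warnings.warn(
            "receiver geometry is near-coplanar; out-of-plane coordinate weakly "
            "constrained",
            stacklevel=2,
        )
    box = config.box_for(tdoas.positions)
    axes = [np.linspace(lo, hi, n) for (lo, hi), n in zip(box, config.grid_shape)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    scores = _objective_grid(grid, tdoas, c)
    # spatially diverse multi-start: greedily take the best nodes that are at
    # least one grid spacing away from the ones already chosen, so all starts
    # cannot collapse into a single (possibly spurious) basin at the box edge
    spacing = max((hi - lo) / max(n - 1, 1) for (lo, hi), n in zip(box, config.grid_shape))
    starts: list[np.ndarray] = []
    for idx in np.argsort(scores):
        node = grid[idx]
        if all(np.linalg.norm(node - s) >= spacing for s in starts):
            starts.append(node)
        if len(starts) >= config.n_starts:
            break

    mask = np.arange(tdoas.n_receivers) != tdoas.ref_index
    h = tdoas.positions
    href = h[tdoas.ref_index]
    dt = tdoas.dt[mask]

    def residuals(p: np.ndarray) -> np.ndarray:
        di = np.linalg.norm(p[None, :] - h[mask], axis=1)
        dref = np.linalg.norm(p - href)
        return dt - (di - dref) / c

    def jac(p: np.ndarray) -> np.ndarray:
        diff_i = p[None, :] - h[mask]
        di = np.linalg.norm(diff_i, axis=1)
        diff_ref = p - href
        dref = np.linalg.norm(diff_ref)
        return -(diff_i / di[:, None] - diff_ref[None, :] / max(dref, 1e-12)) / c

    best = None
    lo, hi = box[:, 0], box[:, 1]
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        sol = least_squares(
            residuals,
            x0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            gtol=config.gtol,
            xtol=1e-12,
            ftol=1e-14,
            max_nfev=config.max_iterations * 3,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    rms = float(np.sqrt(np.mean(best.fun**2)))
    at_bounds = bool(np.any(np.isclose(best.x, lo)) or np.any(np.isclose(best.x, hi)))
    converged = bool(best.success) and tdoas.feasible
    if config.max_residual_rms is not None and rms > config.max_residual_rms:
        converged = False
    return LocalizedPoint(
        tag_id=tdoas.tag_id,
        time=tdoas.time,
        x=float(best.x[0]),
        y=float(best.x[1]),
        z=float(best.x[2]),
        residual_rms=rms,
        n_receivers=tdoas.n_receivers,
        converged=converged,
        at_bounds=at_bounds,
    )


def grid_oracle(
    tdoas: TdoaSet, config: LocalizationConfig, resolution: float
) -> np.ndarray:
    """Exhaustive lattice minimizer of the same objective (verification only)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    box = config.box_for(tdoas.positions)
    axes = [np.arange(lo, hi + resolution / 2, resolution) for lo, hi in box]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    scores = _objective_grid(grid, tdoas, config.sound_speed)
    return grid[int(np.argmin(scores))]


@dataclass
class TrackingResult:
    points: list[LocalizedPoint]
    n_messages: int
    n_attempted: int
    n_failed: int

    @property
    def tracking_count(self) -> int:
        return len(self.points)


def track_tag(
    messages: Iterable[Any],
    positions: dict[str, Sequence[float]],
    config: LocalizationConfig,
    frame: DamFrame | None = None,
    geo: GeoAffine | None = None,
) -> TrackingResult:
    """Localize every >=4-receiver message of one tag, in time order.

    Messages below four receivers are skipped (not attempted); attempted
    solutions that fail to converge are dropped but counted, matching the
    tracking-efficiency accounting (successful locations / transmissions).
    """
    msgs = sorted(messages, key=lambda m: m.time)
    points: list[LocalizedPoint] = []
    n_attempted = 0
    n_failed = 0
    c = config.sound_speed
    for m in msgs:
        tset = message_tdoas(m, positions, c)
        if tset is None:
            continue
        n_attempted += 1
        pt = solve_position(tset, config)
        if not pt.converged:
            n_failed += 1
            continue
        if frame is not None:
            e, n, el = frame.to_geo(pt.x, pt.y, pt.z)
            pt.easting, pt.northing, pt.elevation = float(e), float(n), float(el)
        points.append(pt)
    return TrackingResult(
        points=points, n_messages=len(msgs), n_attempted=n_attempted, n_failed=n_failed
    )
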