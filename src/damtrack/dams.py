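"""Dam geometry: bays, piers, and the passage-route taxonomy.

A run-of-river hydropower dam presents a line of passage openings ("holes"):
powerhouse turbine intakes (T01, T02, ...) and spillway bays (B01, ...), one of
which may host a surface spill weir.  Cabled hydrophones are mounted on the
pier noses between bays, so pier indices anchor the last-detection route
assignment method, while the dam-local Y coordinate (parallel to the dam face)
anchors the 3-D-track method.

Conventions used throughout:

* dam-local frame: X normal to the dam face pointing upstream into the
  forebay, Y parallel to the dam increasing from the first pier, Z normal to
  the water surface (up), dam face at X = 0;
* global bay index ``i`` (1-based from the first pier) is flanked by piers
  ``i`` and ``i + 1``;
* hole labels are numbered within their structure in a per-dam direction
  (e.g. turbines may be numbered south→north at one dam and north→south at
  its neighbor), so label order and physical order need not agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Bay",
    "DamGeometry",
    "ROUTE_TAXONOMY",
    "standard_geometry",
    "valid_route",
]

MAIN_ROUTES = ("powerhouse", "spillway", "dam")
POWERHOUSE_SUBROUTES = ("turbine", "JBS")
SPILLWAY_SUBROUTES = ("regular_spillway", "spillway_weir")


def _holes(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i:02d}" for i in range(1, n + 1))


#: Valid (main route -> subroute -> holes) combinations per studied dam.
#: At LGS the surface weir occupies spillbay B01; at LMN it is B08.  LMN
#: turbines are numbered north-south, LGS turbines south-north; the taxonomy
#: only constrains the label sets, the direction lives in the geometry.
ROUTE_TAXONOMY: dict[str, dict[str, dict[str, tuple[str, ...]]]] = {
    "LGS": {
        "powerhouse": {"turbine": _holes("T", 6), "JBS": _holes("T", 6)},
        "spillway": {"regular_spillway": _holes("B", 7), "spillway_weir": ("B01",)},
        "dam": {"N/A": ("N/A",)},
    },
    "LMN": {
        "powerhouse": {"turbine": _holes("T", 6), "JBS": _holes("T", 6)},
        "spillway": {"regular_spillway": _holes("B", 7), "spillway_weir": ("B08",)},
        "dam": {"N/A": ("N/A",)},
    },
}


def valid_route(array_name: str, route: str, subroute: str, hole: str) -> bool:
    """Check a (route, subroute, hole) triple against the dam's taxonomy.

    Unknown array names are validated structurally only (hole pattern Txx/Bxx
    or N/A), so synthetic dams are not rejected.
    """
    taxonomy = ROUTE_TAXONOMY.get(array_name)
    if taxonomy is None:
        if route == "dam":
            return subroute == "N/A" and hole == "N/A"
        if route == "powerhouse":
            return subroute in POWERHOUSE_SUBROUTES and _hole_ok(hole, "T")
        if route == "spillway":
            return subroute in SPILLWAY_SUBROUTES and _hole_ok(hole, "B")
        return False
    return hole in taxonomy.get(route, {}).get(subroute, ())


def _hole_ok(hole: str, prefix: str) -> bool:
    return len(hole) == 3 and hole.startswith(prefix) and hole[1:].isdigit()


@dataclass(frozen=True)
class Bay:
    """One passage opening with its physical Y-extent in the dam-local frame."""

    hole: str
    index: int  # global bay index; flanked by piers index and index + 1
    y_min: float
    y_max: float

    @property
    def center(self) -> float:
        return 0.5 * (self.y_min + self.y_max)

    @property
    def structure(self) -> str:
        return "powerhouse" if self.hole.startswith("T") else "spillway"


@dataclass(frozen=True)
class DamGeometry:
    name: str
    bays: tuple[Bay, ...]  # ordered by increasing y, contiguous
    weir_bays: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for a, b in zip(self.bays, self.bays[1:]):
            if not (a.y_max <= b.y_min + 1e-9):
                raise ValueError("bay Y-intervals must be disjoint and ordered")
        if {b.index for b in self.bays} != set(range(1, len(self.bays) + 1)):
            raise ValueError("bay indices must be 1..n_bays")

    @property
    def n_piers(self) -> int:
        return len(self.bays) + 1

    @property
    def y_span(self) -> tuple[float, float]:
        return self.bays[0].y_min, self.bays[-1].y_max

    def pier_y(self, pier_id: int) -> float:
        """Y position of a pier nose; pier i is the south edge of bay i."""
        if not 1 <= pier_id <= self.n_piers:
            raise ValueError(f"pier_id must be in [1, {self.n_piers}]")
        if pier_id <= len(self.bays):
            return self.bays[pier_id - 1].y_min
        return self.bays[-1].y_max

    def bay_by_hole(self, hole: str) -> Bay:
        for b in self.bays:
            if b.hole == hole:
                return b
        raise KeyError(hole)

    def bay_for_y(self, y: float) -> Bay | None:
        """Bay whose Y-interval contains y, or None if outside the dam."""
        for b in self.bays:
            if b.y_min <= y < b.y_max:
                return b
        if abs(y - self.bays[-1].y_max) < 1e-9:
            return self.bays[-1]
        return None

    def nearest_bay(self, y: float) -> Bay:
        return min(self.bays, key=lambda b: max(b.y_min - y, y - b.y_max, 0.0))

    def bay_for_pier_average(self, pier_avg: float) -> Bay:
        """Bay corresponding to an averaged pier number.

        Bay i lies between piers i and i+1, so a half-integer average maps
        uniquely (avg 3.5 -> bay 3); an integer average is adjacent to two
        bays and tie-breaks to the lower index (avg 3.0 -> bay 2).
        """
        if float(pier_avg).is_integer():
            idx = int(pier_avg) - 1
        else:
            idx = int(pier_avg)  # floor for positive values
        idx = min(max(idx, 1), len(self.bays))
        return self.bays[idx - 1]

    def main_route_for(self, hole: str) -> tuple[str, str]:
        """(main route, subroute) implied by a hole label, before PIT refinement."""
        bay = self.bay_by_hole(hole)
        if bay.structure == "powerhouse":
            return "powerhouse", "turbine"
        return "spillway", "spillway_weir" if hole in self.weir_bays else "regular_spillway"


def standard_geometry(
    name: str = "SYN",
    n_turbines: int = 6,
    n_spillbays: int = 7,
    turbine_width: float = 26.0,
    spillbay_width: float = 18.0,
    turbine_numbering: str = "south-north",
    spillbay_numbering: str = "south-north",
    weir_bays: Iterable[str] = ("B01",),
    powerhouse_first: bool = True,
) -> DamGeometry:
    """Build a contiguous powerhouse + spillway dam along increasing Y.

    Y increases to the north; with ``powerhouse_first`` the turbine section
    starts at Y = 0 on the south side.  ``*_numbering`` controls whether hole
    labels increase with Y ("south-north") or against it ("north-south").
    """
    sections = [("T", n_turbines, turbine_width, turbine_numbering),
                ("B", n_spillbays, spillbay_width, spillbay_numbering)]
    if not powerhouse_first:
        sections.reverse()
    bays: list[Bay] = []
    y = 0.0
    index = 1
    for prefix, n, width, numbering in sections:
        for k in range(n):
            label_num = k + 1 if numbering == "south-north" else n - k
            bays.append(Bay(f"{prefix}{label_num:02d}", index, y, y + width))
            y += width
            index += 1
    return DamGeometry(name=name, bays=tuple(bays), weir_bays=frozenset(weir_bays))
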