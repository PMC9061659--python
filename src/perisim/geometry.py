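"""Perimetric test grids: construction, eye transposition, matching, sectors.

All coordinates are degrees of visual angle in right-eye format:
positive x = temporal field, positive y = superior field.  Grid locations sit
on odd multiples of 3 deg (6 deg square spacing offset from the axes).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "GridPoint",
    "TestGrid",
    "SectorMap",
    "SECTOR_LABELS",
    "DEFAULT_SEEDS",
    "build_grid",
    "transpose_to_right_eye",
    "match_locations",
    "assign_sectors",
    "sector_of",
    "eccentricity",
    "grid_to_csv",
]


class GridPoint(NamedTuple):
    """A stimulus location in degrees, right-eye format."""

    x: int
    y: int


#: Radial cutoff (deg^2) reproducing the canonical 76-point central-30-deg
#: layout from the 6-deg lattice of odd multiples of 3.
_RADIUS_SQ = 841

#: Blind-spot pair in right-eye format (temporal field, straddling the
#: horizontal midline at 15 deg eccentricity).
BLIND_SPOT_POINTS = (GridPoint(15, 3), GridPoint(15, -3))

_GRID_NAMES = ("30-2", "SPARK66")


@dataclass(frozen=True)
class TestGrid:
    """Named, ordered set of stimulus locations."""

    name: str
    points: tuple[GridPoint, ...]
    blind_spot_points: frozenset[GridPoint] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.points)) != len(self.points):
            raise ValueError(f"grid {self.name!r} contains duplicate points")
        if not self.blind_spot_points <= set(self.points):
            raise ValueError("blind-spot points must be members of the grid")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def index_of(self, point: GridPoint) -> int:
        return self.points.index(GridPoint(*point))

    def __contains__(self, point) -> bool:
        return GridPoint(*point) in set(self.points)


def eccentricity(point: GridPoint) -> float:
    """Euclidean distance from fixation in degrees."""
    return float((point.x**2 + point.y**2) ** 0.5)


def _lattice() -> list[GridPoint]:
    coords = [-27, -21, -15, -9, -3, 3, 9, 15, 21, 27]
    # Row-major, superior to inferior, nasal to temporal: stable ordering.
    return [
        GridPoint(x, y)
        for y in sorted(coords, reverse=True)
        for x in coords
        if x * x + y * y <= _RADIUS_SQ
    ]


def build_grid(pattern: str) -> TestGrid:
    """Construct a canonical test grid.

    ``"30-2"`` is the 76-point central-30-deg pattern; ``"SPARK66"`` is the
    66-point subset with the uppermost/bottommost rows (y = +/-27) and the
    blind-spot pair removed.
    """
    if pattern not in _GRID_NAMES:
        raise ValueError(
            f"unknown grid pattern {pattern!r}; valid names: {list(_GRID_NAMES)}"
        )
    full = _lattice()
    if pattern == "30-2":
        return TestGrid("30-2", tuple(full), frozenset(BLIND_SPOT_POINTS))
    pts = tuple(
        p for p in full if abs(p.y) != 27 and p not in BLIND_SPOT_POINTS
    )
    return TestGrid("SPARK66", pts, frozenset())


def transpose_to_right_eye(
    points: Iterable[GridPoint], eye: str
) -> list[GridPoint]:
    """Mirror left-eye locations into right-eye format (x -> -x)."""
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    pts = [GridPoint(*p) for p in points]
    if eye == "right":
        return pts
    return [GridPoint(-p.x, p.y) for p in pts]


def match_locations(a: TestGrid, b: TestGrid) -> list[tuple[int, int]]:
    """Index pairs (i, j) of coincident locations, ordered by grid ``a``."""
    where_b = {p: j for j, p in enumerate(b.points)}
    return [
        (i, where_b[p]) for i, p in enumerate(a.points) if p in where_b
    ]


# --- sectors ---------------------------------------------------------------

SECTOR_LABELS = (
    "central",
    "temporal",
    "superior_arcuate",
    "inferior_arcuate",
    "superior_nasal",
    "inferior_nasal",
)

#: Default phase-1 seed per sector (right-eye format).  The arcuate seeds sit
#: above/below the blind-spot region, the nasal seeds above/below the nasal
#: horizontal midline, plus one central (<10 deg) and one temporal point.
DEFAULT_SEEDS: dict[str, GridPoint] = {
    "central": GridPoint(3, 3),
    "temporal": GridPoint(27, -3),
    "superior_arcuate": GridPoint(15, 15),
    "inferior_arcuate": GridPoint(15, -9),
    "superior_nasal": GridPoint(-15, 15),
    "inferior_nasal": GridPoint(-15, -9),
}


def sector_of(point: GridPoint) -> str:
    """Bundle-sector label for any lattice point.

    Angular partition in the spirit of nerve-fibre-bundle maps: a central
    region below 10 deg eccentricity, a temporal wedge, and arcuate/nasal
    sectors split at the horizontal midline (no sector crosses the nasal
    midline outside the central region).
    """
    x, y = point
    if x * x + y * y < 100:
        return "central"
    if x >= 21:
        return "temporal"
    if x > 0:
        return "superior_arcuate" if y > 0 else "inferior_arcuate"
    return "superior_nasal" if y > 0 else "inferior_nasal"


@dataclass(frozen=True)
class SectorMap:
    """Partition of a grid into functional sectors with one seed each."""

    grid: TestGrid
    sectors: dict[GridPoint, str]
    seed_points: dict[str, GridPoint]

    def seeds(self) -> list[GridPoint]:
        return [self.seed_points[label] for label in SECTOR_LABELS]

    def members(self, label: str) -> list[GridPoint]:
        if label not in SECTOR_LABELS:
            raise ValueError(
                f"unknown sector {label!r}; valid: {list(SECTOR_LABELS)}"
            )
        return [p for p in self.grid.points if self.sectors[p] == label]


def assign_sectors(
    grid: TestGrid,
    n_regions: int = 6,
    seeds: dict[str, GridPoint] | None = None,
) -> SectorMap:
    """Partition the SPARK66 grid into functional sectors with seed points."""
    if n_regions != 6:
        raise ValueError(f"only 6 regions are supported, got {n_regions}")
    if grid.name != "SPARK66":
        raise ValueError("sector assignment is defined for the SPARK66 grid")
    seeds = dict(DEFAULT_SEEDS if seeds is None else seeds)
    if set(seeds) != set(SECTOR_LABELS):
        raise ValueError(f"seeds must cover sectors {list(SECTOR_LABELS)}")
    mapping = {p: sector_of(p) for p in grid.points}
    for label, seed in seeds.items():
        if seed not in grid:
            raise ValueError(f"seed {tuple(seed)} is not a grid member")
        if mapping[GridPoint(*seed)] != label:
            raise ValueError(
                f"seed {tuple(seed)} lies in sector "
                f"{mapping[GridPoint(*seed)]!r}, not {label!r}"
            )
    return SectorMap(grid, mapping, {k: GridPoint(*v) for k, v in seeds.items()})


def grid_to_csv(grid: TestGrid, path, sector_map: SectorMap | None = None) -> None:
    """Serialize a grid as CSV (index, x_deg, y_deg, is_blind_spot, sector)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "x_deg", "y_deg", "is_blind_spot", "sector"])
        for i, p in enumerate(grid.points):
            sec = sector_map.sectors[p] if sector_map is not None else ""
            w.writerow([i, p.x, p.y, int(p in grid.blind_spot_points), sec])
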