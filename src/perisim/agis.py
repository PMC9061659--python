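"""AGIS-style visual-field severity score (0-20) and categories.

The score is assembled from a total-deviation map: a nasal contribution
(0-2) from contiguous depressed locations in the nasal area, and superior
and inferior hemifield contributions (0-9 each) from clusters of at least
three adjacent depressed locations, graded by how many in-cluster locations
meet progressively deeper criteria.  Every numeric criterion lives in a
single editable table (:data:`DEFAULT_CRITERIA`) so any edition difference
is a one-place fix.  Scores map to the categories none (0), mild (1-5),
moderate (6-11), severe (12-17) and end-stage (18-20).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from perisim.geometry import GridPoint, TestGrid

__all__ = [
    "AGISResult",
    "DEFAULT_CRITERIA",
    "agis_score",
    "agis_category",
    "depression_threshold",
    "load_criteria",
    "save_criteria",
]

CATEGORIES = (
    (0, 0, "none"),
    (1, 5, "mild"),
    (6, 11, "moderate"),
    (12, 17, "severe"),
    (18, 20, "end-stage"),
)


def depression_threshold(x: int, y: int) -> float:
    """Minimum TD depression (dB) for a location to count as depressed.

    Deeper criteria with eccentricity, slightly stricter superiorly, in the
    spirit of location-dependent defect thresholds.
    """
    ecc2 = x * x + y * y
    if ecc2 <= 15**2 + 3**2:
        base = 5.0
    elif ecc2 <= 21**2 + 9**2:
        base = 6.0
    else:
        base = 8.0
    if y > 0 and ecc2 > 15**2 + 3**2:
        base += 1.0
    return base


#: Right-eye-format nasal-area sites (three per hemifield at the nasal edge).
_NASAL_SITES = (
    (-27, 3), (-21, 3), (-21, 9),
    (-27, -3), (-21, -3), (-21, -9),
)

DEFAULT_CRITERIA: dict = {
    "version": 1,
    "nasal_sites": [list(p) for p in _NASAL_SITES],
    "nasal_cluster_min": 3,
    "total_nasal_depth_db": 12.0,
    "hemifield_cluster_min": 3,
    # +1 hemifield point per count threshold reached by in-cluster sites.
    "count_thresholds": [6, 12, 18],
    # +1 hemifield point per depth level with >= depth_min_sites in-cluster
    # sites depressed at least that much.
    "depth_levels_db": [12.0, 16.0, 20.0, 24.0, 28.0],
    "depth_min_sites": 3,
    "max_nasal": 2,
    "max_hemifield": 9,
}


def load_criteria(path) -> dict:
    with open(path) as fh:
        crit = json.load(fh)
    missing = set(DEFAULT_CRITERIA) - set(crit)
    if missing:
        raise ValueError(f"criteria table missing keys: {sorted(missing)}")
    return crit


def save_criteria(criteria: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(criteria, fh, indent=1)


@dataclass(frozen=True)
class AGISResult:
    """Severity score with its per-region breakdown."""

    score: int
    category: str
    nasal: int
    superior: int
    inferior: int
    depressed: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "category": self.category,
            "nasal": self.nasal,
            "superior": self.superior,
            "inferior": self.inferior,
        }


def agis_category(score: int) -> str:
    """Category label for a score, per the published 0-20 boundaries."""
    if not 0 <= score <= 20:
        raise ValueError(f"score must lie in [0, 20], got {score}")
    for lo, hi, label in CATEGORIES:
        if lo <= score <= hi:
            return label
    raise AssertionError("unreachable")


def _clusters(points: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Connected components under 6-degree orthogonal adjacency."""
    remaining = set(points)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x, y = frontier.pop()
            for dx, dy in ((6, 0), (-6, 0), (0, 6), (0, -6)):
                q = (x + dx, y + dy)
                if q in remaining:
                    remaining.remove(q)
                    comp.add(q)
                    frontier.append(q)
        comps.append(comp)
    return comps


def _hemifield_score(
    td: Mapping[tuple[int, int], float],
    sites: list[tuple[int, int]],
    criteria: dict,
) -> int:
    depressed = {
        p for p in sites if td[p] <= -depression_threshold(*p)
    }
    cluster_min = criteria["hemifield_cluster_min"]
    in_cluster = set().union(
        *[c for c in _clusters(depressed) if len(c) >= cluster_min], set()
    )
    if not in_cluster:
        return 0
    score = 1
    n = len(in_cluster)
    for t in criteria["count_thresholds"]:
        if n >= t:
            score += 1
    for d in criteria["depth_levels_db"]:
        deep = sum(1 for p in in_cluster if td[p] <= -d)
        if deep >= criteria["depth_min_sites"]:
            score += 1
    return min(score, criteria["max_hemifield"])


def agis_score(
    td_map: Mapping[tuple[int, int], float] | np.ndarray,
    grid: TestGrid | None = None,
    criteria: dict | None = None,
) -> AGISResult:
    """Score a total-deviation map.

    ``td_map`` is either a mapping from (x, y) to TD in dB, or an array
    aligned with ``grid``.  All nasal-area sites must be present; the
    hemifield contributions use whatever non-nasal locations are available
    (the matched 66-point subset by default in the pipeline).
    """
    criteria = DEFAULT_CRITERIA if criteria is None else criteria
    if not isinstance(td_map, Mapping):
        if grid is None:
            raise ValueError("grid is required when td_map is an array")
        vals = np.asarray(td_map, dtype=float)
        if vals.shape != (len(grid),):
            raise ValueError("td_map length does not match grid")
        td = {(p.x, p.y): float(v) for p, v in zip(grid.points, vals)}
    else:
        td = {(int(x), int(y)): float(v) for (x, y), v in td_map.items()}

    nasal_sites = [tuple(p) for p in criteria["nasal_sites"]]
    missing = [p for p in nasal_sites if p not in td]
    if missing:
        raise ValueError(
            f"insufficient grid coverage; missing nasal sites: {missing}"
        )

    # Nasal contribution: contiguous depressed run, plus one for a total
    # nasal defect (all sites depressed to the deep criterion).
    nasal_depressed = {
        p for p in nasal_sites if td[p] <= -depression_threshold(*p)
    }
    nasal = 0
    if any(
        len(c) >= criteria["nasal_cluster_min"]
        for c in _clusters(nasal_depressed)
    ):
        nasal = 1
        if all(
            td[p] <= -criteria["total_nasal_depth_db"] for p in nasal_sites
        ):
            nasal = 2
    nasal = min(nasal, criteria["max_nasal"])

    nasal_set = set(nasal_sites)
    superior_sites = [p for p in td if p[1] > 0 and p not in nasal_set]
    inferior_sites = [p for p in td if p[1] < 0 and p not in nasal_set]
    superior = _hemifield_score(td, superior_sites, criteria)
    inferior = _hemifield_score(td, inferior_sites, criteria)

    score = nasal + superior + inferior
    return AGISResult(
        score=score,
        category=agis_category(score),
        nasal=nasal,
        superior=superior,
        inferior=inferior,
        depressed={
            "nasal": sorted(nasal_depressed),
        },
    )
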