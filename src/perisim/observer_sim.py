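"""Synthetic observers: ground-truth sensitivity surfaces and responses.

Ground truth is always stored on the k = 40 reference dB scale; instrument
scaling and range clipping happen only at measurement time.  A normal field
is a hill of vision (peak at fixation, linear eccentric decay, age decline)
plus spatially correlated noise; glaucoma-like observers carry focal loss
confined to nerve-fibre-bundle sectors, cataract-like observers a uniform
diffuse depression.  Responses follow a frequency-of-seeing model: a
cumulative-Gaussian psychometric function with sensitivity-dependent spread,
lapses (false negatives) and guesses (false positives).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from perisim.geometry import (
    GridPoint,
    SECTOR_LABELS,
    TestGrid,
    build_grid,
    eccentricity,
    sector_of,
)

__all__ = [
    "REFERENCE_K",
    "TrueField",
    "ResponseParams",
    "HillParams",
    "Observer",
    "CohortConfig",
    "normal_field",
    "add_focal_defect",
    "add_diffuse_loss",
    "p_seen",
    "respond",
    "simulate_cohort",
    "observer_to_dict",
    "observer_from_dict",
    "save_cohort",
    "load_cohort",
]

#: dB constant of the reference scale on which ground truth is stored.
REFERENCE_K = 40.0


@dataclass(frozen=True)
class TrueField:
    """Per-location true sensitivity in dB on the reference (k=40) scale."""

    grid: TestGrid
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.sensitivity, dtype=float)
        object.__setattr__(self, "sensitivity", arr)
        if arr.shape != (len(self.grid),):
            raise ValueError(
                f"sensitivity length {arr.shape} does not match grid "
                f"size {len(self.grid)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("sensitivities must be finite")


@dataclass(frozen=True)
class ResponseParams:
    """Psychometric response parameters.

    The spread of the frequency-of-seeing curve grows as sensitivity falls:
    ``sigma(S) = clamp(exp(slope_a - slope_b * S), sigma_min, sigma_max)``.
    """

    slope_a: float = 3.27
    slope_b: float = 0.081
    fp_rate: float = 0.03
    fn_rate: float = 0.03
    fl_rate: float = 0.05
    sigma_min: float = 1.0
    sigma_max: float = 6.0

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate", "fl_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")

    def sigma(self, sensitivity: float) -> float:
        raw = math.exp(self.slope_a - self.slope_b * sensitivity)
        return min(max(raw, self.sigma_min), self.sigma_max)


@dataclass(frozen=True)
class HillParams:
    """Hill-of-vision model: S0 - g*ecc - a*max(0, age-20) + noise."""

    s0: float = 34.0
    ecc_slope: float = 0.25
    age_slope: float = 0.065
    region_sd: float = 0.8
    white_sd: float = 1.0

    def expected(self, point: GridPoint, age: float) -> float:
        return (
            self.s0
            - self.ecc_slope * eccentricity(point)
            - self.age_slope * max(0.0, age - 20.0)
        )


@dataclass
class Observer:
    """A synthetic subject: ground truth plus response behaviour."""

    uid: str
    group: str
    age: float
    true_field: TrueField
    params: ResponseParams = field(default_factory=ResponseParams)
    meta: dict = field(default_factory=dict)

    @property
    def grid(self) -> TestGrid:
        return self.true_field.grid

    def sensitivity_at(self, index: int) -> float:
        return float(self.true_field.sensitivity[index])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def normal_field(
    grid: TestGrid,
    age: float,
    seed,
    hill: HillParams | None = None,
) -> TrueField:
    """Sample a normal observer's true field (deterministic given seed)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    hill = hill or HillParams()
    rng = _as_rng(seed)
    # Correlated component: one offset per field quadrant, shared by all
    # points in it, so that normal fields have nonzero pattern deviation.
    quad_offsets = rng.normal(0.0, hill.region_sd, size=4)
    white = rng.normal(0.0, hill.white_sd, size=len(grid))
    vals = np.empty(len(grid))
    for i, p in enumerate(grid.points):
        quad = (0 if p.x > 0 else 1) + (0 if p.y > 0 else 2)
        vals[i] = hill.expected(p, age) + quad_offsets[quad] + white[i]
    return TrueField(grid, vals)


def _defect_weights(
    grid: TestGrid, sectors: Sequence[str], edge_sd: float
) -> np.ndarray:
    """Spatial weights: 1 inside the target sectors, Gaussian falloff outside.

    The falloff never crosses the nasal horizontal midline: for a nasal point
    outside the target sectors, in-sector points in the opposite nasal
    hemifield do not contribute.
    """
    for s in sectors:
        if s not in SECTOR_LABELS:
            raise ValueError(
                f"unknown sector {s!r}; valid: {list(SECTOR_LABELS)}"
            )
    target = set(sectors)
    in_sector = [sector_of(p) in target for p in grid.points]
    weights = np.zeros(len(grid))
    for i, p in enumerate(grid.points):
        if in_sector[i]:
            weights[i] = 1.0
            continue
        if edge_sd <= 0:
            continue
        d2 = math.inf
        for j, q in enumerate(grid.points):
            if not in_sector[j]:
                continue
            if p.x < 0 and q.x < 0 and (p.y > 0) != (q.y > 0):
                continue  # no bleed across the nasal midline
            d2 = min(d2, (p.x - q.x) ** 2 + (p.y - q.y) ** 2)
        if math.isfinite(d2):
            weights[i] = math.exp(-d2 / (2.0 * edge_sd**2))
    return weights


def add_focal_defect(
    fld: TrueField,
    sectors: Sequence[str] | str,
    depth: float,
    edge_sd: float = 2.0,
    seed=None,
) -> TrueField:
    """Subtract a focal defect confined to bundle sectors.

    ``depth`` dB is removed inside the named sectors (with mild per-point
    jitter when a seed is given) and decays smoothly just outside them.
    Sensitivity never increases; values may go below 0 dB.
    """
    if depth < 0:
        raise ValueError("defect depth must be non-negative")
    if isinstance(sectors, str):
        sectors = [sectors]
    w = _defect_weights(fld.grid, sectors, edge_sd)
    reduction = depth * w
    if seed is not None and depth > 0:
        rng = _as_rng(seed)
        jitter = rng.normal(0.0, 1.0, size=len(w)) * (w > 0)
        reduction = np.clip(reduction + jitter, 0.0, None)
    return TrueField(fld.grid, fld.sensitivity - reduction)


def add_diffuse_loss(fld: TrueField, loss: float) -> TrueField:
    """Uniform depression at every location (cataract-like)."""
    if loss < 0:
        raise ValueError("diffuse loss must be non-negative")
    return TrueField(fld.grid, fld.sensitivity - loss)


def p_seen(
    stimulus_db: float, true_sensitivity: float, params: ResponseParams
) -> float:
    """Probability that a stimulus (reference-scale dB) is reported seen."""
    sigma = params.sigma(true_sensitivity)
    z = (true_sensitivity - stimulus_db) / sigma
    phi = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return params.fp_rate + (1.0 - params.fp_rate - params.fn_rate) * phi


def respond(
    stimulus_db: float,
    index: int,
    observer: Observer,
    rng: np.random.Generator,
) -> bool:
    """Single Bernoulli response at a grid location."""
    if not 0 <= index < len(observer.grid):
        raise IndexError(
            f"location index {index} outside grid of size {len(observer.grid)}"
        )
    p = p_seen(stimulus_db, observer.sensitivity_at(index), observer.params)
    return bool(rng.random() < p)


# --- cohorts ---------------------------------------------------------------

# Sectors eligible for focal loss (glaucomatous bundle defects).
_DEFECT_SECTORS = (
    "superior_arcuate",
    "inferior_arcuate",
    "superior_nasal",
    "inferior_nasal",
)


@dataclass(frozen=True)
class CohortConfig:
    """Sampling recipe for a group of synthetic observers."""

    group: str
    n_subjects: int
    seed: int
    grid_name: str = "30-2"
    age_mean: float = 55.0
    age_sd: float = 12.0
    # glaucoma-like settings
    n_defects_probs: tuple[float, ...] = (0.25, 0.30, 0.25, 0.20)
    depth_range: tuple[float, float] = (6.0, 34.0)
    edge_sd: float = 2.0
    # cataract-like settings
    diffuse_range: tuple[float, float] = (1.0, 8.0)
    params: ResponseParams = field(default_factory=ResponseParams)

    def __post_init__(self) -> None:
        if self.group not in ("glaucoma", "cataract", "normal"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if abs(sum(self.n_defects_probs) - 1.0) > 1e-9:
            raise ValueError("n_defects_probs must sum to 1")
        lo, hi = self.depth_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid depth_range")
        lo, hi = self.diffuse_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid diffuse_range")


def simulate_cohort(config: CohortConfig) -> list[Observer]:
    """Sample a reproducible cohort of observers."""
    grid = build_grid(config.grid_name)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    observers = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        age = float(
            np.clip(rng.normal(config.age_mean, config.age_sd), 20.0, 90.0)
        )
        fld = normal_field(grid, age, rng)
        meta: dict = {"seed_entropy": int(ss.entropy) % (2**63)}
        if config.group == "glaucoma":
            n_def = int(
                rng.choice(len(config.n_defects_probs), p=config.n_defects_probs)
            )
            sectors = list(
                rng.choice(_DEFECT_SECTORS, size=n_def, replace=False)
            )
            depths = []
            for s in sectors:
                depth = float(rng.uniform(*config.depth_range))
                fld = add_focal_defect(fld, s, depth, config.edge_sd, rng)
                depths.append(depth)
            meta.update(defect_sectors=sectors, defect_depths=depths)
        elif config.group == "cataract":
            loss = float(rng.uniform(*config.diffuse_range))
            fld = add_diffuse_loss(fld, loss)
            meta.update(diffuse_loss=loss)
        observers.append(
            Observer(
                uid=f"{config.group}-{i:03d}",
                group=config.group,
                age=age,
                true_field=fld,
                params=config.params,
                meta=meta,
            )
        )
    return observers


# --- serialization ---------------------------------------------------------

_SCHEMA_VERSION = 1


def observer_to_dict(obs: Observer) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "uid": obs.uid,
        "group": obs.group,
        "age": obs.age,
        "grid": obs.grid.name,
        "sensitivity": [float(v) for v in obs.true_field.sensitivity],
        "params": asdict(obs.params),
        "meta": obs.meta,
    }


def observer_from_dict(d: dict) -> Observer:
    grid = build_grid(d["grid"])
    return Observer(
        uid=d["uid"],
        group=d["group"],
        age=float(d["age"]),
        true_field=TrueField(grid, np.asarray(d["sensitivity"], dtype=float)),
        params=ResponseParams(**d["params"]),
        meta=dict(d.get("meta", {})),
    )


def save_cohort(observers: Sequence[Observer], path) -> None:
    with open(path, "w") as fh:
        json.dump([observer_to_dict(o) for o in observers], fh, indent=1)


def load_cohort(path) -> list[Observer]:
    with open(path) as fh:
        return [observer_from_dict(d) for d in json.load(fh)]
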