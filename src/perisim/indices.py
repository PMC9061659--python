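"""Normative databases and global indices (MS, TD, PD, MD, PSD, NAPDP).

A normative database is built by simulating normal observers and measuring
them with the same strategy/instrument pairing the database will later
correct for, so strategy bias cancels out of the deviation maps.  Total
deviation is measured minus age-corrected normal; pattern deviation
additionally removes the general-height component (a high percentile of the
TD distribution), so diffuse loss drops out of PD while focal loss remains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from perisim.geometry import TestGrid, build_grid
from perisim.observer_sim import (
    Observer,
    ResponseParams,
    normal_field,
)
from perisim.scales import InstrumentModel

__all__ = [
    "NormativeDB",
    "GlobalIndices",
    "build_normative_db",
    "mean_sensitivity",
    "total_deviation",
    "pattern_deviation",
    "mean_deviation",
    "psd",
    "napdp",
    "compute_global_indices",
]

#: TD/PD flag levels stored in a database, most to least lenient.
FLAG_LEVELS = (0.05, 0.02, 0.01, 0.005)

_DEFAULT_GH_PERCENTILE = 85.0


@dataclass
class NormativeDB:
    """Per-location normal statistics and empirical deviation cut-offs."""

    grid: TestGrid
    strategy: str
    instrument: str
    mean: np.ndarray
    sd: np.ndarray
    td_cutoffs: dict[float, np.ndarray]
    pd_cutoffs: dict[float, np.ndarray]
    gh_percentile: float
    age_mean: float
    age_slope: float
    n: int
    seed: int

    def normal_for_age(self, age: float) -> np.ndarray:
        return self.mean - self.age_slope * (age - self.age_mean)

    def subset(self, indices) -> "NormativeDB":
        """Project the database onto a sub-grid (matched-location analysis)."""
        idx = list(indices)
        sub_points = tuple(self.grid.points[i] for i in idx)
        sub_grid = TestGrid(
            f"{self.grid.name}[{len(idx)}]",
            sub_points,
            frozenset(p for p in self.grid.blind_spot_points if p in sub_points),
        )
        return NormativeDB(
            grid=sub_grid,
            strategy=self.strategy,
            instrument=self.instrument,
            mean=self.mean[idx],
            sd=self.sd[idx],
            td_cutoffs={k: v[idx] for k, v in self.td_cutoffs.items()},
            pd_cutoffs={k: v[idx] for k, v in self.pd_cutoffs.items()},
            gh_percentile=self.gh_percentile,
            age_mean=self.age_mean,
            age_slope=self.age_slope,
            n=self.n,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.name,
            "strategy": self.strategy,
            "instrument": self.instrument,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "td_cutoffs": {str(k): v.tolist() for k, v in self.td_cutoffs.items()},
            "pd_cutoffs": {str(k): v.tolist() for k, v in self.pd_cutoffs.items()},
            "gh_percentile": self.gh_percentile,
            "age_mean": self.age_mean,
            "age_slope": self.age_slope,
            "provenance": {"n": self.n, "seed": self.seed},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class GlobalIndices:
    """Summary indices of a single measured field."""

    ms: float
    md: float
    psd: float
    napdp: int


def build_normative_db(
    n: int,
    age_range: tuple[float, float],
    seed: int,
    strategy: str,
    instrument: InstrumentModel,
    grid: TestGrid | None = None,
    regression_model=None,
    gh_percentile: float = _DEFAULT_GH_PERCENTILE,
) -> NormativeDB:
    """Simulate ``n`` normal observers, measure them, and tabulate statistics.

    ``strategy`` is ``"staircase42"`` (any grid) or ``"spark4"`` (the
    66-point grid).  Empirical percentile cut-offs finer than 1/n fall back
    to the most extreme attainable quantile with a warning.
    """
    from perisim import strategies  # local import to avoid a cycle

    if n < 50:
        raise ValueError(f"at least 50 normals are required, got {n}")
    if grid is None:
        grid = build_grid("30-2" if strategy == "staircase42" else "SPARK66")
    rng_master = np.random.SeedSequence(seed)
    age_lo, age_hi = age_range
    ages = np.empty(n)
    thresholds = np.empty((n, len(grid)))
    params = ResponseParams()
    for i, ss in enumerate(rng_master.spawn(n)):
        rng = np.random.default_rng(ss)
        ages[i] = rng.uniform(age_lo, age_hi)
        obs = Observer(
            uid=f"norm-{i:03d}",
            group="normal",
            age=float(ages[i]),
            true_field=normal_field(grid, float(ages[i]), rng),
            params=params,
        )
        if strategy == "staircase42":
            out = strategies.staircase_42(obs, grid, instrument, rng)
        elif strategy == "spark4":
            sm = strategies.assign_sectors(grid)
            out = strategies.run_spark(
                obs, instrument, rng, regression_model=regression_model,
                sector_map=sm,
            )
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        thresholds[i] = out.thresholds

    age_mean = float(np.mean(ages))
    # Per-location age slope pooled across locations for stability.
    centred = ages - age_mean
    denom = float(np.sum(centred**2))
    slopes = (centred @ (np.mean(thresholds, axis=1))) / denom if denom else 0.0
    age_slope = float(max(-slopes, 0.0))

    norm_mean = np.mean(thresholds, axis=0)
    norm_sd = np.std(thresholds, axis=0, ddof=1)
    # Age-correct each subject's thresholds to the cohort mean age.
    corrected = thresholds + age_slope * (ages - age_mean)[:, None]
    td = corrected - np.mean(corrected, axis=0)
    gh = np.percentile(td, gh_percentile, axis=1)
    pd_ = td - gh[:, None]

    def _cutoffs(mat: np.ndarray) -> dict[float, np.ndarray]:
        out: dict[float, np.ndarray] = {}
        for level in FLAG_LEVELS:
            q = level
            if n * level < 1.0:
                q = 1.0 / n
                warnings.warn(
                    f"n={n} too small for the {level:.1%} cut-off; using the "
                    f"{q:.1%} empirical quantile instead",
                    stacklevel=3,
                )
            out[level] = np.quantile(mat, q, axis=0)
        return out

    return NormativeDB(
        grid=grid,
        strategy=strategy,
        instrument=instrument.name,
        mean=norm_mean,
        sd=norm_sd,
        td_cutoffs=_cutoffs(td),
        pd_cutoffs=_cutoffs(pd_),
        gh_percentile=gh_percentile,
        age_mean=age_mean,
        age_slope=age_slope,
        n=n,
        seed=seed,
    )


def _included(values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    vals = np.asarray(values, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("no included locations")
    return vals


def mean_sensitivity(values, mask=None) -> float:
    """Arithmetic mean threshold over included locations."""
    return float(np.mean(_included(values, mask)))


def total_deviation(values, db: NormativeDB, age: float) -> np.ndarray:
    """Measured minus age-corrected normative mean, per location."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != db.mean.shape:
        raise ValueError(
            f"field size {vals.shape} does not match database grid "
            f"{db.mean.shape}"
        )
    return vals - db.normal_for_age(age)


def pattern_deviation(td, db: NormativeDB | None = None,
                      gh_percentile: float | None = None) -> np.ndarray:
    """TD with the general-height component removed."""
    td = np.asarray(td, dtype=float)
    pct = (
        gh_percentile
        if gh_percentile is not None
        else (db.gh_percentile if db is not None else _DEFAULT_GH_PERCENTILE)
    )
    return td - np.percentile(td, pct)


def mean_deviation(td, mask=None) -> float:
    """Unweighted mean of total deviation."""
    return float(np.mean(_included(td, mask)))


def psd(td, md: float | None = None, mask=None) -> float:
    """Root-mean-square spread of TD around MD."""
    vals = _included(td, mask)
    if md is None:
        md = float(np.mean(vals))
    return float(np.sqrt(np.mean((vals - md) ** 2)))


def napdp(pd_values, db: NormativeDB, mask=None, level: float = 0.05) -> int:
    """Number of abnormal pattern-deviation points at the given level."""
    pd_values = np.asarray(pd_values, dtype=float)
    cut = db.pd_cutoffs[level]
    flags = pd_values < cut
    if mask is not None:
        flags = flags & np.asarray(mask, dtype=bool)
    return int(np.sum(flags))


def compute_global_indices(
    values, db: NormativeDB, age: float, mask=None
) -> GlobalIndices:
    """MS, MD, PSD and NAPDP for one measured field."""
    td = total_deviation(values, db, age)
    pd_ = pattern_deviation(td, db)
    md = mean_deviation(td, mask)
    return GlobalIndices(
        ms=mean_sensitivity(values, mask),
        md=md,
        psd=psd(td, md, mask),
        napdp=napdp(pd_, db, mask),
    )
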