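"""Thresholding strategies.

Two estimators of a visual-field threshold surface:

* :func:`staircase_42` — a classic full-threshold 4-2 dB double-crossing
  staircase, run independently at every location.  This is a declared
  stand-in for proprietary Bayesian strategies; what matters for the
  comparisons here is its per-location independence.
* :func:`run_spark` — a four-phase interpolation strategy: phase 1 directly
  brackets only six seed points (one per functional sector) and fills the
  rest by regression/interpolation; phases 2-4 each directly probe 21
  locations with corrections sized by the running standard error, and the
  four per-location estimates are combined by discarding the most extreme
  one and averaging the closest three.

All presentations are expressed on the measuring instrument's dB scale and
clipped to its presentable range; observer ground truth lives on the k=40
reference scale and is converted internally.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from perisim.geometry import (
    SECTOR_LABELS,
    SectorMap,
    TestGrid,
    assign_sectors,
    build_grid,
    match_locations,
)
from perisim.observer_sim import (
    REFERENCE_K,
    HillParams,
    Observer,
    TrueField,
    p_seen,
)
from perisim.scales import InstrumentModel, clip_to_range

__all__ = [
    "Presentation",
    "StrategyOutcome",
    "CatchSchedule",
    "staircase_42",
    "spark_phase1",
    "spark_refine_phase",
    "spark_combine",
    "run_spark",
    "fit_seed_regression",
    "SeedRegression",
    "catch_trials",
    "phase_direct_sets",
]

#: Seconds per presentation and fixed overhead for the test-time proxy.
_SECONDS_PER_PRESENTATION = 1.5
_TIME_OVERHEAD_S = 20.0

_PHASE1_SEED_SE = 2.0
_PHASE1_INTERP_SE = 4.0
_SE_MIN = 1.0


@dataclass(frozen=True)
class Presentation:
    """One stimulus presentation (phase 0 = staircase)."""

    phase: int
    index: int  # grid index; -1 for off-grid catch stimuli
    stimulus_db: float
    seen: bool
    is_catch: bool = False
    catch_type: str | None = None


@dataclass
class StrategyOutcome:
    """Estimated thresholds plus bookkeeping for one strategy run."""

    strategy: str
    grid: TestGrid
    instrument: InstrumentModel
    thresholds: np.ndarray  # instrument dB scale
    saturated: np.ndarray  # bool, floor/ceiling clip flags
    presentations: list[Presentation]
    phase_estimates: np.ndarray | None = None  # (4, n) for the 4-phase strategy
    direct_tested: dict[int, list[int]] = field(default_factory=dict)
    fp_observed: float | None = None
    fn_observed: float | None = None
    fl_observed: float | None = None

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)

    @property
    def test_time_s(self) -> float:
        return self.n_presentations * _SECONDS_PER_PRESENTATION + _TIME_OVERHEAD_S

    def catch_rates(self) -> dict[str, float | None]:
        return {
            "fp": self.fp_observed,
            "fn": self.fn_observed,
            "fl": self.fl_observed,
        }

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "grid": self.grid.name,
            "instrument": self.instrument.name,
            "thresholds": [float(t) for t in self.thresholds],
            "saturated": [bool(s) for s in self.saturated],
            "phase_estimates": (
                None
                if self.phase_estimates is None
                else [[float(v) for v in row] for row in self.phase_estimates]
            ),
            "direct_tested": {str(k): v for k, v in self.direct_tested.items()},
            "n_presentations": self.n_presentations,
            "test_time_s": self.test_time_s,
            "catch_rates": self.catch_rates(),
            "log": [
                [p.phase, p.index, p.stimulus_db, int(p.seen), int(p.is_catch),
                 p.catch_type or ""]
                for p in self.presentations
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def save_csv(self, path) -> None:
        counts = np.zeros(len(self.grid), dtype=int)
        for p in self.presentations:
            if not p.is_catch and p.index >= 0:
                counts[p.index] += 1
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "x_deg", "y_deg", "threshold_db", "n_presentations"])
            for i, pt in enumerate(self.grid.points):
                w.writerow([i, pt.x, pt.y, float(self.thresholds[i]), int(counts[i])])


# --- plumbing --------------------------------------------------------------


def _observer_indexer(observer: Observer, grid: TestGrid) -> list[int]:
    """Map grid indices onto the observer's own grid."""
    if observer.grid.points == grid.points:
        return list(range(len(grid)))
    pairs = match_locations(grid, observer.grid)
    if len(pairs) != len(grid):
        raise ValueError(
            f"observer grid {observer.grid.name!r} does not cover test grid "
            f"{grid.name!r}"
        )
    return [j for _, j in pairs]


def _make_responder(
    observer: Observer,
    obs_index: int,
    instrument: InstrumentModel,
    rng: np.random.Generator,
) -> Callable[[float], bool]:
    """Responder taking a stimulus on the instrument scale."""
    sens = observer.sensitivity_at(obs_index)
    params = observer.params
    shift = REFERENCE_K - instrument.k

    def _respond(stim_inst_db: float) -> bool:
        p = p_seen(stim_inst_db + shift, sens, params)
        return bool(rng.random() < p)

    return _respond


def _expected_normal_inst(
    grid: TestGrid, age: float, instrument: InstrumentModel
) -> np.ndarray:
    """Age-corrected normal starting levels on the instrument scale."""
    hill = HillParams()
    shift = instrument.k - REFERENCE_K
    vals = np.array([hill.expected(p, age) + shift for p in grid.points])
    return np.clip(vals, instrument.db_floor, instrument.db_ceiling)


# --- staircase -------------------------------------------------------------


def _staircase_one(
    respond: Callable[[float], bool],
    start: float,
    lo: float,
    hi: float,
    log: Callable[[float, bool], None],
    steps: Sequence[float] = (4.0, 2.0),
    max_presentations: int = 30,
) -> tuple[float, bool]:
    """Double-crossing staircase at one location.

    Seen responses dim the stimulus (dB up), unseen brighten it; the step
    halves at each response reversal and the run ends after the last step
    size has produced a reversal.  The threshold is the last level seen.
    Returns (threshold, saturated).
    """
    level = min(max(start, lo), hi)
    step_idx = 0
    prev: bool | None = None
    last_seen: float | None = None
    floor_misses = 0
    ceiling_hits = 0
    for _ in range(max_presentations):
        seen = respond(level)
        log(level, seen)
        if seen:
            last_seen = level
        if prev is not None and seen != prev:
            step_idx += 1
            if step_idx >= len(steps):
                break
        prev = seen
        if seen:
            if level >= hi:
                ceiling_hits += 1
                if ceiling_hits >= 2:
                    break
                continue
            level = min(level + steps[step_idx], hi)
        else:
            if level <= lo:
                floor_misses += 1
                if floor_misses >= 2:
                    break
                continue
            level = max(level - steps[step_idx], lo)
    if last_seen is None:
        return lo, True  # never seen, even at maximum brightness: plateau
    if last_seen >= hi and ceiling_hits >= 2:
        return hi, True
    return last_seen, False


_PRIMARY_POINTS = ((9, 9), (-9, 9), (9, -9), (-9, -9))


def staircase_42(
    observer: Observer,
    grid: TestGrid,
    instrument: InstrumentModel,
    rng: np.random.Generator,
    catch_schedule: "CatchSchedule | None" = None,
) -> StrategyOutcome:
    """Independent 4-2 staircases at every grid location.

    Four primary points are measured first starting from age-corrected normal
    levels; remaining locations start from the mean of already-measured
    6-degree neighbours (growth-pattern style).
    """
    obs_idx = _observer_indexer(observer, grid)
    n = len(grid)
    lo, hi = instrument.db_floor, instrument.db_ceiling
    norm_start = _expected_normal_inst(grid, observer.age, instrument)
    presentations: list[Presentation] = []

    primaries = [
        grid.index_of(p) for p in _PRIMARY_POINTS if p in grid
    ]
    # Deterministic order: primaries, then the rest by distance to nearest
    # primary (grid order breaking ties).
    rest = [i for i in range(n) if i not in primaries]

    def _d2_to_primary(i: int) -> int:
        px, py = grid.points[i]
        return min(
            (px - qx) ** 2 + (py - qy) ** 2 for qx, qy in _PRIMARY_POINTS
        )

    order = primaries + sorted(rest, key=lambda i: (_d2_to_primary(i), i))

    neighbours: dict[int, list[int]] = {i: [] for i in range(n)}
    pos = {p: i for i, p in enumerate(grid.points)}
    for i, p in enumerate(grid.points):
        for dx, dy in ((6, 0), (-6, 0), (0, 6), (0, -6)):
            q = (p.x + dx, p.y + dy)
            if q in pos:
                neighbours[i].append(pos[q])

    thresholds = np.full(n, np.nan)
    saturated = np.zeros(n, dtype=bool)
    measured: set[int] = set()
    for i in order:
        done = [j for j in neighbours[i] if j in measured]
        start = (
            float(np.mean([thresholds[j] for j in done]))
            if done
            else float(norm_start[i])
        )
        responder = _make_responder(observer, obs_idx[i], instrument, rng)

        def _log(level: float, seen: bool, _i=i) -> None:
            presentations.append(Presentation(0, _i, level, seen))

        thresholds[i], saturated[i] = _staircase_one(
            responder, start, lo, hi, _log
        )
        measured.add(i)

    outcome = StrategyOutcome(
        strategy="staircase42",
        grid=grid,
        instrument=instrument,
        thresholds=thresholds,
        saturated=saturated,
        presentations=presentations,
        direct_tested={0: list(range(n))},
    )
    schedule = catch_schedule if catch_schedule is not None else CatchSchedule()
    _append_catches(outcome, schedule, observer, obs_idx, instrument, rng)
    return outcome


# --- four-phase strategy ---------------------------------------------------

#: Seed pairing for alternating bracketing: the two points above the
#: horizontal midline, the two below, then central/temporal.
_SEED_PAIRS = (
    ("superior_nasal", "superior_arcuate"),
    ("inferior_nasal", "inferior_arcuate"),
    ("central", "temporal"),
)


def _bracket_pair(
    responders: tuple[Callable[[float], bool], Callable[[float], bool]],
    starts: tuple[float, float],
    lo: float,
    hi: float,
    logs: tuple[Callable[[float, bool], None], Callable[[float, bool], None]],
) -> tuple[float, float]:
    """Alternating 4-2-1 bracketing of a seed pair.

    Presentations alternate between the members; the partner's first
    response nudges the other member's starting level before its first
    presentation, which is the cross-talk the strategy exploits.
    """

    class _State:
        def __init__(self, start: float):
            self.level = min(max(start, lo), hi)
            self.step_idx = 0
            self.prev: bool | None = None
            self.last_seen: float | None = None
            self.reversals = 0
            self.done = False
            self.started = False
            self.floor_misses = 0
            self.ceiling_hits = 0

    steps = (4.0, 2.0, 1.0)
    states = [_State(starts[0]), _State(starts[1])]
    for _ in range(40):  # safety bound; brackets end well before this
        progressed = False
        for m in (0, 1):
            st = states[m]
            if st.done:
                continue
            progressed = True
            seen = responders[m](st.level)
            logs[m](st.level, seen)
            st.started = True
            if seen:
                st.last_seen = st.level
            other = states[1 - m]
            if not other.started:
                # Improve the partner's start from this response.
                other.level = min(
                    max(other.level + (2.0 if seen else -2.0), lo), hi
                )
            if st.prev is not None and seen != st.prev:
                st.reversals += 1
                st.step_idx += 1
                if st.step_idx >= len(steps):
                    st.done = True
            st.prev = seen
            if st.done:
                continue
            if seen:
                if st.level >= hi:
                    st.ceiling_hits += 1
                    if st.ceiling_hits >= 2:
                        st.done = True
                    continue
                st.level = min(st.level + steps[st.step_idx], hi)
            else:
                if st.level <= lo:
                    st.floor_misses += 1
                    if st.floor_misses >= 2:
                        st.done = True
                    continue
                st.level = max(st.level - steps[st.step_idx], lo)
        if not progressed:
            break
    return tuple(
        st.last_seen if st.last_seen is not None else lo for st in states
    )


def _interpolate_from_seeds(
    grid: TestGrid, sector_map: SectorMap, seed_values: dict[str, float]
) -> np.ndarray:
    """Inverse-distance-weighted fill of all locations from the six seeds.

    Reproduces a constant field exactly when all seed values coincide.
    """
    seeds = [(sector_map.seed_points[s], seed_values[s]) for s in SECTOR_LABELS]
    out = np.empty(len(grid))
    for i, p in enumerate(grid.points):
        num = den = 0.0
        hit = None
        for q, v in seeds:
            d2 = (p.x - q.x) ** 2 + (p.y - q.y) ** 2
            if d2 == 0:
                hit = v
                break
            w = 1.0 / d2
            num += w * v
            den += w
        out[i] = hit if hit is not None else num / den
    return out


def spark_phase1(
    observer: Observer,
    sector_map: SectorMap,
    instrument: InstrumentModel,
    rng: np.random.Generator,
    regression_model: "SeedRegression | None" = None,
    log: list[Presentation] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Phase 1: bracket the six seeds, infer the remaining 60 locations.

    Returns (estimates, standard errors, directly tested indices) over the
    full grid, on the instrument scale.
    """
    grid = sector_map.grid
    obs_idx = _observer_indexer(observer, grid)
    lo, hi = instrument.db_floor, instrument.db_ceiling
    norm_start = _expected_normal_inst(grid, observer.age, instrument)
    presentations = log if log is not None else []

    seed_values: dict[str, float] = {}
    direct: list[int] = []
    for label_a, label_b in _SEED_PAIRS:
        ia = grid.index_of(sector_map.seed_points[label_a])
        ib = grid.index_of(sector_map.seed_points[label_b])
        direct += [ia, ib]

        def _mk_log(i: int):
            def _log(level: float, seen: bool) -> None:
                presentations.append(Presentation(1, i, level, seen))

            return _log

        est_a, est_b = _bracket_pair(
            (
                _make_responder(observer, obs_idx[ia], instrument, rng),
                _make_responder(observer, obs_idx[ib], instrument, rng),
            ),
            (float(norm_start[ia]), float(norm_start[ib])),
            lo,
            hi,
            (_mk_log(ia), _mk_log(ib)),
        )
        seed_values[label_a] = est_a
        seed_values[label_b] = est_b

    if regression_model is not None:
        seed_vec = np.array(
            [seed_values[s] for s in regression_model.seed_labels]
        )
        estimates = regression_model.predict(seed_vec)
        se = np.clip(regression_model.resid_sd, _SE_MIN, _PHASE1_INTERP_SE)
    else:
        warnings.warn(
            "no seed-regression model supplied; falling back to pure "
            "seed interpolation",
            stacklevel=2,
        )
        estimates = _interpolate_from_seeds(grid, sector_map, seed_values)
        se = np.full(len(grid), _PHASE1_INTERP_SE)
    estimates = np.clip(estimates, lo, hi)
    se = np.asarray(se, dtype=float).copy()
    for i in direct:
        estimates[i] = np.clip(
            seed_values[sector_map.sectors[grid.points[i]]], lo, hi
        )
        se[i] = _PHASE1_SEED_SE
    return estimates, se, direct


def phase_direct_sets(sector_map: SectorMap) -> dict[int, list[int]]:
    """Direct-test index sets for phases 2-4.

    The 60 non-seed locations are ordered by round-robin over sectors and cut
    into consecutive blocks of 21/21/18; phase 4 is topped up to 21 with the
    first locations of the phase-2 block, so each phase tests exactly 21
    distinct locations and the union of phases 1-4 covers the whole grid.
    """
    grid = sector_map.grid
    seeds = {sector_map.seed_points[s] for s in SECTOR_LABELS}
    queues = {
        s: [
            grid.index_of(p)
            for p in sector_map.members(s)
            if p not in seeds
        ]
        for s in SECTOR_LABELS
    }
    order: list[int] = []
    while any(queues.values()):
        for s in SECTOR_LABELS:
            if queues[s]:
                order.append(queues[s].pop(0))
    sets = {
        2: order[:21],
        3: order[21:42],
        4: order[42:60] + order[: 21 - len(order[42:60])],
    }
    return sets


def spark_refine_phase(
    observer: Observer,
    sector_map: SectorMap,
    previous_estimates: np.ndarray,
    previous_se: np.ndarray,
    phase: int,
    instrument: InstrumentModel,
    rng: np.random.Generator,
    direct_set: Sequence[int] | None = None,
    log: list[Presentation] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """One refinement phase: probe 21 locations, re-interpolate the rest.

    Each direct location receives a two-presentation up/down probe whose
    correction magnitude equals the location's previous standard error;
    locations not tested in this phase are shifted by their sector's mean
    direct correction.
    """
    if phase not in (2, 3, 4):
        raise ValueError(f"phase must be 2, 3 or 4, got {phase}")
    grid = sector_map.grid
    obs_idx = _observer_indexer(observer, grid)
    lo, hi = instrument.db_floor, instrument.db_ceiling
    presentations = log if log is not None else []
    if direct_set is None:
        direct_set = phase_direct_sets(sector_map)[phase]
    direct_set = list(direct_set)

    estimates = np.asarray(previous_estimates, dtype=float).copy()
    se = np.asarray(previous_se, dtype=float).copy()
    deltas: dict[int, float] = {}
    for i in direct_set:
        responder = _make_responder(observer, obs_idx[i], instrument, rng)
        est = float(np.clip(estimates[i], lo, hi))
        step = float(se[i])
        first = responder(est)
        presentations.append(Presentation(phase, i, est, first))
        probe = float(np.clip(est + (step if first else -step), lo, hi))
        second = responder(probe)
        presentations.append(Presentation(phase, i, probe, second))
        if first and second:
            new = est + step
        elif not first and not second:
            new = est - step
        else:
            new = est
        new = float(np.clip(new, lo, hi))
        deltas[i] = new - est
        estimates[i] = new
        se[i] = max(step / 2.0, _SE_MIN)

    # Sector-wise re-interpolation of untested locations.
    sector_delta: dict[str, float] = {}
    for s in SECTOR_LABELS:
        ds = [deltas[i] for i in direct_set if sector_map.sectors[grid.points[i]] == s]
        if ds:
            sector_delta[s] = float(np.mean(ds))
    global_delta = float(np.mean(list(deltas.values()))) if deltas else 0.0
    for i in range(len(grid)):
        if i in deltas:
            continue
        s = sector_map.sectors[grid.points[i]]
        estimates[i] = float(
            np.clip(estimates[i] + sector_delta.get(s, global_delta), lo, hi)
        )
        se[i] = max(se[i] * 0.75, _SE_MIN)
    return estimates, se, direct_set


def spark_combine(four_estimates: Sequence[float]) -> float:
    """Combine the four per-phase estimates at one location.

    Enumerates the four leave-one-out triples, keeps the one with the
    smallest range (discarding the most extreme estimate) and returns its
    mean.  Range ties prefer discarding the phase-1 estimate, then the
    largest value.
    """
    vals = [float(v) for v in four_estimates]
    if len(vals) != 4 or not all(np.isfinite(vals)):
        raise ValueError("exactly 4 finite estimates are required")
    best = None
    for excl in range(4):
        triple = [v for i, v in enumerate(vals) if i != excl]
        rng_ = max(triple) - min(triple)
        key = (rng_, 0 if excl == 0 else 1, -vals[excl], excl)
        if best is None or key < best[0]:
            best = (key, float(np.mean(triple)))
    return best[1]


@dataclass
class CatchSchedule:
    """Numbers of catch trials per type; zero means the type is not assessed."""

    n_fp: int = 10
    n_fn: int = 10
    n_fl: int = 10

    @classmethod
    def spark_default(cls) -> "CatchSchedule":
        # The four-phase strategy does not measure false negatives.
        return cls(n_fp=10, n_fn=0, n_fl=10)


def catch_trials(
    schedule: CatchSchedule,
    observer: Observer,
    rng: np.random.Generator,
    instrument: InstrumentModel | None = None,
    seen_index: int | None = None,
) -> tuple[dict[str, float | None], list[Presentation]]:
    """Run catch trials and return observed rates.

    False-positive catches present an unseeable (beyond-ceiling) stimulus;
    false-negative catches a maximally bright stimulus at the observer's most
    sensitive location; fixation-loss catches probe the blind spot
    (Heijl-Krakau).  A type with zero scheduled catches reports ``None``.
    """
    params = observer.params
    ceiling = instrument.db_ceiling if instrument is not None else REFERENCE_K
    floor = instrument.db_floor if instrument is not None else 0.0
    shift = REFERENCE_K - (instrument.k if instrument is not None else REFERENCE_K)
    if seen_index is None:
        seen_index = int(np.argmax(observer.true_field.sensitivity))
    log: list[Presentation] = []
    rates: dict[str, float | None] = {}

    hits = 0
    for _ in range(schedule.n_fp):
        seen = bool(rng.random() < params.fp_rate)
        log.append(Presentation(0, -1, ceiling + 10.0, seen, True, "fp"))
        hits += seen
    rates["fp"] = hits / schedule.n_fp if schedule.n_fp else None

    misses = 0
    for _ in range(schedule.n_fn):
        p = p_seen(
            floor + shift, observer.sensitivity_at(seen_index), params
        )
        seen = bool(rng.random() < p)
        log.append(Presentation(0, seen_index, floor, seen, True, "fn"))
        misses += not seen
    rates["fn"] = misses / schedule.n_fn if schedule.n_fn else None

    losses = 0
    for _ in range(schedule.n_fl):
        seen = bool(rng.random() < params.fl_rate)
        log.append(Presentation(0, -1, floor, seen, True, "fl"))
        losses += seen
    rates["fl"] = losses / schedule.n_fl if schedule.n_fl else None
    return rates, log


def _append_catches(
    outcome: StrategyOutcome,
    schedule: CatchSchedule,
    observer: Observer,
    obs_idx: list[int],
    instrument: InstrumentModel,
    rng: np.random.Generator,
) -> None:
    best_grid_i = int(np.argmax([observer.sensitivity_at(j) for j in obs_idx]))
    rates, log = catch_trials(
        schedule, observer, rng, instrument, seen_index=obs_idx[best_grid_i]
    )
    outcome.presentations.extend(log)
    outcome.fp_observed = rates["fp"]
    outcome.fn_observed = rates["fn"]
    outcome.fl_observed = rates["fl"]


def run_spark(
    observer: Observer,
    instrument: InstrumentModel,
    rng: np.random.Generator,
    regression_model: "SeedRegression | None" = None,
    sector_map: SectorMap | None = None,
    catch_schedule: CatchSchedule | None = None,
) -> StrategyOutcome:
    """Run the full four-phase strategy on the 66-point grid."""
    if sector_map is None:
        sector_map = assign_sectors(build_grid("SPARK66"))
    grid = sector_map.grid
    obs_idx = _observer_indexer(observer, grid)
    presentations: list[Presentation] = []
    direct_tested: dict[int, list[int]] = {}

    with warnings.catch_warnings():
        if regression_model is None:
            warnings.simplefilter("ignore")
        est, se, direct = spark_phase1(
            observer, sector_map, instrument, rng, regression_model,
            log=presentations,
        )
    direct_tested[1] = direct
    phase_estimates = np.empty((4, len(grid)))
    phase_estimates[0] = est
    sets = phase_direct_sets(sector_map)
    for phase in (2, 3, 4):
        est, se, direct = spark_refine_phase(
            observer, sector_map, est, se, phase, instrument, rng,
            direct_set=sets[phase], log=presentations,
        )
        direct_tested[phase] = direct
        phase_estimates[phase - 1] = est

    thresholds = np.empty(len(grid))
    saturated = np.zeros(len(grid), dtype=bool)
    for i in range(len(grid)):
        combined = spark_combine(phase_estimates[:, i])
        thresholds[i], saturated[i] = clip_to_range(combined, instrument)
        # The floor itself is a plateau record when the combined estimate
        # sits on it and the location was never seen above it.
        if thresholds[i] <= instrument.db_floor:
            saturated[i] = True

    outcome = StrategyOutcome(
        strategy="spark4",
        grid=grid,
        instrument=instrument,
        thresholds=thresholds,
        saturated=saturated,
        presentations=presentations,
        phase_estimates=phase_estimates,
        direct_tested=direct_tested,
    )
    schedule = (
        catch_schedule if catch_schedule is not None else CatchSchedule.spark_default()
    )
    _append_catches(outcome, schedule, observer, obs_idx, instrument, rng)
    return outcome


# --- seed regression -------------------------------------------------------


@dataclass
class SeedRegression:
    """Least-squares map from six seed sensitivities to all 66 locations."""

    coef: np.ndarray  # (7, n) including intercept row 0
    resid_sd: np.ndarray  # (n,)
    seed_labels: tuple[str, ...]
    seed_indices: tuple[int, ...]

    def predict(self, seed_values: np.ndarray) -> np.ndarray:
        x = np.concatenate(([1.0], np.asarray(seed_values, dtype=float)))
        return x @ self.coef


def fit_seed_regression(
    training_fields,
    sector_map: SectorMap,
) -> SeedRegression:
    """Fit the phase-1 regression from a bank of training fields.

    ``training_fields`` is an (n_fields, n_locations) array (or a list of
    :class:`TrueField`) on the scale the model will be used on.  Requires at
    least 50 fields; a rank-deficient design triggers a ridge fallback with a
    warning.
    """
    if len(training_fields) and isinstance(training_fields[0], TrueField):
        y = np.vstack([f.sensitivity for f in training_fields])
    else:
        y = np.asarray(training_fields, dtype=float)
    n_fields, n_loc = y.shape
    if n_fields < 50:
        raise ValueError(
            f"at least 50 training fields are required, got {n_fields}"
        )
    grid = sector_map.grid
    if n_loc != len(grid):
        raise ValueError("training fields do not match the grid size")
    seed_labels = tuple(SECTOR_LABELS)
    seed_idx = tuple(
        grid.index_of(sector_map.seed_points[s]) for s in seed_labels
    )
    x = np.column_stack([np.ones(n_fields), y[:, list(seed_idx)]])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn(
            "degenerate seed design matrix; using a ridge-regularized fit",
            stacklevel=2,
        )
        lam = 1e-8 * np.trace(x.T @ x)
        coef = np.linalg.solve(
            x.T @ x + lam * np.eye(x.shape[1]), x.T @ y
        )
    else:
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = max(n_fields - x.shape[1], 1)
    resid_sd = np.sqrt(np.sum(resid**2, axis=0) / dof)
    return SeedRegression(coef, resid_sd, seed_labels, seed_idx)
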