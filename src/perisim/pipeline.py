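"""End-to-end in-silico study: cohorts -> strategies -> indices -> agreement.

The default design mirrors the comparison of interest: the four-phase
interpolation strategy runs on the short-dynamic-range k=30 instrument and
the staircase stand-in on the k=40 instrument, on the same observers.  A
counterfactual arm can additionally run the four-phase strategy on the k=40
instrument to separate algorithm effects from dynamic-range (plateau)
effects.  Everything is deterministic given the study seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from perisim import __version__
from perisim.agis import AGISResult, agis_score
from perisim.agreement import (
    AgreementSummary,
    PointwiseMap,
    bland_altman,
    pointwise_bias_map,
    spearman_rho,
    wilcoxon_signed_rank,
)
from perisim.geometry import assign_sectors, build_grid, match_locations
from perisim.indices import NormativeDB, build_normative_db, compute_global_indices
from perisim.observer_sim import (
    REFERENCE_K,
    CohortConfig,
    normal_field,
    simulate_cohort,
)
from perisim.scales import InstrumentModel, get_instrument
from perisim.strategies import (
    StrategyOutcome,
    fit_seed_regression,
    run_spark,
    staircase_42,
)

__all__ = [
    "ReliabilityThresholds",
    "StudyConfig",
    "StudyReport",
    "reliability_filter",
    "run_study",
    "write_report",
]

#: Difference convention used by every agreement output in this module.
DIFFERENCE_CONVENTION = "difference = staircase42 - spark4"


@dataclass(frozen=True)
class ReliabilityThresholds:
    """Exclusion cut-offs; a test fails only on strict excess."""

    fp: float = 0.20
    fn: float = 0.20
    fl: float = 0.30


def reliability_filter(
    outcome: StrategyOutcome,
    strategy: str | None = None,
    thresholds: ReliabilityThresholds | None = None,
) -> tuple[bool, list[str]]:
    """Apply reliability criteria to a strategy outcome.

    Returns ``(passed, reasons)``.  A rate that the strategy does not
    measure (reported as ``None``, e.g. FN for the four-phase strategy) is
    never a failure reason.
    """
    thresholds = thresholds or ReliabilityThresholds()
    rates = outcome.catch_rates()
    reasons = []
    for name in ("fp", "fn", "fl"):
        rate = rates[name]
        if rate is not None and rate > getattr(thresholds, name):
            reasons.append(name.upper())
    return (not reasons), reasons


@dataclass(frozen=True)
class StudyConfig:
    """Full recipe for one in-silico study."""

    seed: int = 0
    n_glaucoma: int = 39
    n_cataract: int = 31
    staircase_instrument: str = "HFA"
    spark_instrument: str = "Twinfield2"
    n_normative: int = 60
    normative_age_range: tuple[float, float] = (35.0, 75.0)
    n_training_fields: int = 120
    reliability: ReliabilityThresholds = field(default_factory=ReliabilityThresholds)
    glaucoma_depth_range: tuple[float, float] = (6.0, 34.0)
    cataract_diffuse_range: tuple[float, float] = (1.0, 8.0)
    counterfactual_spark_on_staircase_instrument: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reliability"] = asdict(self.reliability)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "reliability" in d and isinstance(d["reliability"], dict):
            d["reliability"] = ReliabilityThresholds(**d["reliability"])
        for key in (
            "normative_age_range",
            "glaucoma_depth_range",
            "cataract_diffuse_range",
        ):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)


@dataclass
class StudyReport:
    """Aggregated outputs of one study run."""

    config: StudyConfig
    group_summary: pd.DataFrame
    per_subject: pd.DataFrame
    agreement: dict[tuple[str, str], dict]
    pointwise: dict[str, PointwiseMap]
    agis_summary: pd.DataFrame
    agis_scores: pd.DataFrame
    agis_crosstab: pd.DataFrame
    exclusions: list[dict]
    counts: dict[str, dict[str, int]]
    counterfactual: pd.DataFrame | None = None


def _median_iqr(vals) -> tuple[float, float, float]:
    v = np.asarray(vals, dtype=float)
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def _training_bank(
    n: int, seed, grid, instrument: InstrumentModel
) -> np.ndarray:
    """Synthetic training fields (instrument scale) for the seed regression.

    A mixture of normal, focally depressed and diffusely depressed fields so
    the regression sees the spectrum it will be applied to.
    """
    from perisim.observer_sim import add_diffuse_loss, add_focal_defect

    rng = np.random.default_rng(seed)
    shift = instrument.k - REFERENCE_K
    rows = np.empty((n, len(grid)))
    sectors = (
        "superior_arcuate",
        "inferior_arcuate",
        "superior_nasal",
        "inferior_nasal",
    )
    for i in range(n):
        age = float(rng.uniform(30, 80))
        fld = normal_field(grid, age, rng)
        kind = i % 3
        if kind == 1:
            sec = sectors[int(rng.integers(len(sectors)))]
            fld = add_focal_defect(fld, sec, float(rng.uniform(4, 30)), seed=rng)
        elif kind == 2:
            fld = add_diffuse_loss(fld, float(rng.uniform(1, 8)))
        rows[i] = fld.sensitivity + shift
    return rows


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study deterministically from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    (
        ss_train,
        ss_norm_stair,
        ss_norm_spark,
        ss_glaucoma,
        ss_cataract,
        ss_measure,
        ss_order,
    ) = ss.spawn(7)

    grid30 = build_grid("30-2")
    grid66 = build_grid("SPARK66")
    sector_map = assign_sectors(grid66)
    inst_stair = get_instrument(config.staircase_instrument)
    inst_spark = get_instrument(config.spark_instrument)

    training = _training_bank(
        config.n_training_fields, ss_train, grid66, inst_spark
    )
    regression = fit_seed_regression(training, sector_map)

    db_stair = build_normative_db(
        config.n_normative,
        config.normative_age_range,
        seed=int(np.random.default_rng(ss_norm_stair).integers(2**31)),
        strategy="staircase42",
        instrument=inst_stair,
        grid=grid30,
    )
    db_spark = build_normative_db(
        config.n_normative,
        config.normative_age_range,
        seed=int(np.random.default_rng(ss_norm_spark).integers(2**31)),
        strategy="spark4",
        instrument=inst_spark,
        grid=grid66,
        regression_model=regression,
    )

    # Matched-location projection: staircase values at the 66 coincident
    # points, in the 66-point grid's order.
    pairs = match_locations(grid66, grid30)
    stair_at_66 = [j for _, j in pairs]
    db_stair66 = db_stair.subset(stair_at_66)

    cohorts = {
        "glaucoma": simulate_cohort(
            CohortConfig(
                group="glaucoma",
                n_subjects=config.n_glaucoma,
                seed=int(np.random.default_rng(ss_glaucoma).integers(2**31)),
                depth_range=config.glaucoma_depth_range,
            )
        ),
        "cataract": simulate_cohort(
            CohortConfig(
                group="cataract",
                n_subjects=config.n_cataract,
                seed=int(np.random.default_rng(ss_cataract).integers(2**31)),
                diffuse_range=config.cataract_diffuse_range,
            )
        ),
    }

    order_rng = np.random.default_rng(ss_order)
    rows = []
    exclusions = []
    agis_rows = []
    matrices: dict[tuple[str, str], list[np.ndarray]] = {}
    counts = {}
    counterfactual_rows = []
    measure_streams = iter(ss_measure.spawn(
        sum(len(c) for c in cohorts.values())
    ))
    for group, observers in cohorts.items():
        analysed = 0
        for obs in observers:
            ss_obs = next(measure_streams)
            rng_stair, rng_spark, rng_cf = (
                np.random.default_rng(s) for s in ss_obs.spawn(3)
            )
            # Test-order randomisation is metadata only: the two strategies
            # consume independent RNG streams, so results are order-invariant.
            first = "staircase42" if order_rng.random() < 0.5 else "spark4"

            out_stair = staircase_42(obs, grid30, inst_stair, rng_stair)
            out_spark = run_spark(
                obs, inst_spark, rng_spark,
                regression_model=regression, sector_map=sector_map,
            )

            ok_stair, why_stair = reliability_filter(
                out_stair, thresholds=config.reliability
            )
            ok_spark, why_spark = reliability_filter(
                out_spark, thresholds=config.reliability
            )
            if not (ok_stair and ok_spark):
                exclusions.append(
                    {
                        "uid": obs.uid,
                        "group": group,
                        "criteria": ";".join(
                            [f"staircase42:{w}" for w in why_stair]
                            + [f"spark4:{w}" for w in why_spark]
                        ),
                    }
                )
                continue
            analysed += 1

            vals_stair66 = out_stair.thresholds[stair_at_66]
            vals_spark = out_spark.thresholds
            gi_stair = compute_global_indices(vals_stair66, db_stair66, obs.age)
            gi_spark = compute_global_indices(vals_spark, db_spark, obs.age)
            for strat, gi, out in (
                ("staircase42", gi_stair, out_stair),
                ("spark4", gi_spark, out_spark),
            ):
                rows.append(
                    {
                        "uid": obs.uid,
                        "group": group,
                        "strategy": strat,
                        "tested_first": first,
                        "ms": gi.ms,
                        "md": gi.md,
                        "psd": gi.psd,
                        "napdp": gi.napdp,
                        "n_presentations": out.n_presentations,
                        "test_time_s": out.test_time_s,
                    }
                )
            matrices.setdefault((group, "staircase42"), []).append(vals_stair66)
            matrices.setdefault((group, "spark4"), []).append(vals_spark)

            if group == "glaucoma":
                from perisim.indices import total_deviation

                td_stair = total_deviation(vals_stair66, db_stair66, obs.age)
                td_spark = total_deviation(vals_spark, db_spark, obs.age)
                res_stair = agis_score(td_stair, grid66)
                res_spark = agis_score(td_spark, grid66)
                agis_rows.append(
                    {
                        "uid": obs.uid,
                        "staircase42_score": res_stair.score,
                        "staircase42_category": res_stair.category,
                        "spark4_score": res_spark.score,
                        "spark4_category": res_spark.category,
                    }
                )

            if config.counterfactual_spark_on_staircase_instrument:
                shift = inst_stair.k - inst_spark.k
                regression_cf = fit_seed_regression(training + shift, sector_map)
                out_cf = run_spark(
                    obs, inst_stair, rng_cf,
                    regression_model=regression_cf, sector_map=sector_map,
                )
                counterfactual_rows.append(
                    {
                        "uid": obs.uid,
                        "group": group,
                        "ms": float(np.mean(out_cf.thresholds)),
                        "n_presentations": out_cf.n_presentations,
                    }
                )
        counts[group] = {
            "n_input": len(observers),
            "n_analysed": analysed,
            "n_excluded": len(observers) - analysed,
        }

    per_subject = pd.DataFrame(rows)
    summary_rows = []
    for group in cohorts:
        for strat in ("staircase42", "spark4"):
            sub = per_subject[
                (per_subject.group == group) & (per_subject.strategy == strat)
            ]
            if sub.empty:
                summary_rows.append(
                    {"group": group, "strategy": strat, "empty_group": True}
                )
                continue
            for index in ("ms", "md", "psd", "napdp", "test_time_s",
                          "n_presentations"):
                med, lo, hi = _median_iqr(sub[index])
                summary_rows.append(
                    {
                        "group": group,
                        "strategy": strat,
                        "index": index,
                        "median": med,
                        "iqr_low": lo,
                        "iqr_high": hi,
                        "empty_group": False,
                    }
                )
    group_summary = pd.DataFrame(summary_rows)

    agreement: dict[tuple[str, str], dict] = {}
    pointwise: dict[str, PointwiseMap] = {}
    for group in cohorts:
        a = per_subject[
            (per_subject.group == group)
            & (per_subject.strategy == "staircase42")
        ].set_index("uid")
        b = per_subject[
            (per_subject.group == group) & (per_subject.strategy == "spark4")
        ].set_index("uid")
        if a.empty:
            continue
        for index in ("ms", "md", "psd"):
            xa = a[index].to_numpy()
            xb = b.loc[a.index, index].to_numpy()
            summ = bland_altman(xa, xb)
            rho, rho_p = spearman_rho(xa, xb)
            try:
                w_stat, w_p = wilcoxon_signed_rank(xa, xb)
            except ValueError:
                w_stat, w_p = float("nan"), float("nan")
            agreement[(group, index)] = {
                "convention": DIFFERENCE_CONVENTION,
                **summ.to_dict(),
                "spearman_rho": rho,
                "spearman_p": rho_p,
                "wilcoxon_stat": w_stat,
                "wilcoxon_p": w_p,
            }
        pointwise[group] = pointwise_bias_map(
            np.vstack(matrices[(group, "staircase42")]),
            np.vstack(matrices[(group, "spark4")]),
            grid66,
        )

    agis_scores = pd.DataFrame(agis_rows)
    if not agis_scores.empty:
        agis_summary = pd.DataFrame(
            [
                {
                    "strategy": strat,
                    "mean": float(agis_scores[f"{strat}_score"].mean()),
                    "sd": float(agis_scores[f"{strat}_score"].std(ddof=1)),
                    "median": float(agis_scores[f"{strat}_score"].median()),
                    "min": int(agis_scores[f"{strat}_score"].min()),
                    "max": int(agis_scores[f"{strat}_score"].max()),
                }
                for strat in ("staircase42", "spark4")
            ]
        )
        agis_crosstab = pd.crosstab(
            agis_scores["staircase42_category"],
            agis_scores["spark4_category"],
        )
    else:
        agis_summary = pd.DataFrame()
        agis_crosstab = pd.DataFrame()

    return StudyReport(
        config=config,
        group_summary=group_summary,
        per_subject=per_subject,
        agreement=agreement,
        pointwise=pointwise,
        agis_summary=agis_summary,
        agis_scores=agis_scores,
        agis_crosstab=agis_crosstab,
        exclusions=exclusions,
        counts=counts,
        counterfactual=(
            pd.DataFrame(counterfactual_rows) if counterfactual_rows else None
        ),
    )


def write_report(report: StudyReport, out_dir, fmt: str = "csv") -> list[Path]:
    """Persist a study report: CSV tables, figure data and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _frame(df: pd.DataFrame, name: str) -> None:
        path = out / f"{name}.{ 'json' if fmt == 'json' else 'csv'}"
        if fmt == "json":
            df.to_json(path, orient="records", indent=1)
        else:
            df.to_csv(path, index=False)
        written.append(path)

    _frame(report.group_summary, "group_summary")
    _frame(report.per_subject, "per_subject")
    _frame(report.agis_scores, "agis_scores")
    _frame(report.agis_summary, "agis_summary")
    report.agis_crosstab.to_csv(out / "agis_crosstab.csv")
    written.append(out / "agis_crosstab.csv")

    agree_rows = [
        {"group": g, "index": i, **vals}
        for (g, i), vals in report.agreement.items()
    ]
    _frame(pd.DataFrame(agree_rows), "agreement")

    for group, pmap in report.pointwise.items():
        path = out / f"pointwise_{group}.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x_deg", "y_deg", "bias", "sd"])
            w.writerow([f"# {pmap.convention}", "", "", ""])
            for row in pmap.to_rows():
                w.writerow(row)
        written.append(path)

    _frame(pd.DataFrame(report.exclusions), "exclusions")
    if report.counterfactual is not None:
        _frame(report.counterfactual, "counterfactual")

    manifest = {
        "package_version": __version__,
        "seed": report.config.seed,
        "config": report.config.to_dict(),
        "config_hash": report.config.hash(),
        "difference_convention": DIFFERENCE_CONVENTION,
        "counts": report.counts,
        "files": [p.name for p in written],
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    written.append(mpath)
    return written
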