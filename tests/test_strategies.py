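import numpy as np
import pytest

from perisim.observer_sim import Observer, ResponseParams, TrueField, normal_field
from perisim.scales import HFA, TWINFIELD2, convert_db
from perisim.strategies import (
    CatchSchedule,
    SeedRegression,
    catch_trials,
    fit_seed_regression,
    phase_direct_sets,
    run_spark,
    spark_combine,
    spark_phase1,
    spark_refine_phase,
    staircase_42,
)


def brute_force_combine(vals):
    """Oracle: enumerate leave-one-out triples, keep the min-range one."""
    best = None
    for excl in range(4):
        triple = [v for i, v in enumerate(vals) if i != excl]
        r = max(triple) - min(triple)
        if best is None or r < best[0]:
            best = (r, float(np.mean(triple)))
    return best[1]


class TestStaircase:
    def test_deterministic_recovery_near_truth(
        self, grid30, make_uniform_observer, rng
    ):
        obs = make_uniform_observer(grid30, 25.0)
        out = staircase_42(obs, grid30, HFA, rng)
        assert np.all(np.abs(out.thresholds - 25.0) <= 2.0)

    def test_deep_loss_saturates_at_floor(
        self, grid30, make_uniform_observer, rng
    ):
        obs = make_uniform_observer(grid30, -20.0)
        out = staircase_42(obs, grid30, HFA, rng)
        assert np.all(out.thresholds == HFA.db_floor)
        assert np.all(out.saturated)

    def test_mae_within_2db_at_sigma_1(self, grid30):
        # >= 500 thresholds with unit psychometric spread, mid-range truth.
        params = ResponseParams(
            fp_rate=0.0, fn_rate=0.0, sigma_min=1.0, sigma_max=1.0
        )
        rng = np.random.default_rng(2024)
        errors = []
        for rep in range(8):
            s = float(rng.uniform(15, 30))
            obs = Observer(
                "m", "normal", 50.0,
                TrueField(grid30, np.full(76, s)), params,
            )
            out = staircase_42(obs, grid30, HFA, rng)
            errors.extend(np.abs(out.thresholds - s))
        assert len(errors) >= 500
        assert float(np.mean(errors)) <= 2.0

    def test_determinism(self, grid30, make_uniform_observer):
        obs = make_uniform_observer(
            grid30, 22.0, params=ResponseParams()
        )
        a = staircase_42(obs, grid30, HFA, np.random.default_rng(5))
        b = staircase_42(obs, grid30, HFA, np.random.default_rng(5))
        np.testing.assert_array_equal(a.thresholds, b.thresholds)
        assert [
            (p.phase, p.index, p.stimulus_db, p.seen) for p in a.presentations
        ] == [
            (p.phase, p.index, p.stimulus_db, p.seen) for p in b.presentations
        ]

    def test_thresholds_within_instrument_range(self, grid30, rng):
        obs = Observer(
            "g", "glaucoma", 60.0,
            TrueField(grid30, np.linspace(-15, 40, 76)), ResponseParams(),
        )
        out = staircase_42(obs, grid30, TWINFIELD2, rng)
        assert np.all(out.thresholds >= TWINFIELD2.db_floor)
        assert np.all(out.thresholds <= TWINFIELD2.db_ceiling)


class TestSparkPhases:
    def test_phase1_tests_exactly_six_locations(
        self, sector_map, make_uniform_observer, rng
    ):
        obs = make_uniform_observer(sector_map.grid, 25.0)
        log = []
        with pytest.warns(UserWarning, match="regression"):
            est, se, direct = spark_phase1(
                obs, sector_map, HFA, rng, log=log
            )
        assert len(set(direct)) == 6
        tested = {p.index for p in log}
        assert tested == set(direct)

    def test_phase1_uniform_field_interpolates_constant(
        self, sector_map, make_uniform_observer, rng
    ):
        obs = make_uniform_observer(sector_map.grid, 25.0)
        with pytest.warns(UserWarning):
            est, se, direct = spark_phase1(obs, sector_map, HFA, rng)
        assert est.shape == (66,)
        seed_vals = est[direct]
        # Interpolated values lie within the seed estimates' range.
        assert np.all(est >= seed_vals.min() - 1e-9)
        assert np.all(est <= seed_vals.max() + 1e-9)

    def test_refine_phases_test_21_distinct_each(self, sector_map):
        sets = phase_direct_sets(sector_map)
        for phase in (2, 3, 4):
            assert len(set(sets[phase])) == 21

    def test_union_covers_all_66(self, sector_map):
        sets = phase_direct_sets(sector_map)
        seeds = {
            sector_map.grid.index_of(p) for p in sector_map.seeds()
        }
        union = seeds | set(sets[2]) | set(sets[3]) | set(sets[4])
        assert union == set(range(66))

    def test_refine_rejects_bad_phase(
        self, sector_map, make_uniform_observer, rng
    ):
        obs = make_uniform_observer(sector_map.grid, 25.0)
        with pytest.raises(ValueError):
            spark_refine_phase(
                obs, sector_map, np.full(66, 25.0), np.full(66, 2.0), 5,
                HFA, rng,
            )

    def test_noiseless_uniform_estimates_stay_at_truth(
        self, sector_map, make_uniform_observer, rng
    ):
        obs = make_uniform_observer(sector_map.grid, 25.0)
        est, se, _ = spark_refine_phase(
            obs, sector_map, np.full(66, 25.0), np.full(66, 2.0), 2, HFA, rng
        )
        assert np.all(np.abs(est - 25.0) <= 1e-9)


class TestSparkCombine:
    def test_all_equal(self):
        assert spark_combine([20, 20, 20, 20]) == pytest.approx(20.0)

    def test_discards_high_outlier(self):
        assert spark_combine([10, 12, 13, 30]) == pytest.approx(11.666666667)

    def test_discards_outlier_from_zeros(self):
        assert spark_combine([0, 0, 0, 30]) == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            vals = rng.uniform(0, 40, 4)
            assert spark_combine(vals) == pytest.approx(
                brute_force_combine(vals), abs=1e-12
            )

    def test_requires_four_estimates(self):
        with pytest.raises(ValueError):
            spark_combine([1, 2, 3])


class TestRunSpark:
    def test_outcome_structure(self, sector_map, make_uniform_observer, rng):
        obs = make_uniform_observer(sector_map.grid, 25.0)
        out = run_spark(obs, HFA, rng, sector_map=sector_map)
        assert out.thresholds.shape == (66,)
        assert out.phase_estimates.shape == (4, 66)
        assert {len(set(out.direct_tested[p])) for p in (2, 3, 4)} == {21}
        assert len(set(out.direct_tested[1])) == 6

    def test_determinism(self, sector_map, grid66):
        obs = Observer(
            "d", "normal", 50.0,
            TrueField(grid66, np.linspace(15, 32, 66)), ResponseParams(),
        )
        a = run_spark(obs, HFA, np.random.default_rng(11), sector_map=sector_map)
        b = run_spark(obs, HFA, np.random.default_rng(11), sector_map=sector_map)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)
        assert a.n_presentations == b.n_presentations

    def test_fewer_presentations_than_staircase(self, sector_map, grid30):
        counts = {"spark": [], "stair": []}
        for seed in range(10):
            rng_field = np.random.default_rng(seed)
            obs = Observer(
                f"s{seed}", "normal", 50.0,
                normal_field(grid30, 50.0, rng_field), ResponseParams(),
            )
            spark = run_spark(
                obs, TWINFIELD2, np.random.default_rng(seed + 100),
                sector_map=sector_map,
            )
            stair = staircase_42(
                obs, grid30, HFA, np.random.default_rng(seed + 200)
            )
            counts["spark"].append(spark.n_presentations)
            counts["stair"].append(stair.n_presentations)
        assert np.mean(counts["spark"]) < np.mean(counts["stair"])
        assert spark.test_time_s < stair.test_time_s

    def test_plateau_floor_on_short_range_instrument(self, sector_map, grid66):
        # True sensitivities far below the k=30 floor: recorded thresholds,
        # converted to the k=40 scale, can never drop below 10 dB.
        obs = Observer(
            "deep", "glaucoma", 55.0,
            TrueField(grid66, np.full(66, -5.0)), ResponseParams(),
        )
        out = run_spark(
            obs, TWINFIELD2, np.random.default_rng(0), sector_map=sector_map
        )
        on_hfa = convert_db(out.thresholds, TWINFIELD2, HFA)
        assert np.all(on_hfa >= 10.0 - 1e-9)

    def test_lower_replicate_variance_than_staircase(self, sector_map, grid30):
        # The interpolating strategy pools information across locations, so
        # its per-location spread over replicate runs is smaller on average.
        obs = Observer(
            "v", "normal", 50.0,
            normal_field(grid30, 50.0, np.random.default_rng(1)),
            ResponseParams(),
        )
        from perisim.geometry import match_locations

        pairs = match_locations(sector_map.grid, grid30)
        at66 = [j for _, j in pairs]
        spark_runs, stair_runs = [], []
        for seed in range(15):
            spark_runs.append(
                run_spark(
                    obs, HFA, np.random.default_rng(seed),
                    sector_map=sector_map,
                ).thresholds
            )
            stair_runs.append(
                staircase_42(
                    obs, grid30, HFA, np.random.default_rng(1000 + seed)
                ).thresholds[at66]
            )
        var_spark = np.var(np.vstack(spark_runs), axis=0).mean()
        var_stair = np.var(np.vstack(stair_runs), axis=0).mean()
        assert var_spark < var_stair


class TestSeedRegression:
    def _training(self, grid, n=80, seed=0):
        rng = np.random.default_rng(seed)
        base = np.array([30.0 - 0.25 * (p.x**2 + p.y**2) ** 0.5 for p in grid.points])
        rows = base + rng.normal(0, 2, size=(n, 1)) + rng.normal(0, 1, (n, len(grid)))
        return rows

    def test_constant_training_reproduced(self, sector_map):
        rows = np.full((60, 66), 27.0)
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_seed_regression(rows, sector_map)
        pred = model.predict(np.full(6, 27.0))
        np.testing.assert_allclose(pred, 27.0, atol=1e-4)

    def test_seed_self_prediction_identity(self, sector_map):
        model = fit_seed_regression(self._training(sector_map.grid), sector_map)
        seed_vals = np.array([20.0, 25.0, 22.0, 28.0, 24.0, 26.0])
        pred = model.predict(seed_vals)
        # Seed locations are in the design: they predict themselves exactly.
        for pos, idx in enumerate(model.seed_indices):
            assert pred[idx] == pytest.approx(seed_vals[pos], abs=1e-6)

    def test_beats_grand_mean_baseline(self, sector_map):
        train = self._training(sector_map.grid, n=100, seed=1)
        test = self._training(sector_map.grid, n=40, seed=2)
        model = fit_seed_regression(train, sector_map)
        idx = list(model.seed_indices)
        pred = np.vstack([model.predict(row[idx]) for row in test])
        rmse_model = np.sqrt(np.mean((pred - test) ** 2))
        rmse_mean = np.sqrt(np.mean((train.mean(axis=0) - test) ** 2))
        assert rmse_model < rmse_mean

    def test_too_few_fields_rejected(self, sector_map):
        with pytest.raises(ValueError, match="50"):
            fit_seed_regression(np.zeros((10, 66)), sector_map)


class TestCatchTrials:
    def test_zero_fp_rate_observed_zero(self, grid66, rng):
        obs = Observer(
            "c", "normal", 50.0,
            TrueField(grid66, np.full(66, 30.0)),
            ResponseParams(fp_rate=0.0),
        )
        rates, _ = catch_trials(CatchSchedule(n_fp=50), obs, rng, HFA)
        assert rates["fp"] == 0.0

    def test_spark_schedule_has_no_fn(self, grid66, rng):
        obs = Observer(
            "c", "normal", 50.0,
            TrueField(grid66, np.full(66, 30.0)), ResponseParams(),
        )
        rates, _ = catch_trials(CatchSchedule.spark_default(), obs, rng, TWINFIELD2)
        assert rates["fn"] is None
        assert rates["fp"] is not None and rates["fl"] is not None

    def test_rates_converge_to_configured(self, grid66):
        params = ResponseParams(fp_rate=0.10, fn_rate=0.08, fl_rate=0.20)
        obs = Observer(
            "c", "normal", 50.0,
            TrueField(grid66, np.full(66, 30.0)), params,
        )
        rng = np.random.default_rng(3)
        rates, _ = catch_trials(
            CatchSchedule(n_fp=1000, n_fn=1000, n_fl=1000), obs, rng, HFA
        )
        for key, p in (("fp", 0.10), ("fn", 0.08), ("fl", 0.20)):
            tol = 3 * np.sqrt(p * (1 - p) / 1000)
            assert rates[key] == pytest.approx(p, abs=tol)
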