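import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perisim.agis import agis_score
from perisim.geometry import sector_of
from perisim.indices import pattern_deviation
from perisim.observer_sim import (
    CohortConfig,
    HillParams,
    Observer,
    ResponseParams,
    TrueField,
    add_diffuse_loss,
    add_focal_defect,
    load_cohort,
    normal_field,
    observer_from_dict,
    observer_to_dict,
    p_seen,
    respond,
    save_cohort,
    simulate_cohort,
)


class TestNormalField:
    def test_determinism(self, grid30):
        a = normal_field(grid30, 50, seed=7)
        b = normal_field(grid30, 50, seed=7)
        np.testing.assert_array_equal(a.sensitivity, b.sensitivity)

    def test_center_has_highest_expectation(self, grid30):
        hill = HillParams()
        exps = [hill.expected(p, 50) for p in grid30.points]
        center = min(
            range(len(grid30)),
            key=lambda i: grid30.points[i].x ** 2 + grid30.points[i].y ** 2,
        )
        assert exps[center] == max(exps)

    def test_mean_matches_closed_form(self, grid30):
        # Analytic expectation of the field mean; noise terms average out.
        hill = HillParams()
        expected = np.mean([hill.expected(p, 50) for p in grid30.points])
        means = [
            float(np.mean(normal_field(grid30, 50, seed=s).sensitivity))
            for s in range(30)
        ]
        # SE of one field mean: quadrant offsets (shared) dominate.
        se_one = np.sqrt(hill.region_sd**2 / 4 + hill.white_sd**2 / 76)
        tol = 4 * se_one / np.sqrt(len(means))
        assert np.mean(means) == pytest.approx(expected, abs=tol)

    def test_negative_age_rejected(self, grid30):
        with pytest.raises(ValueError):
            normal_field(grid30, -1, seed=0)


class TestFocalDefect:
    def test_depth_zero_unchanged(self, grid66):
        fld = normal_field(grid66, 50, seed=1)
        out = add_focal_defect(fld, "superior_nasal", 0.0)
        np.testing.assert_array_equal(out.sensitivity, fld.sensitivity)

    def test_locality_sharp_edge(self, grid66):
        fld = TrueField(grid66, np.full(66, 30.0))
        out = add_focal_defect(fld, "superior_nasal", 30.0, edge_sd=0.0)
        for p, before, after in zip(
            grid66.points, fld.sensitivity, out.sensitivity
        ):
            if sector_of(p) == "superior_nasal":
                assert after == pytest.approx(before - 30.0)
            else:
                assert after == pytest.approx(before)

    def test_never_increases_sensitivity(self, grid66):
        fld = normal_field(grid66, 60, seed=3)
        out = add_focal_defect(fld, "inferior_arcuate", 15.0, seed=4)
        assert np.all(out.sensitivity <= fld.sensitivity + 1e-12)

    def test_no_bleed_across_nasal_midline(self, grid66):
        fld = TrueField(grid66, np.full(66, 30.0))
        out = add_focal_defect(fld, "superior_nasal", 30.0, edge_sd=3.0)
        for p, after in zip(grid66.points, out.sensitivity):
            if p.x < 0 and p.y < 0:
                assert after == pytest.approx(30.0)

    def test_deep_defect_detected_by_agis(self, grid66):
        hill = HillParams(region_sd=0.0, white_sd=0.0)
        fld = normal_field(grid66, 50, seed=0, hill=hill)
        out = add_focal_defect(fld, "superior_nasal", 30.0)
        td = out.sensitivity - fld.sensitivity
        result = agis_score(td, grid66)
        assert result.score >= 1

    def test_unknown_sector(self, grid66):
        fld = normal_field(grid66, 50, seed=1)
        with pytest.raises(ValueError):
            add_focal_defect(fld, "parafoveal", 10.0)


class TestDiffuseLoss:
    def test_zero_unchanged(self, grid66):
        fld = normal_field(grid66, 50, seed=1)
        np.testing.assert_array_equal(
            add_diffuse_loss(fld, 0.0).sensitivity, fld.sensitivity
        )

    def test_ms_drops_exactly(self, grid66):
        fld = normal_field(grid66, 50, seed=1)
        out = add_diffuse_loss(fld, 5.0)
        assert float(np.mean(fld.sensitivity - out.sensitivity)) == pytest.approx(5.0)

    def test_pattern_deviation_removes_general_height(self, grid66):
        fld = normal_field(grid66, 50, seed=1)
        td = fld.sensitivity - np.mean(fld.sensitivity)
        np.testing.assert_allclose(
            pattern_deviation(td - 5.0), pattern_deviation(td), atol=1e-12
        )


class TestResponseModel:
    def test_threshold_stimulus_is_half_seen(self):
        params = ResponseParams(fp_rate=0.0, fn_rate=0.0)
        assert p_seen(25.0, 25.0, params) == pytest.approx(0.5)

    def test_bright_limit_is_one_minus_fn(self):
        params = ResponseParams(fp_rate=0.0, fn_rate=0.05)
        assert p_seen(-1e6, 25.0, params) == pytest.approx(0.95)

    def test_dim_limit_is_fp(self):
        params = ResponseParams(fp_rate=0.07, fn_rate=0.0)
        assert p_seen(1e6, 25.0, params) == pytest.approx(0.07)

    @given(
        st.floats(-5, 45),
        st.floats(-5, 45),
        st.floats(0, 40),
    )
    @settings(max_examples=50)
    def test_monotone_and_bounded(self, s1, s2, sens):
        params = ResponseParams()
        lo, hi = sorted((s1, s2))
        p_hi = p_seen(lo, sens, params)
        p_lo = p_seen(hi, sens, params)
        assert p_lo <= p_hi + 1e-12
        for p in (p_lo, p_hi):
            assert params.fp_rate - 1e-12 <= p <= 1 - params.fn_rate + 1e-12

    def test_monte_carlo_matches_binomial_oracle(self, grid66, rng):
        params = ResponseParams(fp_rate=0.05, fn_rate=0.05)
        obs = Observer(
            "mc", "normal", 50.0,
            TrueField(grid66, np.full(66, 25.0)), params,
        )
        stim = 24.0
        p = p_seen(stim, 25.0, params)
        n = 10_000
        hits = sum(respond(stim, 0, obs, rng) for _ in range(n))
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert hits / n == pytest.approx(p, abs=tol)

    def test_off_grid_location_rejected(self, grid66, rng):
        obs = Observer(
            "x", "normal", 50.0, TrueField(grid66, np.full(66, 25.0)),
            ResponseParams(),
        )
        with pytest.raises(IndexError):
            respond(20.0, 66, obs, rng)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ResponseParams(fp_rate=1.2)


class TestCohorts:
    def test_group_sizes(self):
        g = simulate_cohort(CohortConfig(group="glaucoma", n_subjects=39, seed=1))
        c = simulate_cohort(CohortConfig(group="cataract", n_subjects=31, seed=1))
        assert len(g) == 39 and len(c) == 31

    def test_same_seed_identical(self):
        cfg = CohortConfig(group="glaucoma", n_subjects=5, seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for oa, ob in zip(a, b):
            np.testing.assert_array_equal(
                oa.true_field.sensitivity, ob.true_field.sensitivity
            )
            assert oa.age == ob.age and oa.meta == ob.meta

    def test_cataract_receives_only_diffuse_loss(self):
        for obs in simulate_cohort(
            CohortConfig(group="cataract", n_subjects=5, seed=2)
        ):
            assert "diffuse_loss" in obs.meta
            assert "defect_sectors" not in obs.meta

    def test_glaucoma_defect_spectrum(self):
        cohort = simulate_cohort(
            CohortConfig(group="glaucoma", n_subjects=39, seed=3)
        )
        n_defects = [len(o.meta["defect_sectors"]) for o in cohort]
        assert min(n_defects) == 0 and max(n_defects) >= 2

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CohortConfig(group="amd", n_subjects=5, seed=0)
        with pytest.raises(ValueError):
            CohortConfig(group="normal", n_subjects=0, seed=0)

    def test_serialization_round_trip(self, tmp_path):
        cohort = simulate_cohort(
            CohortConfig(group="glaucoma", n_subjects=3, seed=4)
        )
        path = tmp_path / "cohort.json"
        save_cohort(cohort, path)
        loaded = load_cohort(path)
        for a, b in zip(cohort, loaded):
            assert a.uid == b.uid and a.age == b.age
            np.testing.assert_array_equal(
                a.true_field.sensitivity, b.true_field.sensitivity
            )
            assert a.params == b.params

    def test_observer_dict_round_trip(self, grid66):
        obs = Observer(
            "o1", "normal", 44.0,
            TrueField(grid66, np.linspace(10, 35, 66)), ResponseParams(),
        )
        back = observer_from_dict(observer_to_dict(obs))
        assert back.uid == obs.uid
        np.testing.assert_array_equal(
            back.true_field.sensitivity, obs.true_field.sensitivity
        )
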