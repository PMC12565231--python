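"""Synthetic cohorts: weather, generation, closed-form truth, presets."""

import math
from dataclasses import replace

import numpy as np
import pytest

from parademog import (
    PRESETS,
    SEASONS,
    SurvivalModel,
    SyntheticConfig,
    build_cohort_schedule,
    compute_life_table,
    generate_cohort,
    generate_weather,
    get_preset,
    net_reproductive_rate,
    true_schedules,
)

from conftest import constant_weather


class TestWeather:
    def test_ordering_invariants_every_day(self):
        for season in ("spring", "summer", "autumn"):
            w = generate_weather(season, 60, seed=1)
            assert np.all(w.tmin <= w.tmean) and np.all(w.tmean <= w.tmax)
            assert np.all(w.rhmin <= w.rhmean) and np.all(w.rhmean <= w.rhmax)
            assert w.rhmin.min() >= 0 and w.rhmax.max() <= 100

    def test_zero_noise_reduces_to_means(self):
        clim = replace(
            SEASONS["spring"],
            se_tmean=0.0, se_tmax=0.0, se_tmin=0.0,
            se_rhmean=0.0, se_rhmax=0.0, se_rhmin=0.0,
        )
        w = generate_weather(clim, 10, seed=0)
        assert np.allclose(w.tmean, clim.tmean)
        assert np.allclose(w.tmax, clim.tmax)
        assert np.allclose(w.rhmin, clim.rhmin)

    def test_autumn_tmin_calibration(self):
        """Mean of Tmin sample means over many draws sits near 5.3 degC."""
        means = [
            generate_weather("autumn", 31, seed=s).tmin.mean() for s in range(500)
        ]
        assert np.mean(means) == pytest.approx(5.3, abs=0.5)

    def test_sample_mean_se_matches_summary(self):
        """SD of the 31-day Tmin mean across draws approximates the stated SE."""
        means = [
            generate_weather("autumn", 31, seed=s).tmin.mean() for s in range(500)
        ]
        # clipping of offsets distorts slightly; same order of magnitude
        assert np.std(means) == pytest.approx(0.5, abs=0.25)

    def test_seeded_reproducibility(self):
        w1 = generate_weather("summer", 40, seed=9)
        w2 = generate_weather("summer", 40, seed=9)
        np.testing.assert_array_equal(w1.tmin, w2.tmin)


class TestGenerateCohort:
    def test_zero_fecundity_means_no_offspring(self):
        cfg = SyntheticConfig(cohort_id="z", n_females=20, fecundity_a=0.0, max_age=50)
        recs = generate_cohort(cfg, constant_weather("lab", 50), seed=1)
        assert all(e.daughters == e.sons == 0 for r in recs for e in r.exposures)
        lt = compute_life_table(build_cohort_schedule(recs))
        assert net_reproductive_rate(lt) == 0.0

    def test_exposure_cutoff_respected(self):
        cfg = SyntheticConfig(
            cohort_id="c", n_females=40, exposure_cutoff=19, max_age=60,
            survival=SurvivalModel("geometric", p=0.02),
        )
        recs = generate_cohort(cfg, constant_weather("lab", 60), seed=2)
        ages = [e.maternal_age for r in recs for e in r.exposures]
        assert ages and max(ages) <= 19

    def test_exposures_every_other_day_from_day_two(self):
        cfg = SyntheticConfig(cohort_id="c", n_females=10, max_age=30)
        recs = generate_cohort(cfg, constant_weather("lab", 30), seed=3)
        for r in recs:
            for e in r.exposures:
                assert e.maternal_age >= 2 and e.maternal_age % 2 == 0
                assert e.maternal_age < r.age_at_death

    def test_records_pass_cohort_invariants(self):
        for (line, setting), cfg in PRESETS.items():
            w = generate_weather(SEASONS[setting], cfg.max_age, seed=4)
            recs = generate_cohort(cfg, w, seed=5)
            sched = build_cohort_schedule(recs)  # validates internally
            assert sched.n0 == cfg.n_females

    def test_large_cohort_matches_true_schedules(self):
        """Empirical lx and mx track the closed-form truth pointwise."""
        cfg, _ = get_preset("lab", "bip")
        cfg = replace(cfg, n_females=5000)
        w = constant_weather("lab", cfg.max_age)
        recs = generate_cohort(cfg, w, seed=6)
        truth = true_schedules(cfg, w)
        lt = compute_life_table(build_cohort_schedule(recs))
        k = lt.lx.size
        visible = truth.lx[:k] > 0.1
        assert np.max(np.abs(lt.lx[visible] - truth.lx[:k][visible])) < 0.05
        rel_mx = np.abs(lt.mx[visible] - truth.mx[:k][visible]) / np.maximum(
            truth.mx[:k][visible], 1e-9
        )
        on_schedule = truth.mx[:k][visible] > 0
        assert np.median(rel_mx[on_schedule]) < 0.05


class TestTrueSchedules:
    def test_geometric_single_age_hand_computation(self):
        # survive day 0->1 with prob 0.5; one exposure at age 1 yielding
        # 4 expected offspring, all female: R0 = 0.5*4 = 2, T = 1, r = ln 2
        cfg = SyntheticConfig(
            cohort_id="g",
            survival=SurvivalModel("geometric", p=0.5),
            fecundity_a=4.0 * math.e * 1.0,  # f(1) = a*1*e^{-b} = 4 with b = 1
            fecundity_b=1.0,
            p_female=1.0,
            exposure_start=1,
            exposure_step=100,
            max_age=50,
        )
        truth = true_schedules(cfg, constant_weather("lab", 50))
        assert truth.params_ratio.R0 == pytest.approx(2.0, rel=1e-9)
        assert truth.params_ratio.T == pytest.approx(1.0, rel=1e-9)
        assert truth.params_lotka.r == pytest.approx(math.log(2), abs=1e-9)

    def test_fecundity_collapse_pushes_T_to_first_exposure(self):
        cfg = SyntheticConfig(cohort_id="b", fecundity_b=8.0, max_age=40)
        truth = true_schedules(cfg, constant_weather("lab", 40))
        assert truth.params_ratio.T == pytest.approx(cfg.exposure_start, abs=1e-4)

    def test_lotka_r_equals_leslie_eigenvalue(self):
        for setting in ("lab", "spring", "summer"):
            cfg, _ = get_preset(setting, "tsl")
            w = constant_weather(setting, cfg.max_age)
            truth = true_schedules(cfg, w)
            r = truth.params_lotka.r
            lx, mx = truth.lx, truth.mx
            p = lx[1:] / np.maximum(lx[:-1], 1e-300)
            k = lx.size
            A = np.zeros((k - 1, k - 1))
            A[0, :] = p * mx[1:]
            A[np.arange(1, k - 1), np.arange(k - 2)] = p[:-1]
            lam_dom = max(abs(np.linalg.eigvals(A)))
            assert abs(math.exp(r) - lam_dom) < 1e-8

    def test_cold_threshold_silences_fecundity(self):
        # default ramp: modifier is 0 at or below 10 degC Tmin
        cfg = SyntheticConfig(cohort_id="cold", fecundity_a=3.0, max_age=30)
        w = constant_weather("autumn", 30)  # Tmin 5.3
        truth = true_schedules(cfg, w)
        assert truth.mx.sum() == 0
        assert truth.params_ratio is None


class TestPresets:
    def test_all_presets_valid(self):
        assert len(PRESETS) == 8
        for cfg in PRESETS.values():
            assert cfg.n_females >= 20
            assert cfg.p_female > 0
            days = cfg.exposure_days()
            assert days[0] == 2 and np.all(np.diff(days) == 2)

    def test_semi_field_cutoff(self):
        for (line, setting), cfg in PRESETS.items():
            if setting == "lab":
                assert cfg.exposure_cutoff is None
            else:
                assert cfg.exposure_cutoff == 19

    def test_seasonal_R0_magnitudes(self):
        """True R0 at mean weather reproduces the seasonal contrasts:
        warm seasons ~20, lab largest, autumn straddling 1 by line."""
        R0 = {}
        for (line, setting), cfg in PRESETS.items():
            w = constant_weather(setting, cfg.max_age)
            R0[(line, setting)] = true_schedules(cfg, w).params_ratio.R0
        assert R0[("bip", "lab")] > R0[("tsl", "lab")] > 50
        for line in ("bip", "tsl"):
            assert 15 < R0[(line, "spring")] < 30
            assert 15 < R0[(line, "summer")] < 30
        assert R0[("bip", "autumn")] > 1 > R0[("tsl", "autumn")]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            get_preset("winter", "bip")


class TestRecovery:
    def test_parameter_recovery_at_n200(self):
        """Median error of r under 0.02/day, R0 within 10%, warm presets."""
        rng = np.random.default_rng(77)
        for setting in ("lab", "spring"):
            cfg, clim = get_preset(setting, "bip")
            cfg = replace(cfg, n_females=200)
            r_errs, R0_rel = [], []
            for _ in range(25):
                w = generate_weather(clim, cfg.max_age, seed=rng)
                truth = true_schedules(cfg, w).params_ratio
                recs = generate_cohort(cfg, w, seed=rng)
                lt = compute_life_table(build_cohort_schedule(recs))
                from parademog import population_parameters

                est = population_parameters(lt, mode="ratio")
                r_errs.append(abs(est.r - truth.r))
                R0_rel.append(abs(est.R0 - truth.R0) / truth.R0)
            assert np.median(r_errs) <= 0.02
            assert np.median(R0_rel) <= 0.10
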