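"""Feeding module: conversion efficiency, consumption, metabolic rate,
energy-budget cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from leatherback import (
    ConversionParams,
    MetabolicParams,
    assay_summary,
    body_energy,
    consumption_from_energy_budget,
    consumption_rate,
    cumulative_consumption,
    fit_beta,
    k1_at_mass,
    mass_at_age,
    metabolic_rate,
)
from leatherback.growth import growth_rate
from leatherback.synthetic import CohortSimSpec, simulate_cohort, simulate_energy_assays


class TestK1:
    def test_zero_at_asymptote(self, gp, cp):
        assert k1_at_mass(gp.w_inf, gp, cp) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mass, expected", [
        (0.046, 1 - (0.046 / 319) ** 0.0328),   # ~0.252
        (1.0, 1 - (1.0 / 319) ** 0.0328),       # ~0.172
    ])
    def test_direct_evaluation(self, gp, cp, mass, expected):
        assert k1_at_mass(mass, gp, cp) == pytest.approx(expected, rel=1e-12)

    def test_reference_values(self, gp, cp):
        assert k1_at_mass(0.046, gp, cp) == pytest.approx(0.252, abs=5e-4)
        assert k1_at_mass(1.0, gp, cp) == pytest.approx(0.172, abs=5e-4)

    def test_decreasing_in_mass(self, gp, cp):
        w = np.linspace(0.05, 319, 500)
        assert np.all(np.diff(k1_at_mass(w, gp, cp)) < 0)

    def test_domain_errors(self, gp, cp):
        with pytest.raises(ValueError):
            k1_at_mass(-1.0, gp, cp)
        with pytest.raises(ValueError):
            k1_at_mass(gp.w_inf * 1.01, gp, cp)


class TestFitBeta:
    def test_noiseless_exact_recovery(self, gp, cp):
        _, records = simulate_cohort(CohortSimSpec(
            seed=3, k_individual_sd=0.0, mass_obs_sd=0.0, food_obs_sd=0.0))
        fit = fit_beta(records, gp)
        assert fit.beta == pytest.approx(cp.beta, abs=1e-6)
        assert fit.n_excluded == 0

    def test_noisy_recovery_within_two_se(self, gp, cp):
        _, records = simulate_cohort(CohortSimSpec(seed=17))
        fit = fit_beta(records, gp)
        assert abs(fit.beta - cp.beta) <= 2 * fit.se

    def test_bad_records_excluded_with_warning(self, gp):
        _, records = simulate_cohort(CohortSimSpec(
            seed=3, k_individual_sd=0.0, mass_obs_sd=0.0, food_obs_sd=0.0))
        records.loc[records.index[0], "food_wet_kg"] = 0.0
        with pytest.warns(UserWarning, match="excluding"):
            fit = fit_beta(records, gp)
        assert fit.n_excluded == 1

    def test_too_few_records_rejected(self, gp):
        df = pd.DataFrame({
            "animal_id": ["a"] * 5, "age_start_yr": np.arange(5) / 52,
            "age_end_yr": np.arange(1, 6) / 52,
            "mass_start_kg": np.linspace(1, 2, 5),
            "mass_end_kg": np.linspace(1.1, 2.1, 5),
            "food_wet_kg": np.ones(5)})
        with pytest.raises(ValueError):
            fit_beta(df, gp)


class TestConsumptionRate:
    def test_adult_limit_closed_form(self, gp, cp):
        # k * W_inf / beta in diet units, x10 for jellyfish
        limit = cp.jelly_factor * gp.k * gp.w_inf / cp.beta
        assert consumption_rate(200.0, gp, cp) == pytest.approx(limit, rel=1e-6)
        # ~29.1 t jellyfish per year ~ 80 kg per day
        assert limit / 1000 == pytest.approx(29.1, abs=0.1)
        assert limit / 365 == pytest.approx(80, abs=1)

    def test_continuity_near_asymptote(self, gp, cp):
        # general formula at W = 0.999 W_inf agrees with the analytic limit
        from leatherback.growth import solve_t0
        t999 = gp.t0 - np.log(1 - 0.999 ** (1 / gp.b)) / gp.k
        general = consumption_rate(t999, gp, cp, units="diet")
        limit = gp.k * gp.w_inf / cp.beta
        assert general == pytest.approx(limit, rel=2e-3)

    def test_adult_250kg_daily_ration(self, gp, cp):
        t250 = gp.t0 - np.log(1 - (250 / gp.w_inf) ** (1 / gp.b)) / gp.k
        per_day = consumption_rate(t250, gp, cp) / 365
        assert per_day == pytest.approx(65, abs=2)

    def test_hatchling_daily_ration(self, gp, cp):
        diet_g_day = consumption_rate(0.0, gp, cp, units="diet") * 1000 / 365
        assert diet_g_day == pytest.approx(9, abs=0.5)
        jelly_kg_day = consumption_rate(0.0, gp, cp) / 365
        assert jelly_kg_day == pytest.approx(0.09, abs=0.005)

    def test_positive_and_finite_at_all_ages(self, gp, cp):
        t = np.linspace(0, 500, 2000)
        f = consumption_rate(t, gp, cp)
        assert np.all(np.isfinite(f)) and np.all(f > 0)

    def test_units_argument(self, gp, cp):
        assert consumption_rate(5.0, gp, cp, units="jellyfish") == pytest.approx(
            cp.jelly_factor * consumption_rate(5.0, gp, cp, units="diet"))
        with pytest.raises(ValueError):
            consumption_rate(5.0, gp, cp, units="squid")


class TestCumulativeConsumption:
    def test_lifetime_total(self, gp, cp):
        assert cumulative_consumption(0, 40, gp, cp) == pytest.approx(1014, rel=0.1)

    def test_to_maturity_total(self, gp, cp):
        total = cumulative_consumption(0, 16, gp, cp)
        assert total >= 310 * 0.9
        assert 291 * 0.9 <= total <= 332 * 1.1

    def test_empty_interval(self, gp, cp):
        assert cumulative_consumption(7.0, 7.0, gp, cp) == 0.0

    def test_additive_over_adjacent_intervals(self, gp, cp):
        whole = cumulative_consumption(0, 40, gp, cp)
        split = (cumulative_consumption(0, 16, gp, cp)
                 + cumulative_consumption(16, 40, gp, cp))
        assert split == pytest.approx(whole, rel=1e-6)

    def test_reversed_interval_rejected(self, gp, cp):
        with pytest.raises(ValueError):
            cumulative_consumption(10, 5, gp, cp)

    def test_growth_equals_k1_weighted_intake(self, gp, cp):
        # conservation: mass gain over [t1,t2] = integral of F_diet * K1 dt
        t1, t2 = 1.0, 10.0
        gain, _ = quad(lambda u: consumption_rate(u, gp, cp, units="diet")
                       * k1_at_mass(mass_at_age(u, gp), gp, cp), t1, t2,
                       epsrel=1e-10, limit=200)
        assert gain == pytest.approx(
            mass_at_age(t2, gp) - mass_at_age(t1, gp), rel=1e-6)

    def test_unit_consistency_with_energy(self, gp, cp):
        # jellyfish total is exactly 10x the diet total; the energy-equivalent
        # totals then agree to the <=1% slack of the fixed conversion factor
        diet_total, _ = quad(lambda u: consumption_rate(u, gp, cp, units="diet"),
                             0, 40, epsrel=1e-9, limit=200)
        jelly_total = cumulative_consumption(0, 40, gp, cp) * 1000
        assert jelly_total == pytest.approx(cp.jelly_factor * diet_total, rel=1e-6)
        assert diet_total * cp.diet_energy_wm == pytest.approx(
            jelly_total * cp.jelly_energy_wm, rel=0.01)


class TestMetabolicRate:
    def test_hatchling_rate(self, gp, cp):
        assert metabolic_rate(0.0, gp, cp) == pytest.approx(2.1, abs=0.1)

    def test_adult_limit(self, gp, cp):
        from leatherback.params import SECONDS_PER_YEAR
        expected = (gp.k * gp.w_inf / cp.beta) * cp.diet_energy_wm * 1000 \
            * 0.63 * 1000 / SECONDS_PER_YEAR / gp.w_inf
        assert metabolic_rate(300.0, gp, cp) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.37, abs=0.01)

    def test_scaling_with_available_energy(self, gp, cp):
        half = MetabolicParams(total_available=0.315)
        full = MetabolicParams(total_available=0.63)
        assert metabolic_rate(3.0, gp, cp, half) == pytest.approx(
            metabolic_rate(3.0, gp, cp, full) / 2)

    def test_monotone_decline_past_first_half_year(self, gp, cp):
        t = np.linspace(0.5, 30, 500)
        mr = metabolic_rate(t, gp, cp)
        assert np.all(np.diff(mr) < 0)
        # beyond that the curve flattens onto the adult limit (non-increasing
        # within floating-point noise)
        t_late = np.linspace(30, 60, 200)
        assert np.all(np.diff(metabolic_rate(t_late, gp, cp)) < 1e-6)
        # hatchling > juvenile > adult mass-specific rate
        assert metabolic_rate(0.0, gp, cp) > metabolic_rate(7.0, gp, cp) \
            > metabolic_rate(40.0, gp, cp)


class TestBodyEnergy:
    def test_adult_total(self):
        assert body_energy(319, 0.712, 21.1) == pytest.approx(1938, abs=1)

    def test_all_water_limit(self):
        assert body_energy(319, 1 - 1e-12, 21.1) == pytest.approx(0.0, abs=1e-6)

    def test_linearity_in_mass(self):
        assert body_energy(638, 0.712, 21.1) == pytest.approx(
            2 * body_energy(319, 0.712, 21.1))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            body_energy(319, 1.2, 21.1)


class TestEnergyBudget:
    def test_cross_check_tonnage(self):
        t = consumption_from_energy_budget(1938, 0.0328, 0.2)
        assert t == pytest.approx(295, abs=2)
        assert 291 <= t <= 332

    def test_inverse_proportionality_in_beta(self):
        assert consumption_from_energy_budget(1938, 2 * 0.0328) == pytest.approx(
            consumption_from_energy_budget(1938, 0.0328) / 2)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            consumption_from_energy_budget(1938, 0.0)


class TestAssaySummary:
    def test_simulated_means_within_two_se(self):
        assays = simulate_energy_assays(1000, seed=8)
        summ = assay_summary(assays)
        assert abs(summ.mean_energy - 20.16) <= 2 * 0.58 / np.sqrt(1000)
        assert summ.mean_dry_fraction == pytest.approx(0.10, abs=0.002)
        assert summ.sd_energy == pytest.approx(0.58, rel=0.15)

    def test_single_assay_sd_flagged(self):
        assays = simulate_energy_assays(1, seed=0)
        with pytest.warns(UserWarning, match="SD undefined"):
            summ = assay_summary(assays)
        assert np.isnan(summ.sd_energy)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assay_summary(pd.DataFrame(columns=["sample_id", "dry_fraction",
                                                "energy_kj_per_g_dm"]))


class TestConversionParamsValidation:
    def test_inconsistent_jelly_factor_rejected(self):
        with pytest.raises(ValueError):
            ConversionParams(jelly_factor=5.0)

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ConversionParams(beta=1.5)
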