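"""Generator structure: determinism, ranges, gradient statistics, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dryq10 import GeneratorConfig, generate_cohort, source_rates
from dryq10.config import ConfigError
from dryq10.synthetic import _rngs, generate_sites, generate_soils, generate_truth


class TestCohortShape:
    def test_default_dimensions(self, cohort):
        assert len(cohort.sites) == 30
        assert len(cohort.samples) == 30 * 2 * 4
        assert len(cohort.incubation) == 30 * 2 * 4 * 6

    def test_aridity_and_mat_within_configured_ranges(self, cohort):
        assert cohort.sites["aridity_index"].between(0.04, 0.59).all()
        assert cohort.sites["mat"].between(-1.2, 10.0).all()

    def test_six_ascending_temperature_steps_per_jar(self, cohort):
        grp = cohort.incubation.groupby("sample_id")["temperature_C"]
        assert (grp.count() == 6).all()
        assert sorted(cohort.incubation["temperature_C"].unique()) == [
            5.0, 10.0, 15.0, 20.0, 25.0, 30.0]

    def test_concentrations_nonnegative(self, cohort):
        assert (cohort.incubation["co2_initial_ppm"] >= 0).all()
        assert (cohort.incubation["co2_final_ppm"] >= 0).all()
        assert (cohort.samples[["soc", "sic", "oc_pom", "oc_maom"]] >= 0).all().all()
        assert cohort.samples["ph"].between(4, 11).all()


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ta, tb in zip((a.sites, a.samples, a.incubation, a.truth),
                          (b.sites, b.samples, b.incubation, b.truth)):
            assert ta.to_csv(index=False) == tb.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(seed=1))
        b = generate_cohort(GeneratorConfig(seed=2))
        assert not a.sites["aridity_index"].equals(b.sites["aridity_index"])


class TestConfigValidation:
    def test_too_few_sites_rejected(self):
        with pytest.raises(ConfigError, match="3 sites"):
            GeneratorConfig(n_sites=2).validate()

    def test_empty_moisture_rejected(self):
        with pytest.raises(ConfigError, match="moisture"):
            GeneratorConfig(moisture_levels=()).validate()

    def test_bad_sic_contribution_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(sic_contribution_20c=(0.0, 0.1)).validate()


class TestSourceRates:
    def test_flat_response_at_zero_k(self):
        row = {"true_b_soc": 0.05, "true_k_soc": 0.0,
               "true_b_sic": 0.01, "true_k_sic": 0.0}
        r_soc, _ = source_rates(row, 30.0)
        assert r_soc == pytest.approx(0.05)

    def test_exponential_doubling(self):
        row = {"true_b_soc": 0.05, "true_k_soc": 0.0693,
               "true_b_sic": 0.01, "true_k_sic": 0.0}
        r_soc, _ = source_rates(row, 10.0)
        assert r_soc == pytest.approx(0.1, abs=1e-4)

    def test_contribution_calibration_algebra(self):
        # with c = 0.072 and r_soc(20) = 1.0 the SIC rate is c/(1-c)
        cfg = GeneratorConfig(seed=3, rate_lognorm_sd=0.0, q10_noise_sd=0.0)
        cohort = generate_cohort(cfg)
        row = cohort.truth[cohort.truth["sample_id"] == "S01_topsoil_field"].iloc[0]
        r_soc, r_sic = source_rates(row, 20.0)
        assert r_soc == pytest.approx(1.0, rel=1e-9)
        assert r_sic == pytest.approx(0.072 / (1 - 0.072), rel=1e-9)
        assert r_sic == pytest.approx(0.0776, abs=5e-5)

    def test_missing_ground_truth_raises(self):
        with pytest.raises(ValueError, match="ground-truth"):
            source_rates({"true_b_soc": 0.05}, 20.0)


def test_zero_source_rates_leave_headspace_flushed(run_config):
    """With B = 0 for both sources the final CO2 equals the (flushed) initial."""
    cfg = dataclasses.replace(run_config.generator, seed=11).noiseless()
    cohort = generate_cohort(cfg)
    truth = cohort.truth.copy()
    truth[["true_b_soc", "true_b_sic"]] = 0.0
    from dryq10.synthetic import synthesize_incubation
    inc = synthesize_incubation(truth, cohort.samples, run_config.protocol,
                                run_config.end_members,
                                np.random.default_rng(0), cfg)
    np.testing.assert_array_equal(inc["co2_final_ppm"], inc["co2_initial_ppm"])


def test_true_q10_slope_matches_generating_slope():
    """Monte-Carlo: the OLS slope of true Q10 on AI averages to the input slope."""
    slopes_soc, slopes_sic = [], []
    for seed in range(200):
        cfg = GeneratorConfig(seed=seed)
        rngs = _rngs(seed)
        sites = generate_sites(cfg, rngs["sites"])
        soils = generate_soils(cfg, sites, rngs["soils"])
        truth = generate_truth(cfg, soils, rngs["q10"])
        top = truth[(truth["depth"] == "topsoil") & (truth["moisture"] == "field")]
        slopes_soc.append(stats.linregress(
            top["aridity_index"], top["true_q10_soc"]).slope)
        slopes_sic.append(stats.linregress(
            top["aridity_index"], top["true_q10_sic"]).slope)
    assert np.mean(slopes_soc) == pytest.approx(4.7, abs=0.5)
    assert np.mean(slopes_sic) == pytest.approx(-3.9, abs=0.5)


def test_ph_and_sic_decline_with_aridity_index():
    """Structural invariant: r(pH, AI) < 0 and r(SIC, AI) < 0 (p < 0.05)
    in at least 90% of default cohorts."""
    hits = 0
    n_cohorts = 100
    for seed in range(n_cohorts):
        cfg = GeneratorConfig(seed=seed)
        rngs = _rngs(seed)
        sites = generate_sites(cfg, rngs["sites"])
        soils = generate_soils(cfg, sites, rngs["soils"])
        top = soils[soils["depth"] == "topsoil"]
        r_ph, p_ph = stats.pearsonr(top["ph"], top["aridity_index"])
        r_sic, p_sic = stats.pearsonr(top["sic"], top["aridity_index"])
        if r_ph < 0 and p_ph < 0.05 and r_sic < 0 and p_sic < 0.05:
            hits += 1
    assert hits >= 0.9 * n_cohorts


def test_moisture_effect_is_linear_in_treatment_index():
    """Noiseless truth: WHC steps shift Q10 by +/- the configured increment."""
    cfg = GeneratorConfig(seed=5, q10_noise_sd=0.0)
    truth = generate_cohort(cfg).truth
    piv = truth.pivot_table(index=["site_id", "depth"], columns="moisture",
                            values="true_q10_soc")
    np.testing.assert_allclose(piv["WHC40"] - piv["WHC20"], 0.4, rtol=1e-9)
    np.testing.assert_allclose(piv["WHC60"] - piv["WHC40"], 0.4, rtol=1e-9)
    piv_sic = truth.pivot_table(index=["site_id", "depth"], columns="moisture",
                                values="true_q10_sic")
    np.testing.assert_allclose(piv_sic["WHC60"] - piv_sic["WHC20"], -0.8, rtol=1e-9)
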