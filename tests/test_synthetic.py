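"""The synthetic study generator: contracts, truths and determinism."""

import numpy as np
import pandas as pd
import pytest

from streamprod.growth import fit_growth_model, instantaneous_growth
from streamprod.scaling import standardize_temperature
from streamprod.synthetic import (
    MIN_LENGTH_MM,
    SimulationConfig,
    TaxonSpec,
    binned_length_distribution,
    simulate_chlorophyll,
    simulate_community,
    simulate_environment,
    simulate_gpp,
    simulate_growth_chambers,
    simulate_study,
    sample_surber,
)


class TestConfigValidation:
    def test_minimum_streams(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_streams=1, mean_annual_temp_C=(10.0,))

    def test_amplitude_below_freezing_guard(self):
        with pytest.raises(ValueError, match="-2"):
            SimulationConfig(
                n_streams=2, mean_annual_temp_C=(3.0, 10.0),
                temp_seasonal_amplitude_C=8.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd_log_chla=-0.1)

    def test_taxon_allometry_positive(self):
        with pytest.raises(ValueError):
            TaxonSpec("bad", lm_a=-1.0, lm_b=2.5, cohort_synchronous=False,
                      relative_abundance=1.0, mean_length_mm=3.0, sd_length_mm=1.0)


class TestEnvironment:
    def test_zero_amplitude_constant_temperature(self):
        cfg = SimulationConfig(
            n_streams=2, mean_annual_temp_C=(8.0, 20.0),
            temp_seasonal_amplitude_C=0.0, light_temp_correlation=0.0, seed=1)
        env = simulate_environment(cfg)
        for sid, mean in zip(cfg.stream_ids, cfg.mean_annual_temp_C):
            t = env.loc[env["stream_id"] == sid, "temp_C"]
            assert t.nunique() == 1
            assert t.iloc[0] == pytest.approx(mean)

    def test_annual_mean_within_half_degree(self):
        env = simulate_environment(SimulationConfig(seed=2))
        cfg = SimulationConfig(seed=2)
        for sid, mean in zip(cfg.stream_ids, cfg.mean_annual_temp_C):
            assert env.loc[env["stream_id"] == sid, "temp_C"].mean() == pytest.approx(
                mean, abs=0.5)

    def test_same_seed_bit_identical(self):
        a = simulate_environment(SimulationConfig(seed=3))
        b = simulate_environment(SimulationConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_light_temperature_correlation_calibration(self):
        """The solved phase lag delivers the target Pearson correlation:
        realized r lands in the +/-0.15 band in nearly every seed."""
        target, hits, n_seeds = 0.67, 0, 100
        for s in range(n_seeds):
            cfg = SimulationConfig(n_streams=2, mean_annual_temp_C=(6.0, 20.0),
                                   light_temp_correlation=target, seed=s)
            env = simulate_environment(cfg)
            g = env[env["stream_id"] == "st1"]
            r = np.corrcoef(g["temp_C"], g["light"])[0, 1]
            hits += 0.52 <= r <= 0.82
        assert hits >= 95

    def test_daily_coverage(self):
        env = simulate_environment(SimulationConfig(seed=0))
        counts = env.groupby("stream_id")["day"].count()
        assert (counts == 365).all()


class TestChlorophyll:
    def test_noise_free_boltzmann_ratio(self):
        """Two streams exactly one standardised-temperature unit apart have
        annual-mean chlorophyll in the ratio exp(E_chla)."""
        t_hot = 24.077  # x(24.077 C) - x(10 C) = 1.0 within rounding
        from streamprod.scaling import unstandardize_temperature
        t_hot = unstandardize_temperature(standardize_temperature(10.0) + 1.0)
        cfg = SimulationConfig(
            n_streams=2, mean_annual_temp_C=(10.0, t_hot),
            noise_sd_log_chla=0.0, noise_sd_log_chla_stream=0.0, seed=4)
        env = simulate_environment(cfg)
        chla = simulate_chlorophyll(cfg, env)
        means = chla.groupby("stream_id")["chla_mg_m2"].mean()
        assert means["st2"] / means["st1"] == pytest.approx(
            np.exp(cfg.E_chla_true), rel=1e-6)

    def test_never_negative(self):
        cfg = SimulationConfig(noise_sd_log_chla=1.0, seed=5)
        chla = simulate_chlorophyll(cfg, simulate_environment(cfg))
        assert (chla["chla_mg_m2"] > 0).all()

    def test_recovered_slope_nearly_unbiased(self):
        """Date-level noise 0.3, no stream-level scatter: the mean recovered
        Boltzmann slope over seeds stays within 0.05 of the generating
        0.53 eV."""
        from streamprod.resources import annual_chla_bootstrap, fit_chla_temperature

        slopes = []
        for s in range(60):
            cfg = SimulationConfig(noise_sd_log_chla=0.3,
                                   noise_sd_log_chla_stream=0.0, seed=s)
            chla = simulate_chlorophyll(cfg, simulate_environment(cfg))
            dists = annual_chla_bootstrap(chla, n_boot=200, seed=s)
            x = standardize_temperature(np.asarray(cfg.mean_annual_temp_C))
            est = fit_chla_temperature([dists[k] for k in cfg.stream_ids], x,
                                       n_boot=400, seed=s)
            slopes.append(est.E_mean)
        assert abs(np.mean(slopes) - 0.53) < 0.05


class TestCommunity:
    def test_bookkeeping_identity(self, small_config, small_study):
        """Stored per-taxon interval production sums exactly to the stream's
        true annual production."""
        for sid, t in small_study.truth["streams"].items():
            per_taxon = np.array(list(t["taxon_interval_production_mg_m2"].values()))
            assert per_taxon.sum() == pytest.approx(t["annual_production_mg_m2"], rel=1e-9)
            np.testing.assert_allclose(
                per_taxon.sum(axis=0), t["interval_production_mg_m2"], rtol=1e-9)

    def test_biomass_positive(self, small_study):
        assert (small_study.community["biomass_mg_m2"] > 0).all()

    def test_resource_driven_target(self, small_config, small_study):
        """With direct_temp_E = 0, true annual production is an exact
        power-law in realized annual chlorophyll."""
        cfg = small_config
        for sid, t in small_study.truth["streams"].items():
            expected = (cfg.annual_p_ref_g_m2 * 1000.0
                        * (t["annual_chla_mg_m2"] / cfg.chla_ref_mg_m2)
                        ** cfg.production_chla_exponent)
            assert t["annual_production_mg_m2"] == pytest.approx(expected, rel=1e-9)


class TestBinnedLengths:
    def test_mesh_floor_respected(self):
        lowers, probs = binned_length_distribution(0.5, 0.4)
        assert lowers.min() >= MIN_LENGTH_MM
        assert probs.sum() == pytest.approx(1.0)

    def test_probabilities_match_truncated_normal(self):
        from scipy import stats
        mu, sd = 4.0, 1.0
        lowers, probs = binned_length_distribution(mu, sd)
        # mass below the floor is excluded, the rest renormalised
        total = 1.0 - stats.norm.cdf(MIN_LENGTH_MM, mu, sd)
        p0 = (stats.norm.cdf(lowers[0] + 0.25, mu, sd)
              - stats.norm.cdf(lowers[0], mu, sd)) / total
        assert probs[0] == pytest.approx(p0, rel=1e-6)


class TestSurberSampling:
    def _one_taxon_community(self, density):
        return pd.DataFrame([{
            "stream_id": "s1", "date": "2011-06-15", "day": 166, "taxon_id": "chiro",
            "density_m2": density, "mean_mass_mg": 0.1, "biomass_mg_m2": density * 0.1,
            "mean_length_mm": 4.0, "sd_length_mm": 1.0,
        }])

    def _cfg(self, **kw):
        taxa = (TaxonSpec("chiro", 0.002, 2.6, True, 1.0, 4.0, 1.0),)
        return SimulationConfig(n_streams=2, mean_annual_temp_C=(10.0, 20.0),
                                taxa=taxa, **kw)

    def test_zero_density_zero_counts(self):
        df = sample_surber(self._one_taxon_community(0.0), self._cfg(seed=0))
        assert (df["count"] == 0).all()

    def test_expected_total_count(self):
        """Empirical mean catch over many draws within 3 SE of
        density x area x replicates."""
        density = 800.0
        cfg = self._cfg(seed=0)
        totals = []
        for s in range(300):
            df = sample_surber(self._one_taxon_community(density), cfg, seed=s)
            totals.append((df["count"] / df["split_fraction"]).sum())
        expected = density * cfg.sample_area_m2 * cfg.n_replicate_samples
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_split_fractions_from_allowed_set(self, small_study):
        assert set(small_study.samples["split_fraction"].unique()) <= {
            1.0, 0.5, 0.25, 0.125, 0.0625}

    def test_no_individuals_below_mesh(self, small_study):
        assert (small_study.samples["length_bin_mm"] >= MIN_LENGTH_MM).all()

    def test_replicate_roster_complete(self, small_study):
        per_date = small_study.samples.groupby(["stream_id", "date"])["replicate"].nunique()
        assert (per_date == small_study.config.n_replicate_samples).all()


class TestGrowthChambers:
    def test_construction_identity(self, small_study):
        """Recomputing g from the generated masses and applying the inverse
        reproduces the final mass to machine precision."""
        df = small_study.growth
        g = instantaneous_growth(df["W_t_mg"].to_numpy(), df["W_t_dt_mg"].to_numpy(),
                                 df["dt_days"].to_numpy())
        np.testing.assert_allclose(
            df["W_t_mg"].to_numpy() * np.exp(g * df["dt_days"].to_numpy()),
            df["W_t_dt_mg"].to_numpy(), rtol=1e-12)

    def test_interval_bounds(self, small_study):
        dt = small_study.growth["dt_days"]
        assert dt.between(7.0, 15.0).all()

    def test_noise_free_intercept(self):
        cfg = SimulationConfig(noise_sd_log_growth=0.0, seed=6)
        env = simulate_environment(cfg)
        growth = simulate_growth_chambers(cfg, env, n_obs=50)
        model = fit_growth_model(growth)
        assert model.intercept == pytest.approx(cfg.ln_g0_true, abs=1e-6)
        assert model.a == pytest.approx(cfg.a_true, abs=1e-7)
        assert model.E_ind == pytest.approx(cfg.E_ind_true, abs=1e-6)


class TestGPPSeries:
    def test_two_instrumented_streams(self, small_config, small_study):
        assert small_study.gpp["stream_id"].nunique() == 2

    def test_noise_free_temperature_dependence(self):
        from streamprod.resources import fit_gpp_model
        cfg = SimulationConfig(noise_sd_log_gpp=0.0, seed=7)
        env = simulate_environment(cfg)
        chla = simulate_chlorophyll(cfg, env)
        gpp = simulate_gpp(cfg, env, chla)
        model = fit_gpp_model(
            gpp["gpp"], gpp["chla"], gpp["light"],
            standardize_temperature(gpp["temp_C"].to_numpy()),
            n_boot=200, seed=0)
        assert model.coefficients["temp"] == pytest.approx(
            cfg.resource_production_E_true, abs=1e-6)


class TestDeterminism:
    def test_full_study_reproducible(self, small_config):
        a = simulate_study(small_config, n_growth_obs=60)
        b = simulate_study(small_config, n_growth_obs=60)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.chlorophyll, b.chlorophyll)
        pd.testing.assert_frame_equal(a.growth, b.growth)
        assert a.truth == b.truth
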