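"""Chlorophyll bootstrap, AICc competition and resource correction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from streamprod.bootstrap import BootstrapDistribution
from streamprod.resources import (
    _fit_mixed_ml,
    aicc,
    among_stream_selection,
    annual_chla_bootstrap,
    fit_chla_temperature,
    fit_gpp_model,
    log_with_floor,
    resource_correct_within,
    within_stream_selection,
)
from streamprod.scaling import standardize_temperature


def _chla_frame(values_by_date, stream="s1", stones_per_date=1):
    rows = []
    for d, (date, vals) in enumerate(values_by_date.items()):
        for i, v in enumerate(np.atleast_1d(vals)):
            rows.append({"stream_id": stream, "date": date, "stone_id": i + 1,
                         "chla_mg_m2": float(v)})
    return pd.DataFrame(rows)


class TestAnnualChla:
    def test_constant_input_zero_width(self):
        df = _chla_frame({"2011-05-01": 7.0, "2011-06-01": 7.0, "2011-07-01": 7.0})
        out = annual_chla_bootstrap(df, n_boot=100, seed=0)
        np.testing.assert_allclose(out["s1"].replicates, 7.0)

    def test_two_date_enumeration(self):
        """Dates {2, 4}: date resampling gives annual means {2,3,4} with
        probabilities {1/4, 1/2, 1/4}; needs >=3 dates so a spectator date
        is checked separately."""
        df = _chla_frame({"2011-05-01": 2.0, "2011-06-01": 4.0, "2011-07-01": 3.0})
        out = annual_chla_bootstrap(df, n_boot=200_000, seed=1)
        reps = out["s1"].replicates
        # resampled means live on the 1/3 grid between 2 and 4
        assert reps.min() >= 2.0 and reps.max() <= 4.0
        mc_se = reps.std() / np.sqrt(reps.size)
        assert abs(reps.mean() - 3.0) < 3 * mc_se

    def test_unbiasedness(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(1, 0.5, size=10)
        df = _chla_frame({f"2011-{m:02d}-01": v for m, v in enumerate(vals, start=1)})
        out = annual_chla_bootstrap(df, n_boot=50_000, seed=3)
        reps = out["s1"].replicates
        mc_se = reps.std() / np.sqrt(reps.size)
        assert abs(reps.mean() - vals.mean()) < 3 * mc_se

    def test_too_few_dates(self):
        df = _chla_frame({"2011-05-01": 2.0, "2011-06-01": 4.0})
        with pytest.raises(ValueError, match=">= 3"):
            annual_chla_bootstrap(df, n_boot=10, seed=0)

    def test_negative_chla_rejected(self):
        df = _chla_frame({"2011-05-01": -1.0, "2011-06-01": 4.0, "2011-07-01": 3.0})
        with pytest.raises(ValueError):
            annual_chla_bootstrap(df, n_boot=10, seed=0)


class TestChlaTemperature:
    def test_zero_noise_exact(self):
        x = np.array([-1.4, -0.9, -0.2, 0.3, 1.0, 1.6])
        chla = {f"s{i}": BootstrapDistribution(np.array([np.exp(0.53 * xi)]))
                for i, xi in enumerate(x)}
        est = fit_chla_temperature(chla, x, n_boot=300, seed=0)
        assert est.E_mean == pytest.approx(0.53, rel=1e-9)
        assert est.quantity == "chla"


class TestAICc:
    def test_hand_value(self):
        # -2*(-10) + 2*3 + 2*3*4/(10-3-1) = 30
        assert aicc(-10.0, 3, 10) == pytest.approx(30.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_undefined_correction(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 9, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1e3, max_value=0.0), st.integers(1, 10),
           st.integers(13, 500))
    def test_always_exceeds_aic(self, ll, k, n):
        assert aicc(ll, k, n) > -2 * ll + 2 * k


def _inner(values, sd, n, rng):
    return [np.exp(np.log(v) + rng.normal(0, sd, size=n)) for v in values]


class TestAmongStreamSelection:
    x = np.array([-1.447, -1.374, -1.331, -0.540, 0.355, 1.625])

    def test_resource_driven_production(self):
        """When production follows chlorophyll and chlorophyll carries
        temperature-independent variation, the chla-only model dominates
        and the additive model's temperature coefficient straddles zero."""
        rng = np.random.default_rng(0)
        chla_true = np.exp(0.53 * self.x + rng.normal(0, 0.5, 6)) * 20
        p_true = 3.0 * (chla_true / 20) ** 1.2
        sel = among_stream_selection(
            _inner(p_true, 0.05, 400, rng), self.x, _inner(chla_true, 0.08, 400, rng),
            n_rep=400, seed=1)
        assert sel.winner == "chla"
        assert sel.frequencies["chla"] > 0.5
        assert sel.corrected_E.ci_low < 0 < sel.corrected_E.ci_high
        assert sum(sel.frequencies.values()) == pytest.approx(1.0)

    def test_temperature_driven_production(self):
        """Mirror case: flat chlorophyll, production driven by temperature."""
        rng = np.random.default_rng(1)
        p_true = np.exp(0.67 * self.x)
        chla_true = np.full(6, 20.0) * np.exp(rng.normal(0, 0.3, 6))
        sel = among_stream_selection(
            _inner(p_true, 0.05, 400, rng), self.x, _inner(chla_true, 0.05, 400, rng),
            n_rep=400, seed=2)
        assert sel.winner == "temp"
        assert sel.apparent_E.mean == pytest.approx(0.67, abs=0.1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        p = _inner(np.exp(0.6 * self.x), 0.1, 200, rng)
        c = _inner(np.exp(0.5 * self.x), 0.1, 200, rng)
        a = among_stream_selection(p, self.x, c, n_rep=150, seed=9)
        b = among_stream_selection(p, self.x, c, n_rep=150, seed=9)
        assert a.frequencies == b.frequencies
        np.testing.assert_array_equal(a.corrected_E.replicates, b.corrected_E.replicates)

    def test_too_few_streams(self):
        with pytest.raises(ValueError):
            among_stream_selection([[1.0]] * 3, [0, 1, 2], [[1.0]] * 3, n_rep=10, seed=0)

    def test_nonpositive_production_rejected(self):
        vals = [[1.0]] * 5 + [[0.0]]
        with pytest.raises(ValueError):
            among_stream_selection(vals, self.x, [[1.0]] * 6, n_rep=10, seed=0)


class TestMixedFit:
    def test_matches_statsmodels_reml(self):
        rng = np.random.default_rng(0)
        n, groups = 66, np.repeat([f"s{i}" for i in range(6)], 11)
        u = dict(zip(np.unique(groups), rng.normal(0, 0.5, 6)))
        x = rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        y = 1 + np.array([u[g] for g in groups]) + 1.5 * x + 0.5 * c + rng.normal(0, 0.3, n)
        X = np.column_stack([np.ones(n), x, c])
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=True, maxiter=200)
        mine = _fit_mixed_ml(y, [x, c], groups, reml=True)
        assert mine.llf == pytest.approx(float(ref.llf), abs=1e-4)
        np.testing.assert_allclose(mine.fe_params, np.asarray(ref.fe_params), atol=1e-4)
        assert mine.re_var == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-3)

    def test_ml_likelihood_not_worse_than_statsmodels(self):
        rng = np.random.default_rng(1)
        n, groups = 44, np.repeat([f"s{i}" for i in range(4)], 11)
        u = dict(zip(np.unique(groups), rng.normal(0, 0.4, 4)))
        x = rng.normal(0, 1, n)
        y = 0.5 + np.array([u[g] for g in groups]) + 1.2 * x + rng.normal(0, 0.4, n)
        ref = sm.MixedLM(y, np.column_stack([np.ones(n), x]), groups=groups).fit(
            reml=False, maxiter=200)
        mine = _fit_mixed_ml(y, [x], groups, reml=False)
        assert mine.llf >= float(ref.llf) - 1e-4

    def test_boundary_case_equals_ols(self):
        rng = np.random.default_rng(2)
        n, groups = 40, np.repeat(list("abcd"), 10)
        x = rng.normal(0, 1, n)
        y = 1 + 2 * x + rng.normal(0, 0.1, n)  # no group effects at all
        mine = _fit_mixed_ml(y, [x], groups, reml=False)
        ols = sm.OLS(y, np.column_stack([np.ones(n), x])).fit()
        assert mine.re_var == pytest.approx(0.0, abs=1e-4)
        np.testing.assert_allclose(mine.fe_params, np.asarray(ols.params), atol=1e-5)


class TestWithinStreamSelection:
    def _intervals(self, seed, e_temp=1.5, b_chla=0.6, b_light=0.4, sd=0.15):
        rng = np.random.default_rng(seed)
        streams = np.repeat([f"s{i}" for i in range(4)], 8)
        n = streams.size
        x = rng.uniform(-1.0, 1.5, n)
        chla_true = np.exp(rng.normal(2.0, 0.6, n))
        light = np.exp(rng.normal(0.0, 0.5, n))
        u = dict(zip(np.unique(streams), rng.normal(0, 0.4, 4)))
        ln_p = (np.array([u[s] for s in streams]) + e_temp * x
                + b_chla * np.log(chla_true) + b_light * np.log(light)
                + rng.normal(0, sd, n))
        p = [np.exp(ln_p[i] + rng.normal(0, 0.05, 200)) for i in range(n)]
        chla = [np.exp(np.log(chla_true[i]) + rng.normal(0, 0.05, 200)) for i in range(n)]
        return p, x, chla, light, streams

    def test_recovers_additive_structure_and_coefficients(self):
        p, x, chla, light, streams = self._intervals(0)
        sel, fit = within_stream_selection(p, x, chla, light, streams,
                                           n_rep=80, seed=1)
        assert sel.winner == "temp+chla+light"
        assert sel.coefficients["temp"].mean == pytest.approx(1.5, abs=0.2)
        assert sel.coefficients["ln_chla"].mean == pytest.approx(0.6, abs=0.15)
        assert sel.coefficients["ln_light"].mean == pytest.approx(0.4, abs=0.15)
        assert fit is not None and fit.model == sel.winner
        assert sum(sel.frequencies.values()) == pytest.approx(1.0)

    def test_null_data_selects_null(self):
        p, x, chla, light, streams = self._intervals(3, e_temp=0.0, b_chla=0.0,
                                                     b_light=0.0, sd=0.3)
        sel, _ = within_stream_selection(p, x, chla, light, streams, n_rep=60, seed=2)
        assert sel.winner == "null"

    def test_needs_two_streams(self):
        p, x, chla, light, streams = self._intervals(0)
        one = streams == "s0"
        with pytest.raises(ValueError):
            within_stream_selection(
                [p[i] for i in np.nonzero(one)[0]], x[one],
                [chla[i] for i in np.nonzero(one)[0]], light[one], streams[one],
                n_rep=10, seed=0)


class TestGPPModel:
    def _series(self, noise=0.0, n=24, seed=0):
        rng = np.random.default_rng(seed)
        temp = rng.uniform(5, 25, n)
        x = standardize_temperature(temp)
        light = np.exp(rng.normal(0, 0.4, n))
        chla = np.exp(rng.normal(2, 0.5, n))
        gpp = np.exp(0.8 + 1.37 * x + 0.5 * np.log(light) + 0.3 * np.log(chla)
                     + rng.normal(0, noise, n))
        return gpp, chla, light, x

    def test_zero_noise_exact_recovery(self):
        gpp, chla, light, x = self._series()
        model = fit_gpp_model(gpp, chla, light, x, n_boot=200, seed=0)
        assert model.coefficients["temp"] == pytest.approx(1.37, rel=1e-9)
        assert model.E_gpp.ci_low == pytest.approx(1.37, rel=1e-6)

    def test_noisy_recovery_within_ci(self):
        gpp, chla, light, x = self._series(noise=0.15, seed=1)
        model = fit_gpp_model(gpp, chla, light, x, n_boot=1000, seed=2)
        assert model.E_gpp.ci_low < 1.37 < model.E_gpp.ci_high

    def test_minimum_observations(self):
        gpp, chla, light, x = self._series(n=6)
        with pytest.raises(ValueError):
            fit_gpp_model(gpp, chla, light, x)

    def test_nonpositive_gpp_rejected(self):
        gpp, chla, light, x = self._series()
        gpp[0] = 0.0
        with pytest.raises(ValueError):
            fit_gpp_model(gpp, chla, light, x)


class TestResourceCorrection:
    def test_identical_distributions_center_on_zero(self):
        rng = np.random.default_rng(0)
        d = BootstrapDistribution(rng.normal(1.5, 0.2, 2000))
        out = resource_correct_within(d, d, n_boot=50_000, seed=1)
        se = out.slopes.replicates.std() / np.sqrt(out.n_boot)
        assert abs(out.E_mean) < 3 * se

    def test_shift_identity(self):
        a = BootstrapDistribution(np.full(100, 1.52))
        b = BootstrapDistribution(np.full(100, 1.37))
        out = resource_correct_within(a, b, n_boot=500, seed=0)
        np.testing.assert_allclose(out.slopes.replicates, 0.15)
        assert out.E_mean == pytest.approx(1.52 - 1.37)


class TestLogFloor:
    def test_floor_is_half_smallest_positive(self):
        out = log_with_floor([0.0, 2.0, 8.0])
        assert out[0] == pytest.approx(np.log(1.0))

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_with_floor([0.0, -1.0])
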