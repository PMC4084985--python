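import numpy as np
import pandas as pd
import pytest
from scipy import special

from spawntrack import synth
from spawntrack.cpue import (HurdleCPUEModel, bin_covariate, combine_monte_carlo,
                             kde_region_classify, marginal_means)


def _survey(truth=None, years=range(2000, 2006), seed=0, hauls_per_month=20,
            region_from_truth=True):
    truth = truth or synth.default_survey_truth()
    sim = synth.simulate_survey(truth, n_grids=80, years=years,
                                hauls_per_month=hauls_per_month, seed=seed)
    df = sim.hauls.copy()
    if region_from_truth:
        conc = sim.grids.set_index("grid_id")["concentrated_true"]
        df["region"] = np.where(conc.reindex(df["grid_id"]).to_numpy(),
                                "concentrated", "not")
    return df, sim


class TestBinCovariate:
    def test_interior_value(self):
        cat = bin_covariate([23.0])
        assert cat[0] == pytest.approx(23.75)  # midpoint of [22.5, 25.0)

    def test_boundary_goes_to_upper_bin(self):
        cat = bin_covariate([25.0])
        assert cat[0] == pytest.approx(26.25)  # midpoint of [25.0, 27.5)

    def test_matches_floor_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(-10, 40, 500)
        cat = bin_covariate(v, width=2.5)
        oracle = (np.floor(v / 2.5) + 0.5) * 2.5
        np.testing.assert_allclose(np.asarray(cat, float), oracle)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            bin_covariate([1.0], width=0.0)


class TestKDERegions:
    def test_single_hotspot_locality(self):
        hauls = pd.DataFrame({
            "grid_id": [f"G{i}" for i in range(20)],
            "x": np.concatenate([np.full(10, 1.0) + np.linspace(-0.4, 0.4, 10),
                                 np.linspace(6, 10, 10)]),
            "y": np.ones(20),
            "adult_count": [12] * 10 + [0] * 10,
        })
        rc = kde_region_classify(hauls, bandwidth=0.8, contour_level=0.5)
        assert rc.labels[[f"G{i}" for i in range(10)]].all()
        assert not rc.labels[[f"G{i}" for i in range(15, 20)]].any()

    def test_contour_level_one_labels_everything(self):
        hauls = pd.DataFrame({
            "grid_id": [f"G{i}" for i in range(12)],
            "x": np.linspace(0, 6, 12), "y": np.zeros(12),
            "adult_count": [3] * 6 + [0] * 6,
        })
        rc = kde_region_classify(hauls, bandwidth=1.5, contour_level=0.9999999)
        assert rc.labels.all()

    def test_all_zero_cpue_rejected(self):
        hauls = pd.DataFrame({"grid_id": ["G0", "G1"], "x": [0.0, 1.0],
                              "y": [0.0, 0.0], "adult_count": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            kde_region_classify(hauls)

    def test_recovers_truth_hotspot_grids(self):
        df, sim = _survey(seed=7, region_from_truth=False)
        rc = kde_region_classify(df, bandwidth=2.0, contour_level=0.5)
        truth_conc = sim.grids.set_index("grid_id")["concentrated_true"]
        surveyed = truth_conc.index.intersection(rc.labels.index)
        hot = truth_conc[surveyed]
        recovered = rc.labels[surveyed][hot].mean()
        assert recovered >= 0.9

    def test_unweighted_variant_runs(self):
        df, _ = _survey(seed=3, region_from_truth=False)
        rc = kde_region_classify(df, weighted=False)
        assert rc.labels.any()


class TestForwardSelection:
    def test_final_aic_never_worse_than_year_only(self):
        df, _ = _survey(seed=4)
        fit = HurdleCPUEModel(df).fit()
        for trace in (fit.binomial_trace, fit.lognormal_trace):
            aics = [a for _, a in trace]
            assert all(np.diff(aics) < 0)  # every accepted step reduced AIC
            assert aics[-1] <= aics[0]

    def test_region_effect_is_selected(self):
        truth = synth.SurveyTruth(season_effect=0.0, temperature_slope_per_c=0.0,
                                  vegetation_effect=0.0)
        df, _ = _survey(truth, seed=5)
        fit = HurdleCPUEModel(df).fit()
        assert "region" in fit.binomial_terms
        assert "region" in fit.lognormal_terms

    def test_month_and_season_never_coexist(self):
        for seed in range(4):
            df, _ = _survey(seed=seed)
            fit = HurdleCPUEModel(df).fit()
            for terms in (fit.binomial_terms, fit.lognormal_terms):
                assert not ({"month", "season"} <= set(terms))

    def test_interaction_requires_both_mains(self):
        for seed in range(4):
            df, _ = _survey(seed=10 + seed)
            fit = HurdleCPUEModel(df).fit()
            for terms in (fit.binomial_terms, fit.lognormal_terms):
                if "region_x_season" in terms:
                    assert {"region", "season"} <= set(terms)

    def test_year_always_retained(self):
        df, _ = _survey(seed=6)
        fit = HurdleCPUEModel(df).fit()
        assert fit.binomial_terms[0] == "year"
        assert fit.lognormal_terms[0] == "year"

    def test_rejects_single_year_or_all_zero(self):
        df, _ = _survey(seed=1)
        with pytest.raises(ValueError):
            HurdleCPUEModel(df[df["year"] == 2000])
        allzero = df.copy()
        allzero["adult_count"] = 0
        with pytest.raises(ValueError):
            HurdleCPUEModel(allzero)


class TestMarginalMeans:
    def test_year_only_model_equals_fitted_link_values(self):
        df, _ = _survey(seed=8)
        fit = HurdleCPUEModel(df, candidates=()).fit()
        mm = marginal_means(fit.binomial)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        ref = smf.glm("present ~ C(year)", data=fit.model.data,
                      family=sm.families.Binomial()).fit()
        for _, row in mm.iterrows():
            sub = fit.model.data[fit.model.data["year"] == row["year"]]
            eta = ref.predict(sub.iloc[[0]], which="linear").iloc[0]
            assert row["estimate"] == pytest.approx(eta, abs=1e-8)

    def test_balanced_two_factor_equals_cell_mean_average(self):
        # fully balanced year x region design fitted by OLS: the balanced-grid
        # marginal mean must equal the average of per-cell means
        rng = np.random.default_rng(2)
        years = np.repeat([2000, 2001], 40)
        region = np.tile(np.repeat(["concentrated", "not"], 20), 2)
        y = 1.0 + 0.5 * (years == 2001) + 0.8 * (region == "concentrated") \
            + rng.normal(0, 0.2, 80)
        df = pd.DataFrame({"year": years, "region": region, "log_count": y,
                           "present": 1, "adult_count": np.exp(y)})
        import statsmodels.formula.api as smf
        res = smf.ols("log_count ~ C(year) + C(region)", data=df).fit()
        mm = marginal_means(res).set_index("year")
        cells = df.groupby(["year", "region"])["log_count"].mean()
        for yr in (2000, 2001):
            assert mm.at[yr, "estimate"] == pytest.approx(cells[yr].mean(), abs=0.02)

    def test_balanced_factor_leaves_year_contrasts_unchanged(self):
        df, _ = _survey(seed=9)
        base = HurdleCPUEModel(df, candidates=()).fit()
        mm0 = marginal_means(base.lognormal).set_index("year")["estimate"]
        import statsmodels.formula.api as smf
        res = smf.ols("log_count ~ C(year) + C(vegetation)",
                      data=base.model.positives).fit()
        mm1 = marginal_means(res).set_index("year")["estimate"]
        d0 = mm0 - mm0.mean()
        d1 = mm1 - mm1.mean()
        np.testing.assert_allclose(d0, d1, atol=0.05)


class TestMonteCarlo:
    def _mm(self, est, se, years=(2000, 2001), df=100.0):
        return pd.DataFrame({"year": years, "estimate": est, "se": se,
                             "df": df})

    def test_zero_se_degenerates_to_point_product(self):
        b = self._mm([0.4, -0.2], 0.0)
        l = self._mm([1.5, 1.2], 0.0)
        idx = combine_monte_carlo(b, l, sigma2=0.5, n_draws=200, seed=1)
        expect0 = special.expit(0.4) * np.exp(1.5 + 0.25)
        assert np.allclose(idx.draws[2000], expect0)

    def test_logit_zero_presence_factor_half(self):
        b = self._mm([0.0, 0.0], 0.05)
        l = self._mm([0.0, 0.0], 0.0)
        idx = combine_monte_carlo(b, l, sigma2=0.0, n_draws=20000, seed=2)
        assert idx.draws[2000].mean() == pytest.approx(0.5, abs=0.01)

    def test_mismatched_years_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_monte_carlo(self._mm([0], 0.1, years=(2000,)),
                                self._mm([0], 0.1, years=(2001,)), 0.1)

    def test_fixed_seed_bit_reproducible(self):
        b = self._mm([0.3, 0.1], 0.2)
        l = self._mm([1.0, 0.9], 0.15)
        a = combine_monte_carlo(b, l, 0.4, n_draws=500, seed=7)
        c = combine_monte_carlo(b, l, 0.4, n_draws=500, seed=7)
        pd.testing.assert_frame_equal(a.draws, c.draws)

    def test_summary_percentiles_ordered(self):
        b = self._mm([0.3, 0.1], 0.2)
        l = self._mm([1.0, 0.9], 0.15)
        s = combine_monte_carlo(b, l, 0.4, n_draws=2000, seed=3).summary()
        assert (s["q2.5"] <= s["median"]).all() and (s["median"] <= s["q97.5"]).all()


class TestIndexProperties:
    def test_scaling_positive_catches_scales_index(self):
        df, _ = _survey(seed=12)
        fit = HurdleCPUEModel(df).fit()
        idx = fit.standardized_index(n_draws=400, seed=5)
        scaled = df.copy()
        scaled["adult_count"] = scaled["adult_count"] * 10
        fit10 = HurdleCPUEModel(scaled, candidates=tuple(fit.lognormal_terms[1:])).fit()
        idx10 = fit10.standardized_index(n_draws=400, seed=5)
        if fit10.lognormal_terms == fit.lognormal_terms \
                and fit10.binomial_terms == fit.binomial_terms:
            ratio = idx10.draws.mean() / idx.draws.mean()
            np.testing.assert_allclose(ratio, 10.0, rtol=0.01)

    def test_hurdle_decomposition_conserves_stratum_means(self):
        # presence-prob x positive-mean must reproduce empirical unconditional
        # means per region stratum on a large simulation
        truth = synth.SurveyTruth(season_effect=0.0, temperature_slope_per_c=0.0,
                                  vegetation_effect=0.0)
        sim = synth.simulate_survey(truth, n_grids=100, years=range(2000, 2010),
                                    hauls_per_month=420, seed=13)
        df = sim.hauls.copy()
        conc = sim.grids.set_index("grid_id")["concentrated_true"]
        df["region"] = np.where(conc.reindex(df["grid_id"]).to_numpy(),
                                "concentrated", "not")
        assert len(df) >= 50000
        fit = HurdleCPUEModel(df, candidates=("region",)).fit()
        pos = fit.model.positives
        for region in ("concentrated", "not"):
            sub = df[df["region"] == region]
            p = fit.binomial.predict(sub.iloc[[0]]).iloc[0]
            mu = np.exp(fit.lognormal.predict(pos[pos["region"] == region].iloc[[0]]).iloc[0]
                        + fit.sigma2 / 2.0)
            empirical = sub["adult_count"].mean()
            # year covariate averages out: compare within 5%
            assert p * mu == pytest.approx(empirical, rel=0.05)
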