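"""Case-crossover model: strata, design, conditioning oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

import windlag as w
from windlag import _fit
from windlag.model import CaseCrossoverModel, ModelConfig, build_strata
from windlag.timeindex import month_index


def _stratum_frame(exposed_years, years=range(1990, 1995), deaths=3):
    """One county, September months only, exposure in the given years."""
    rows = []
    for y in years:
        t = month_index(y, 9, 1990)
        rows.append(("c1", t, deaths, 1.0 if y in exposed_years else 0.0, True, 1000.0))
    return pd.DataFrame(
        rows,
        columns=["county_id", "month_index", "deaths", "lag_0", "lag_complete", "population"],
    )


class TestStrata:
    def test_single_exposed_year_gives_one_case(self):
        tagged = build_strata(_stratum_frame({1992}))
        assert tagged["stratum"].nunique() == 1
        assert tagged["stratum_size"].iloc[0] == 5
        assert tagged["is_case"].sum() == 1
        assert tagged["informative"].all()

    def test_three_exposed_years_give_three_cases(self):
        tagged = build_strata(_stratum_frame({1990, 1992, 1994}))
        assert tagged["is_case"].sum() == 3

    def test_constant_exposure_is_noninformative(self):
        tagged = build_strata(_stratum_frame(set(range(1990, 1995))))
        assert not tagged["informative"].any()

    def test_breakpoint_month_arithmetic(self):
        assert month_index(2015, 12, 1988) == 335


class TestDesign:
    def test_column_accounting(self, small_inputs):
        model = CaseCrossoverModel.from_inputs(small_inputs, config=ModelConfig(seed=0))
        d = model.design
        n_cols = d.X.shape[1]
        assert n_cols == len(d.info["col_labels"])
        assert n_cols == 4 + len(d.spline_cols) + len(d.temp_cols)
        assert len(d.temp_cols) == 19  # 20 bins under a sum-to-zero constraint

    def test_constant_temperature_drops_rw2(self, small_inputs):
        temp = small_inputs.temperature.copy()
        temp["temp_c"] = 15.0
        inputs = w.PanelInputs(
            mortality=small_inputs.mortality,
            exposure=small_inputs.exposure,
            annual_population=small_inputs.annual_population,
            temperature=temp,
            start_year=small_inputs.start_year,
        )
        with pytest.warns(UserWarning, match="temperature constant"):
            model = CaseCrossoverModel.from_inputs(inputs, config=ModelConfig(seed=0))
        assert len(model.design.temp_cols) == 0

    def test_incomplete_lag_months_excluded(self, small_inputs):
        model = CaseCrossoverModel.from_inputs(small_inputs, config=ModelConfig(seed=0))
        assert model.design.info["n_incomplete_lag_excluded"] == 10 * 3  # L=3 per county
        assert model.design.frame["month_index"].min() == 3


class TestConditioningOracles:
    def test_flat_prior_mode_matches_grid_search_mle(self, one_stratum_frame, no_adjust_config):
        model = CaseCrossoverModel.from_frame(one_stratum_frame, no_adjust_config, start_year=1990)
        res = model.fit()
        y = np.array([2.0, 5.0, 3.0])
        grid = np.linspace(-1.0, 2.0, 300001)
        ll = [y[1] * b - y.sum() * np.logaddexp.reduce([0.0, b, 0.0]) for b in grid]
        b_grid = grid[int(np.argmax(ll))]
        assert res.beta_mean[0] == pytest.approx(b_grid, abs=1e-4)

    def test_matches_poisson_with_stratum_intercepts(self, small_inputs):
        import statsmodels.api as sm

        cfg = ModelConfig(
            lag=1, use_trend=False, use_temperature=False,
            overdispersion="none", beta_prior_sd=np.inf, seed=0,
        )
        model = CaseCrossoverModel.from_inputs(small_inputs, config=cfg)
        res = model.fit()
        frame = model.design.frame
        X = pd.get_dummies(frame["stratum"].astype("category"), drop_first=False).astype(float)
        X = pd.concat([frame[["lag_0", "lag_1"]].reset_index(drop=True),
                       X.reset_index(drop=True)], axis=1)
        X.columns = X.columns.astype(str)
        glm = sm.GLM(
            frame["deaths"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.log(frame["population"].to_numpy()),
        ).fit()
        assert res.beta_mean == pytest.approx(glm.params[["lag_0", "lag_1"]].to_numpy(), abs=1e-5)

    def test_map_and_mcmc_agree_on_fixture(self):
        cfg_gen = w.GeneratorConfig(
            n_counties=4,
            year_range=(2015, 2019),
            baseline_monthly_rate=1e-3,
            overdispersion=0.0,
            exposure_rate=2.0,
            trend_slopes=(0.0, 0.0),
            seasonal_amplitude=0.0,
            temp_effect_knots=((0.0, 0.0), (30.0, 0.0)),
            county_effect_sd=0.0,
            planted_lag_log_rr=(0.05, 0.0),
            seed=19,
        )
        inputs = w.PanelInputs.from_synthetic(w.generate_panel(cfg_gen))
        common = dict(lag=1, use_trend=False, use_temperature=False,
                      overdispersion="none", seed=5, draws=500, warmup=300)
        res_map = CaseCrossoverModel.from_inputs(
            inputs, config=ModelConfig(inference="map_laplace", **common)
        ).fit()
        res_mcmc = CaseCrossoverModel.from_inputs(
            inputs, config=ModelConfig(inference="mcmc", **common)
        ).fit()
        assert res_mcmc.beta_mean == pytest.approx(res_map.beta_mean, abs=0.03)

    def test_mcmc_runs_with_olre_overdispersion(self):
        cfg_gen = w.GeneratorConfig(
            n_counties=3, year_range=(2016, 2019), exposure_rate=2.0, seed=6
        )
        inputs = w.PanelInputs.from_synthetic(w.generate_panel(cfg_gen))
        cfg = ModelConfig(lag=0, use_trend=False, use_temperature=False,
                          inference="mcmc", chains=2, draws=250, warmup=150, seed=7)
        res = CaseCrossoverModel.from_inputs(inputs, config=cfg).fit()
        lo, hi = res.beta_ci[0]
        assert lo <= res.beta_mean[0] <= hi
        assert "tau_olre" in res.hyper


class TestInvariances:
    def test_translation_within_stratum(self):
        rng = np.random.default_rng(0)
        stratum = np.repeat(np.arange(8), 5)
        eta = rng.normal(size=40)
        y = rng.poisson(3.0, size=40).astype(float)
        groups = _fit.StratumGroups.from_codes(stratum)
        shifts = rng.normal(size=8)[stratum]
        a = _fit.cond_loglik(eta, y, groups)
        b = _fit.cond_loglik(eta + shifts, y, groups)
        assert b == pytest.approx(a, abs=1e-9)

    def test_offset_doubling_leaves_posterior_unchanged(self):
        cfg_gen = w.GeneratorConfig(n_counties=6, year_range=(2016, 2019), seed=10)
        panel = w.generate_panel(cfg_gen)
        inputs = w.PanelInputs.from_synthetic(panel)
        doubled_pop = panel.counties.population.copy()
        doubled_pop["population"] = doubled_pop["population"] * 2.0
        inputs2 = w.PanelInputs(
            mortality=inputs.mortality,
            exposure=inputs.exposure,
            annual_population=doubled_pop,
            temperature=inputs.temperature,
            start_year=inputs.start_year,
        )
        cfg = ModelConfig(seed=3)
        res1 = CaseCrossoverModel.from_inputs(inputs, config=cfg).fit()
        res2 = CaseCrossoverModel.from_inputs(inputs2, config=cfg).fit()
        assert np.allclose(res1.beta_mean, res2.beta_mean, atol=1e-7)
        assert np.allclose(res1.draws, res2.draws, atol=1e-6)

    def test_monotone_in_planted_effect(self):
        means = []
        for b0 in (0.0, 0.05, 0.10):
            cfg_gen = w.GeneratorConfig(
                n_counties=15,
                year_range=(2013, 2019),
                planted_lag_log_rr=(b0, 0.0, 0.0, 0.0),
                seed=29,
            )
            inputs = w.PanelInputs.from_synthetic(w.generate_panel(cfg_gen))
            res = CaseCrossoverModel.from_inputs(inputs, config=ModelConfig(seed=29)).fit()
            means.append(res.beta_mean[0])
        assert means[0] < means[1] < means[2]


class TestRefusals:
    def test_no_exposure_is_not_identifiable(self):
        cfg_gen = w.GeneratorConfig(n_counties=4, year_range=(2017, 2019),
                                    exposure_rate=0.0, seed=12)
        inputs = w.PanelInputs.from_synthetic(w.generate_panel(cfg_gen))
        model = CaseCrossoverModel.from_inputs(inputs, config=ModelConfig(seed=0))
        with pytest.raises(RuntimeError, match="not identifiable"):
            model.fit()

    def test_empty_subgroup_refuses(self, small_inputs):
        with pytest.raises(RuntimeError, match="no outcome events"):
            CaseCrossoverModel.from_inputs(
                small_inputs, config=ModelConfig(seed=0),
                subset={"age_group": "nonexistent"},
            )

    def test_single_member_strata_are_excluded(self):
        frame = _stratum_frame({1990}, years=[1990])  # one September only
        with pytest.raises(RuntimeError, match="no county-months"):
            CaseCrossoverModel.from_frame(
                frame,
                ModelConfig(lag=0, use_trend=False, use_temperature=False,
                            overdispersion="none", seed=0),
                start_year=1990,
            )


class TestSubgroups:
    def test_empty_subset_equals_full_fit(self, small_inputs):
        cfg = ModelConfig(seed=1)
        m_full = CaseCrossoverModel.from_inputs(small_inputs, config=cfg)
        m_sub = CaseCrossoverModel.from_inputs(small_inputs, config=cfg, subset={})
        assert np.array_equal(m_full.design.X, m_sub.design.X)
        assert np.array_equal(m_full.design.y, m_sub.design.y)

    def test_sex_specific_planted_effects_recovered(self):
        cfg_gen = w.GeneratorConfig(
            subgroup_log_rr={
                "sex": {"female": (0.06, 0.0, 0.0, 0.0), "male": (0.03, 0.0, 0.0, 0.0)}
            },
            seed=47,
        )
        inputs = w.PanelInputs.from_synthetic(w.generate_panel(cfg_gen))
        res = {}
        for sex in ("female", "male"):
            res[sex] = CaseCrossoverModel.from_inputs(
                inputs, config=ModelConfig(seed=47), subset={"sex": sex}
            ).fit()
        assert res["female"].beta_mean[0] == pytest.approx(0.06, abs=0.04)
        assert res["male"].beta_mean[0] == pytest.approx(0.03, abs=0.04)
        contrast = w.subgroup_difference(res["female"], res["male"], "female", "male")
        lag0 = contrast.table.iloc[0]
        assert lag0["delta_mean"] == pytest.approx(0.06 - 0.03, abs=0.04)


class TestResultsSurface:
    def test_summary_table_shape_and_ordering(self, small_fit):
        tab = small_fit.summary()
        assert list(tab.columns) == ["lag", "mean", "sd", "lower95", "upper95", "ess"]
        assert len(tab) == 4
        assert (tab["lower95"] <= tab["mean"]).all()
        assert (tab["mean"] <= tab["upper95"]).all()

    def test_draw_count_and_finiteness(self, small_fit):
        assert small_fit.draws.shape == (4000, 4)
        assert np.isfinite(small_fit.draws).all()

    def test_plot_effects_returns_axis(self, small_fit):
        import matplotlib

        matplotlib.use("Agg")
        ax = small_fit.plot_effects()
        assert len(ax.lines) >= 1
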