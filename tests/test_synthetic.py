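"""Generator: determinism, seasonal structure, planted-effect calibration."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import windlag as w
from windlag.synthetic import expected_log_mu


class TestCounties:
    def test_adjacency_invariants(self):
        cfg = w.GeneratorConfig(n_counties=4, n_states=2, seed=7)
        counties = w.generate_counties(cfg)
        g = counties.adjacency
        assert g.number_of_nodes() == 4
        assert nx.is_connected(g)
        assert all(u != v for u, v in g.edges)  # irreflexive

    def test_median_split_nonempty(self):
        cfg = w.GeneratorConfig(n_counties=25, seed=11)
        counties = w.generate_counties(cfg)
        med = counties.table["poverty_pct"].median()
        above = (counties.table["poverty_pct"] > med).sum()
        assert 0 < above < 25

    def test_positive_populations_every_year_and_subgroup(self):
        cfg = w.GeneratorConfig(n_counties=5, year_range=(2015, 2019), seed=2)
        counties = w.generate_counties(cfg)
        pop = counties.population
        assert (pop["population"] > 0).all()
        assert pop.groupby("county_id")["year"].nunique().eq(5).all()
        assert pop.groupby(["county_id", "year"]).size().eq(10).all()  # 5 ages x 2 sexes

    def test_too_few_counties_rejected(self):
        with pytest.raises(ValueError, match="invalid config"):
            w.GeneratorConfig(n_counties=1)


class TestExposure:
    def test_zero_rate_gives_all_zero_panel(self):
        cfg = w.GeneratorConfig(n_counties=5, exposure_rate=0.0, seed=1)
        counties = w.generate_counties(cfg)
        panel = w.generate_exposure(counties, cfg)
        assert (panel["exposure_days_total"] == 0).all()

    def test_determinism_under_seed(self):
        cfg = w.GeneratorConfig(n_counties=8, seed=5)
        counties = w.generate_counties(cfg)
        a = w.generate_exposure(counties, w.GeneratorConfig(n_counties=8, seed=5))
        b = w.generate_exposure(counties, w.GeneratorConfig(n_counties=8, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_season_window_and_coverage(self):
        cfg = w.GeneratorConfig(n_counties=20, seed=9)
        counties = w.generate_counties(cfg)
        panel = w.generate_exposure(counties, cfg)
        exposed = panel.loc[panel["exposure_days_total"] > 0]
        assert set(exposed["month"]).issubset(set(range(5, 12)))
        # every county has at least one exposed month
        assert exposed["county_id"].nunique() == 20
        # strength classes partition the total
        assert (
            panel["exposure_days_gale"] + panel["exposure_days_hurricane"]
            == panel["exposure_days_total"]
        ).all()

    def test_september_modal_in_large_simulation(self):
        cfg = w.GeneratorConfig(
            n_counties=200, n_states=4, exposure_rate=5.0, seed=13
        )
        counties = w.generate_counties(cfg)
        panel = w.generate_exposure(counties, cfg)
        exposed = panel.loc[panel["exposure_days_total"] > 0]
        assert len(exposed) > 5000
        tally = exposed.groupby("month").size()
        assert tally.idxmax() == 9

    def test_day_counts_within_calendar_bounds(self):
        cfg = w.GeneratorConfig(n_counties=50, exposure_rate=3.0, seed=4)
        counties = w.generate_counties(cfg)
        panel = w.generate_exposure(counties, cfg)
        from windlag.timeindex import days_in_month

        exposed = panel.loc[panel["exposure_days_total"] > 0]
        limits = [days_in_month(y, m) for y, m in zip(exposed["year"], exposed["month"])]
        assert (exposed["exposure_days_total"] <= limits).all()


class TestDeaths:
    def test_full_panel_bit_identical_under_seed(self):
        a = w.generate_panel(w.GeneratorConfig(n_counties=6, year_range=(2016, 2019), seed=21))
        b = w.generate_panel(w.GeneratorConfig(n_counties=6, year_range=(2016, 2019), seed=21))
        pd.testing.assert_frame_equal(a.deaths, b.deaths)
        pd.testing.assert_frame_equal(a.temperature, b.temperature)
        pd.testing.assert_frame_equal(a.counties.table, b.counties.table)

    def test_null_effect_mean_matches_baseline(self):
        cfg = w.GeneratorConfig(
            n_counties=20,
            year_range=(2014, 2019),
            planted_lag_log_rr=(0.0, 0.0),
            trend_slopes=(0.0, 0.0),
            seasonal_amplitude=0.0,
            temp_effect_knots=((0.0, 0.0), (30.0, 0.0)),
            county_effect_sd=0.0,
            overdispersion=0.0,
            seed=17,
        )
        panel = w.generate_panel(cfg)
        person_months = panel.counties.population["population"].sum() * 12
        rate = panel.deaths["deaths"].sum() / person_months
        assert rate == pytest.approx(cfg.baseline_monthly_rate, rel=0.03)

    def test_planted_lag0_effect_in_empirical_rates(self):
        cfg = w.GeneratorConfig(
            n_counties=300,
            n_states=3,
            planted_lag_log_rr=(0.05, 0.0, 0.0, 0.0),
            trend_slopes=(0.0, 0.0),
            seasonal_amplitude=0.0,
            temp_effect_knots=((0.0, 0.0), (30.0, 0.0)),
            county_effect_sd=0.0,
            overdispersion=0.0,
            seed=23,
        )
        panel = w.generate_panel(cfg)
        lagged = panel.exposure.sort_values(["county_id", "month_index"]).copy()
        g = lagged.groupby("county_id")["exposure_days_total"]
        for lag in range(4):
            lagged[f"x_{lag}"] = g.shift(lag).fillna(0.0)
        deaths = panel.deaths.groupby(["county_id", "month_index"])["deaths"].sum()
        pop = panel.counties.annual_totals().set_index(["county_id", "year"])["population"]
        lagged["deaths"] = [
            deaths.get((c, t), 0) for c, t in zip(lagged["county_id"], lagged["month_index"])
        ]
        lagged["pop"] = [
            pop[(c, int(y))] for c, y in zip(lagged["county_id"], lagged["year"])
        ]
        clean = lagged[(lagged[["x_1", "x_2", "x_3"]] == 0).all(axis=1)]
        exposed = clean[clean["x_0"] == 1.0]
        unexposed = clean[clean["x_0"] == 0.0]
        ratio = (exposed["deaths"].sum() / exposed["pop"].sum()) / (
            unexposed["deaths"].sum() / unexposed["pop"].sum()
        )
        assert ratio == pytest.approx(np.exp(0.05), rel=0.03)

    def test_overdispersion_inflates_variance(self):
        cfg = w.GeneratorConfig(
            n_counties=2,
            year_range=(2010, 2019),
            planted_lag_log_rr=(0.0,),
            trend_slopes=(0.0, 0.0),
            seasonal_amplitude=0.0,
            temp_effect_knots=((0.0, 0.0), (30.0, 0.0)),
            county_effect_sd=0.0,
            overdispersion=0.5,
            exposure_rate=0.0,
            seed=31,
        )
        panel = w.generate_panel(cfg)
        sub = panel.deaths.loc[
            (panel.deaths["age_group"] == "30-44") & (panel.deaths["sex"] == "male")
        ]
        counts = sub.groupby(["county_id", "month_index"])["deaths"].sum()
        months = panel.exposure["month_index"].unique()
        for county in panel.counties.county_ids:
            # zero-count months matter for the variance
            series = np.array([counts.get((county, m), 0) for m in months], dtype=float)
            assert series.var() / series.mean() > 1.5

    def test_truth_log_mean_reproduces_sampling_mean(self):
        panel = w.generate_panel(
            w.GeneratorConfig(n_counties=4, year_range=(2017, 2019), seed=41)
        )
        recomputed = expected_log_mu(panel)
        merged = recomputed.merge(
            panel.truth["mu"], on=["county_id", "month_index", "age_group", "sex"]
        )
        assert np.allclose(np.exp(merged["log_mu"]), merged["mu"], rtol=1e-10)

    def test_misaligned_panels_name_offender(self):
        cfg = w.GeneratorConfig(n_counties=3, year_range=(2018, 2019), seed=2)
        counties = w.generate_counties(cfg)
        exposure = w.generate_exposure(counties, cfg)
        temperature = w.generate_temperature(counties, cfg).iloc[:-1]
        with pytest.raises(ValueError, match="misaligned"):
            w.generate_deaths(counties, exposure, temperature, cfg)


class TestRecords:
    def test_records_reaggregate_to_panel(self):
        panel = w.generate_panel(
            w.GeneratorConfig(n_counties=4, year_range=(2018, 2019), seed=8)
        )
        records = w.death_records(panel)
        agg, report = __import__("windlag").aggregate_deaths(
            records, start_year=2018
        )
        assert report["other"] == 0 and report["dropped"] == 0
        totals = agg.groupby(["county_id", "month_index", "category"])["deaths"].sum()
        expected = panel.deaths.groupby(["county_id", "month_index", "category"])[
            "deaths"
        ].sum()
        pd.testing.assert_series_equal(totals, expected, check_like=True)
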