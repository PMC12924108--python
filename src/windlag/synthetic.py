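"""Synthetic county-month panels with planted exposure effects.

Real inputs for this analysis (restricted vital-statistics death records,
county wind-exposure days, bridged-race populations, PRISM temperatures)
cannot be redistributed, so every downstream stage is validated on
generated panels that reproduce the statistical structure the model
assumes:

* sparse May-November tropical-cyclone exposure peaking in September, with
  right-skewed exposure-day counts (median 2 days) split into gale
  (34-63 kt) and rarer hurricane (>=64 kt) days;
* overdispersed (negative-binomial) monthly death counts with a county
  effect, calendar seasonality, a piecewise log-linear long-term trend
  with a configurable breakpoint, and a smooth temperature effect;
* planted per-lag log rate ratios per additional exposure day — the truth
  record against which parameter recovery is judged.

A single global seed feeds one substream per stage (counties, exposure,
temperature, deaths, records) via ``numpy`` seed sequences, so stages are
individually reproducible and bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .timeindex import days_in_month, month_index

EXPOSURE_MONTHS = (5, 6, 7, 8, 9, 10, 11)
# relative frequency of exposed months May..November; September modal
EXPOSURE_MONTH_WEIGHTS = (0.04, 0.07, 0.12, 0.22, 0.33, 0.14, 0.08)

AGE_FRACTIONS = {"<15": 0.19, "15-29": 0.20, "30-44": 0.19, "45-59": 0.19, ">=60": 0.23}
SEX_FRACTIONS = {"female": 0.51, "male": 0.49}
# relative psychoactive-death rate multipliers by age band and sex
AGE_RATE_MULT = {"<15": 0.02, "15-29": 0.8, "30-44": 1.5, "45-59": 1.6, ">=60": 0.7}
SEX_RATE_MULT = {"female": 0.45, "male": 1.55}
CATEGORY_SHARES = {"overdose": 0.58, "mental_behavioral": 0.17, "alcohol_induced": 0.25}
SUBCLASS_OF = {"overdose": "acute", "mental_behavioral": "chronic", "alcohol_induced": "chronic"}

_ICD10_CODES = {
    "overdose": ("X42", "X44", "X41", "Y12"),
    "mental_behavioral": ("F10.2", "F11.2", "F14.1", "F19.2"),
    "alcohol_induced": ("K70.3", "K70.0", "I42.6", "K85.2"),
}
_ICD9_CODES = {
    "overdose": ("E850", "E854", "E980.0", "E858"),
    "mental_behavioral": ("303", "304", "305"),
    "alcohol_induced": ("571.2", "571.0", "425.5"),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic panel generator."""

    n_counties: int = 30
    n_states: int = 3
    year_range: tuple[int, int] = (2010, 2019)
    baseline_monthly_rate: float = 1.0e-4  # deaths per person-month
    planted_lag_log_rr: tuple[float, ...] = (0.05, 0.0, 0.0, 0.0)
    trend_breakpoint: tuple[int, int] = (2015, 12)  # last (year, month) of period 1
    trend_slopes: tuple[float, float] = (0.05, 0.10)  # log-rate per year, pre/post
    seasonal_amplitude: float = 0.1
    temp_effect_knots: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (10.0, 0.01),
        (20.0, 0.03),
        (30.0, 0.06),
    )
    overdispersion: float = 0.05  # NB: var = mu + overdispersion * mu^2
    exposure_rate: float = 1.0  # expected exposed county-months / county / year
    hurricane_day_prob: float = 0.045
    exposure_day_geom_p: float = 0.3  # zero-truncated geometric, median 2 days
    county_effect_sd: float = 0.2
    population_log_mean: float = np.log(8.0e4)
    population_log_sd: float = 0.7
    subgroup_log_rr: dict | None = None  # e.g. {"sex": {"female": (...), "male": (...)}}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 2:
            raise ValueError("invalid config: n_counties must be >= 2")
        if self.n_states < 1:
            raise ValueError("invalid config: n_states must be >= 1")
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("invalid config: year_range must be increasing")
        if self.baseline_monthly_rate <= 0:
            raise ValueError("invalid config: baseline_monthly_rate must be > 0")
        if self.overdispersion < 0 or self.exposure_rate < 0 or self.seasonal_amplitude < 0:
            raise ValueError("invalid config: rates and amplitudes must be non-negative")

    @property
    def start_year(self) -> int:
        return self.year_range[0]

    @property
    def n_years(self) -> int:
        return self.year_range[1] - self.year_range[0] + 1

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    @property
    def lag_order(self) -> int:
        return len(self.planted_lag_log_rr) - 1


@dataclass
class CountyTable:
    """Static county attributes with adjacency and annual populations."""

    table: pd.DataFrame  # county_id, state, poverty_pct, minority_pct
    adjacency: nx.Graph
    population: pd.DataFrame  # county_id, year, age_group, sex, population

    @property
    def county_ids(self) -> list[str]:
        return list(self.table["county_id"])

    def annual_totals(self) -> pd.DataFrame:
        return (
            self.population.groupby(["county_id", "year"], sort=True)["population"]
            .sum()
            .reset_index()
        )


@dataclass
class SyntheticPanel:
    """One generated study: inputs, outcomes, and the planted truth."""

    counties: CountyTable
    exposure: pd.DataFrame
    temperature: pd.DataFrame
    deaths: pd.DataFrame
    truth: dict = field(default_factory=dict)
    config: GeneratorConfig | None = None

    @property
    def population(self) -> pd.DataFrame:
        return self.counties.population


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("counties", "exposure", "temperature", "deaths", "records")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.Generator(np.random.PCG64(c)) for n, c in zip(names, children)}


def generate_counties(config: GeneratorConfig, rng: np.random.Generator | None = None) -> CountyTable:
    """Counties with states, adjacency, disadvantage covariates, populations.

    Poverty and minority percentages are drawn from unimodal distributions
    centered near the observed national medians (16% poverty, 18% minority
    residents), so the empirical medians split the counties roughly in
    half.  Adjacency is a connected, symmetric, irreflexive graph built
    from a backbone chain plus random shortcuts.
    """
    if rng is None:
        rng = _substreams(config.seed)["counties"]
    n = config.n_counties
    ids = [f"c{i:04d}" for i in range(n)]
    # contiguous state blocks
    bounds = np.linspace(0, n, config.n_states + 1).astype(int)
    states = np.empty(n, dtype=object)
    for s in range(config.n_states):
        states[bounds[s] : bounds[s + 1]] = f"s{s:02d}"

    poverty = np.clip(rng.normal(16.0, 6.0, size=n), 2.0, 45.0)
    minority = np.clip(np.exp(rng.normal(np.log(18.0), 0.6, size=n)), 1.0, 95.0)
    table = pd.DataFrame(
        {"county_id": ids, "state": states, "poverty_pct": poverty, "minority_pct": minority}
    )

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n - 1):
        graph.add_edge(ids[i], ids[i + 1])
    n_extra = max(1, n // 3)
    for _ in range(n_extra):
        i, j = rng.choice(n, size=2, replace=False)
        if i != j:
            graph.add_edge(ids[int(i)], ids[int(j)])

    base = np.exp(rng.normal(config.population_log_mean, config.population_log_sd, size=n))
    growth = rng.normal(0.005, 0.003, size=n)
    years = np.arange(config.year_range[0], config.year_range[1] + 1)
    rows = []
    for i, cid in enumerate(ids):
        for y in years:
            tot = base[i] * (1.0 + growth[i]) ** (y - years[0])
            for age, fa in AGE_FRACTIONS.items():
                for sex, fs in SEX_FRACTIONS.items():
                    rows.append((cid, int(y), age, sex, max(1.0, round(tot * fa * fs))))
    population = pd.DataFrame(rows, columns=["county_id", "year", "age_group", "sex", "population"])
    return CountyTable(table=table, adjacency=graph, population=population)


def generate_exposure(
    counties: CountyTable, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sparse seasonal exposure panel (dense county-month grid, zero-filled).

    Exposed county-months fall in May-November with September modal;
    exposure-day counts per exposed month follow a zero-truncated geometric
    capped at the days in that calendar month; each exposed day is
    independently a hurricane day with small probability, otherwise gale.
    With a positive exposure rate every county is guaranteed at least one
    exposed month.
    """
    if rng is None:
        rng = _substreams(config.seed)["exposure"]
    start_year = config.start_year
    years = np.arange(config.year_range[0], config.year_range[1] + 1)
    candidates = [(int(y), int(m)) for y in years for m in EXPOSURE_MONTHS]
    weights = np.array([EXPOSURE_MONTH_WEIGHTS[EXPOSURE_MONTHS.index(m)] for _, m in candidates])
    weights = weights / weights.sum()

    records: dict[tuple[str, int], tuple[int, int]] = {}
    for cid in counties.county_ids:
        n_exposed = rng.poisson(config.exposure_rate * config.n_years)
        if config.exposure_rate > 0:
            n_exposed = max(1, min(n_exposed, len(candidates)))
        else:
            n_exposed = 0
        if n_exposed == 0:
            continue
        chosen = rng.choice(len(candidates), size=n_exposed, replace=False, p=weights)
        for k in chosen:
            y, m = candidates[int(k)]
            days = int(rng.geometric(config.exposure_day_geom_p))
            days = min(days, days_in_month(y, m))
            hurr = int(rng.binomial(days, config.hurricane_day_prob))
            records[(cid, month_index(y, m, start_year))] = (days - hurr, hurr)

    rows = []
    for cid in counties.county_ids:
        for t in range(config.n_months):
            gale, hurr = records.get((cid, t), (0, 0))
            y, m = start_year + t // 12, t % 12 + 1
            rows.append((cid, t, y, m, gale + hurr, gale, hurr))
    return pd.DataFrame(
        rows,
        columns=[
            "county_id",
            "month_index",
            "year",
            "month",
            "exposure_days_total",
            "exposure_days_gale",
            "exposure_days_hurricane",
        ],
    )


def generate_temperature(
    counties: CountyTable, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """County-month mean temperature: county sinusoid plus Gaussian noise."""
    if rng is None:
        rng = _substreams(config.seed)["temperature"]
    n = config.n_counties
    level = rng.uniform(12.0, 22.0, size=n)
    amp = rng.uniform(6.0, 12.0, size=n)
    rows = []
    for i, cid in enumerate(counties.county_ids):
        t = np.arange(config.n_months)
        m_cal = t % 12 + 1
        temp = level[i] + amp[i] * np.cos(2 * np.pi * (m_cal - 7) / 12.0)
        temp = temp + rng.normal(0.0, 1.0, size=config.n_months)
        for ti, v in zip(t, temp):
            rows.append((cid, int(ti), float(v)))
    return pd.DataFrame(rows, columns=["county_id", "month_index", "temp_c"])


def _trend(month_idx: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Piecewise log-linear long-term trend, continuous at the breakpoint."""
    t_bp = month_index(*config.trend_breakpoint, config.start_year)
    s_pre, s_post = (s / 12.0 for s in config.trend_slopes)
    center = config.n_months / 2.0
    out = np.where(
        month_idx <= t_bp,
        s_pre * (month_idx - center),
        s_pre * (t_bp - center) + s_post * (month_idx - t_bp),
    )
    return out


def _seasonal(month_cal: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    # late-winter peak in drug-related deaths
    return config.seasonal_amplitude * np.cos(2 * np.pi * (month_cal - 2) / 12.0)


def _temp_effect(temp_c: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    knots = np.asarray(config.temp_effect_knots, dtype=float)
    f = PchipInterpolator(knots[:, 0], knots[:, 1], extrapolate=True)
    return f(temp_c)


def _group_multipliers() -> dict[tuple[str, str], float]:
    """Age x sex rate multipliers normalized to population-weighted mean 1."""
    raw = {
        (a, s): AGE_RATE_MULT[a] * SEX_RATE_MULT[s]
        for a in AGE_FRACTIONS
        for s in SEX_FRACTIONS
    }
    wmean = sum(AGE_FRACTIONS[a] * SEX_FRACTIONS[s] * v for (a, s), v in raw.items())
    return {k: v / wmean for k, v in raw.items()}


def _lagged_exposure(exposure: pd.DataFrame, L: int) -> pd.DataFrame:
    """x_{t-l} per county-month; months before the series start count as 0."""
    out = exposure.sort_values(["county_id", "month_index"]).copy()
    for lag in range(L + 1):
        out[f"x_{lag}"] = (
            out.groupby("county_id")["exposure_days_total"].shift(lag).fillna(0.0)
        )
    return out


def generate_deaths(
    counties: CountyTable,
    exposure: pd.DataFrame,
    temperature: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticPanel:
    """Sample negative-binomial death counts around the planted log-mean.

    log mu = log population + log baseline rate + group multiplier
    + county effect + seasonal term + piecewise trend + temperature effect
    + sum_l beta_l * exposure_days(t - l), per county-month x age x sex
    cell; counts are then split into cause categories multinomially.  The
    truth record stores every planted component plus the expected counts
    used for sampling.
    """
    if rng is None:
        rng = _substreams(config.seed)["deaths"]
    exp_keys = set(zip(exposure["county_id"], exposure["month_index"]))
    temp_keys = set(zip(temperature["county_id"], temperature["month_index"]))
    if exp_keys != temp_keys:
        cid, t = sorted(exp_keys ^ temp_keys)[0]
        raise ValueError(
            f"exposure and temperature panels misaligned at county {cid}, month index {t}"
        )

    L = config.lag_order
    lagged = _lagged_exposure(exposure, L)
    lagged = lagged.merge(temperature, on=["county_id", "month_index"], validate="1:1")
    county_effect = dict(
        zip(
            counties.county_ids,
            rng.normal(0.0, config.county_effect_sd, size=config.n_counties),
        )
    )
    mults = _group_multipliers()
    betas = np.asarray(config.planted_lag_log_rr, dtype=float)

    def betas_for(age: str, sex: str) -> np.ndarray:
        if config.subgroup_log_rr:
            axis, table = next(iter(config.subgroup_log_rr.items()))
            level = {"sex": sex, "age_group": age}[axis]
            if level in table:
                return np.asarray(table[level], dtype=float)
        return betas

    lagged["ceff"] = lagged["county_id"].map(county_effect)
    lagged["seasonal"] = _seasonal(lagged["month"].to_numpy(), config)
    lagged["trend"] = _trend(lagged["month_index"].to_numpy(), config)
    lagged["temp_eff"] = _temp_effect(lagged["temp_c"].to_numpy(), config)
    xcols = [f"x_{l}" for l in range(L + 1)]
    X = lagged[xcols].to_numpy()

    pop = counties.population.copy()
    pop["month_year"] = pop["year"]
    rows = []
    mu_rows = []
    base_log = (
        lagged["ceff"] + lagged["seasonal"] + lagged["trend"] + lagged["temp_eff"]
    ).to_numpy() + np.log(config.baseline_monthly_rate)
    pop_lookup = {
        (r.county_id, r.year, r.age_group, r.sex): r.population
        for r in pop.itertuples()
    }
    cids = lagged["county_id"].to_numpy()
    years = lagged["year"].to_numpy()
    tidx = lagged["month_index"].to_numpy()
    categories = list(CATEGORY_SHARES)
    shares = np.array([CATEGORY_SHARES[c] for c in categories])

    for age in AGE_FRACTIONS:
        for sex in SEX_FRACTIONS:
            b = betas_for(age, sex)
            eta = base_log + np.log(mults[(age, sex)]) + X @ b
            pops = np.array(
                [pop_lookup[(c, int(y), age, sex)] for c, y in zip(cids, years)]
            )
            mu = pops * np.exp(eta)
            if config.overdispersion > 0:
                nshape = 1.0 / config.overdispersion
                counts = rng.negative_binomial(nshape, 1.0 / (1.0 + config.overdispersion * mu))
            else:
                counts = rng.poisson(mu)
            for i, cnt in enumerate(counts):
                mu_rows.append((cids[i], int(tidx[i]), age, sex, float(mu[i])))
                if cnt == 0:
                    continue
                split = rng.multinomial(int(cnt), shares)
                for cat, k in zip(categories, split):
                    if k > 0:
                        rows.append(
                            (cids[i], int(tidx[i]), age, sex, cat, SUBCLASS_OF[cat], int(k))
                        )

    deaths = pd.DataFrame(
        rows,
        columns=["county_id", "month_index", "age_group", "sex", "category", "subclass", "deaths"],
    )
    mu_df = pd.DataFrame(mu_rows, columns=["county_id", "month_index", "age_group", "sex", "mu"])
    truth = {
        "planted_lag_log_rr": tuple(betas),
        "subgroup_log_rr": config.subgroup_log_rr,
        "county_effect": county_effect,
        "group_multipliers": mults,
        "baseline_monthly_rate": config.baseline_monthly_rate,
        "trend_breakpoint": config.trend_breakpoint,
        "trend_slopes": config.trend_slopes,
        "seasonal_amplitude": config.seasonal_amplitude,
        "temp_effect_knots": config.temp_effect_knots,
        "overdispersion": config.overdispersion,
        "mu": mu_df,
    }
    return SyntheticPanel(
        counties=counties,
        exposure=exposure,
        temperature=temperature,
        deaths=deaths,
        truth=truth,
        config=config,
    )


def expected_log_mu(panel: SyntheticPanel) -> pd.DataFrame:
    """Recompute the generator's log-mean from the truth record.

    Internal-consistency helper: evaluates the planted components stored in
    the truth record against the panel's exposure/temperature/population
    data and returns a frame aligned with ``truth["mu"]``.
    """
    cfg = panel.config
    truth = panel.truth
    L = len(truth["planted_lag_log_rr"]) - 1
    lagged = _lagged_exposure(panel.exposure, L)
    lagged = lagged.merge(panel.temperature, on=["county_id", "month_index"], validate="1:1")
    base = (
        lagged["county_id"].map(truth["county_effect"]).to_numpy()
        + _seasonal(lagged["month"].to_numpy(), cfg)
        + _trend(lagged["month_index"].to_numpy(), cfg)
        + _temp_effect(lagged["temp_c"].to_numpy(), cfg)
        + np.log(truth["baseline_monthly_rate"])
    )
    X = lagged[[f"x_{l}" for l in range(L + 1)]].to_numpy()
    pop_lookup = {
        (r.county_id, r.year, r.age_group, r.sex): r.population
        for r in panel.counties.population.itertuples()
    }
    rows = []
    for age in AGE_FRACTIONS:
        for sex in SEX_FRACTIONS:
            if cfg.subgroup_log_rr:
                axis, table = next(iter(cfg.subgroup_log_rr.items()))
                level = {"sex": sex, "age_group": age}[axis]
                b = np.asarray(table.get(level, truth["planted_lag_log_rr"]), dtype=float)
            else:
                b = np.asarray(truth["planted_lag_log_rr"], dtype=float)
            eta = base + np.log(truth["group_multipliers"][(age, sex)]) + X @ b
            for i in range(len(lagged)):
                p = pop_lookup[(lagged["county_id"].iat[i], int(lagged["year"].iat[i]), age, sex)]
                rows.append(
                    (
                        lagged["county_id"].iat[i],
                        int(lagged["month_index"].iat[i]),
                        age,
                        sex,
                        np.log(p) + eta[i],
                    )
                )
    return pd.DataFrame(rows, columns=["county_id", "month_index", "age_group", "sex", "log_mu"])


def generate_panel(config: GeneratorConfig) -> SyntheticPanel:
    """Full pipeline: counties -> exposure -> temperature -> deaths."""
    streams = _substreams(config.seed)
    counties = generate_counties(config, streams["counties"])
    exposure = generate_exposure(counties, config, streams["exposure"])
    temperature = generate_temperature(counties, config, streams["temperature"])
    return generate_deaths(counties, exposure, temperature, config, streams["deaths"])


def death_records(panel: SyntheticPanel, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Expand the aggregated death panel to record level with ICD codes.

    Used to exercise the classification stage end to end: aggregating the
    emitted records with the default code map returns the panel counts.
    Years before 1999 get ICD-9 codes, later years ICD-10.
    """
    if rng is None:
        rng = _substreams(panel.config.seed)["records"]
    start_year = panel.config.start_year
    age_bands = {"<15": (0, 14), "15-29": (15, 29), "30-44": (30, 44), "45-59": (45, 59), ">=60": (60, 85)}
    rows = []
    for r in panel.deaths.itertuples():
        year = start_year + r.month_index // 12
        month = r.month_index % 12 + 1
        version = 9 if year < 1999 else 10
        pool = (_ICD9_CODES if version == 9 else _ICD10_CODES)[r.category]
        lo, hi = age_bands[r.age_group]
        for _ in range(int(r.deaths)):
            rows.append(
                (
                    r.county_id,
                    year,
                    month,
                    int(rng.integers(lo, hi + 1)),
                    r.sex,
                    version,
                    pool[int(rng.integers(len(pool)))],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["county_id", "year", "month", "age_years", "sex", "icd_version", "icd_code"],
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    return d
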