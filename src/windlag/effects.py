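"""Translation of lag-coefficient posteriors into reported quantities.

A posterior draw ``beta`` of a log rate ratio per additional exposure day
becomes a percent change ``100 * (exp(beta) - 1)``; multiplying the
relative change by a baseline age-standardized monthly death rate per
million (R0) gives additional deaths per million (DPM).  An association is
reported positive when its equal-tailed 95% credible interval is entirely
non-negative, negative when entirely non-positive, and null otherwise.
Subgroup contrasts are posterior mean differences of group-specific log
rate ratios, formed by pairing independent draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_DRAWS = 1000


def _summaries(draws: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.mean(draws)),
        float(np.percentile(draws, 2.5)),
        float(np.percentile(draws, 97.5)),
    )


def _check_draws(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float).ravel()
    n_bad = int(np.sum(~np.isfinite(draws)))
    if n_bad:
        raise ValueError(f"{n_bad} non-finite posterior draw(s)")
    if len(draws) < MIN_DRAWS:
        warnings.warn(
            f"only {len(draws)} draws; credible intervals are reported from "
            f">= {MIN_DRAWS} draws",
            stacklevel=3,
        )
    return draws


def percent_change(beta_draws) -> tuple[float, float, float]:
    """Mean and equal-tailed 95% CrI of 100*(exp(beta)-1), in percent."""
    draws = _check_draws(beta_draws)
    return _summaries(100.0 * np.expm1(draws))


def to_dpm(percent_draws, baseline_rate: float) -> tuple[float, float, float]:
    """Scale percent-change draws by a baseline monthly death rate per 1e6."""
    if baseline_rate <= 0:
        raise ValueError("baseline rate R0 must be positive")
    draws = _check_draws(percent_draws)
    return _summaries(draws * (baseline_rate / 100.0))


def classify_association(lower95: float, upper95: float) -> str:
    """CrI-sign reporting rule: positive / negative / null."""
    if lower95 > upper95:
        raise ValueError("interval endpoints out of order")
    if lower95 >= 0:
        return "positive"
    if upper95 <= 0:
        return "negative"
    return "null"


@dataclass
class SubgroupContrast:
    """Per-lag posterior mean differences between two groups' coefficients."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # lag, delta_mean, lower95, upper95, meaningful
    approximate: bool = False  # True when built from summaries, not draws


def subgroup_difference(result_a, result_b, group_a: str = "A", group_b: str = "B",
                        seed: int | None = None) -> SubgroupContrast:
    """Contrast two independently fitted subgroup posteriors, lag by lag.

    Draws are paired by index (the fits share no parameters, so the
    groups' posteriors are treated as independent).  If either result
    lacks draws, a Gaussian approximation on the log scale is used and
    flagged.
    """
    lags_a = np.asarray(result_a.lags)
    lags_b = np.asarray(result_b.lags)
    if not np.array_equal(lags_a, lags_b):
        raise ValueError("subgroup results have mismatched lag sets")
    draws_a = getattr(result_a, "draws", None)
    draws_b = getattr(result_b, "draws", None)
    approximate = draws_a is None or draws_b is None
    rows = []
    if not approximate:
        n = min(len(draws_a), len(draws_b))
        rng = np.random.default_rng(seed)
        ia = rng.permutation(len(draws_a))[:n] if len(draws_a) != n else np.arange(n)
        ib = rng.permutation(len(draws_b))[:n] if len(draws_b) != n else np.arange(n)
        delta = draws_a[ia] - draws_b[ib]
        for l in lags_a:
            mean, lo, hi = _summaries(delta[:, l])
            rows.append((int(l), mean, lo, hi, classify_association(lo, hi) != "null"))
    else:
        from scipy import stats

        for l in lags_a:
            ma, (la, ua) = result_a.beta_mean[l], result_a.beta_ci[l]
            mb, (lb, ub) = result_b.beta_mean[l], result_b.beta_ci[l]
            sa = (ua - la) / (2 * stats.norm.ppf(0.975))
            sb = (ub - lb) / (2 * stats.norm.ppf(0.975))
            sd = np.hypot(sa, sb)
            mean = ma - mb
            lo, hi = stats.norm.interval(0.95, loc=mean, scale=sd)
            rows.append((int(l), float(mean), float(lo), float(hi),
                         classify_association(lo, hi) != "null"))
    table = pd.DataFrame(
        rows, columns=["lag", "delta_mean", "lower95", "upper95", "meaningful"]
    )
    return SubgroupContrast(group_a=group_a, group_b=group_b, table=table,
                            approximate=approximate)


def categorize_disadvantage(counties: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Cross-classify counties by median-dichotomized poverty and minority %.

    Medians are computed once over counties with both covariates present;
    values strictly above the median flag "high", at-or-below flag "low"
    (ties go low).  Counties missing a covariate are excluded and counted.
    Returns ``(table, meta)`` where the table adds ``poverty_flag``,
    ``minority_flag`` and ``category`` columns.
    """
    req = {"county_id", "poverty_pct", "minority_pct"}
    if not req <= set(counties.columns):
        raise ValueError(f"county table needs columns {sorted(req)}")
    df = counties.copy()
    ok = df["poverty_pct"].notna() & df["minority_pct"].notna()
    n_excluded = int((~ok).sum())
    df = df.loc[ok].copy()
    med_pov = float(df["poverty_pct"].median())
    med_min = float(df["minority_pct"].median())
    df["poverty_flag"] = np.where(df["poverty_pct"] > med_pov, "high", "low")
    df["minority_flag"] = np.where(df["minority_pct"] > med_min, "high", "low")
    df["category"] = df["poverty_flag"] + "-" + df["minority_flag"]
    counts = df["category"].value_counts().to_dict()
    meta = {
        "median_poverty_pct": med_pov,
        "median_minority_pct": med_min,
        "tie_rule": "at-or-below median is low",
        "n_included": len(df),
        "n_excluded_missing": n_excluded,
        "category_counts": counts,
    }
    return df, meta


def effect_summary(result, baseline_dpm: float, group: str = "all",
                   strength: str = "total") -> pd.DataFrame:
    """Per-lag percent change, DPM and CrI-sign label for one fitted result.

    DPM equals percent/100 times the baseline rate at the mean and both
    interval endpoints by construction.
    """
    if baseline_dpm <= 0:
        raise ValueError("baseline rate R0 must be positive")
    rows = []
    for l in result.lags:
        pct_draws = 100.0 * np.expm1(_check_draws(result.draws[:, l]))
        pm, pl, ph = _summaries(pct_draws)
        dm, dl, dh = (v * baseline_dpm / 100.0 for v in (pm, pl, ph))
        rows.append(
            (group, strength, int(l), pm, pl, ph, dm, dl, dh,
             classify_association(pl, ph))
        )
    return pd.DataFrame(
        rows,
        columns=["group", "strength_class", "lag", "pct_mean", "pct_lo", "pct_hi",
                 "dpm_mean", "dpm_lo", "dpm_hi", "label"],
    )


def baseline_rate_per_million(
    mortality: pd.DataFrame,
    annual_population: pd.DataFrame,
    year: int,
    start_year: int,
    standard_weights: dict[str, float] | None = None,
) -> float:
    """Median county age-standardized monthly death rate per 1 000 000.

    Direct standardization: for each county, the age-specific monthly
    death rate in ``year`` (deaths over 12, divided by the age-group
    population) is weighted by the standard population weights; the
    median over counties, scaled to one million, is the baseline R0 used
    for the DPM translation.  ``standard_weights`` defaults to the pooled
    age distribution of the supplied population.
    """
    months = range((year - start_year) * 12, (year - start_year + 1) * 12)
    mort = mortality.loc[mortality["month_index"].isin(months)]
    pop = annual_population.loc[annual_population["year"] == year]
    if len(pop) == 0:
        raise ValueError(f"no population data for year {year}")
    pop_age = pop.groupby(["county_id", "age_group"], sort=True)["population"].sum()
    if standard_weights is None:
        tot = pop.groupby("age_group")["population"].sum()
        standard_weights = (tot / tot.sum()).to_dict()
    deaths_age = mort.groupby(["county_id", "age_group"], sort=True)["deaths"].sum()
    rates = []
    for county in pop["county_id"].unique():
        r = 0.0
        for age, w in standard_weights.items():
            p = pop_age.get((county, age), 0.0)
            if p <= 0:
                continue
            d = deaths_age.get((county, age), 0.0)
            r += w * (d / 12.0) / p
        rates.append(r)
    return float(np.median(rates) * 1.0e6)
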