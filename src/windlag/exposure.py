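"""Exposure assembly: daily winds -> monthly exposure-day panels, lags, offsets.

A county counts as tropical-cyclone exposed on a day when the maximum
sustained wind at its population mean center reaches 34 knots.  Days are
classed by strength: gale to violent storm (34-63 kt) and hurricane
(>=64 kt).  Monthly counts of exposed days per class are the exposure
covariates; distributed-lag vectors carry the counts from the index month
and the L preceding months.  Annual population counts are anchored to June
and interpolated linearly to months to form the rate offset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .timeindex import june_index, month_index

GALE_MIN_KT = 34.0
HURRICANE_MIN_KT = 64.0


def count_exposure_days(
    daily_winds: pd.DataFrame,
    start_year: int | None = None,
    end_year: int | None = None,
) -> pd.DataFrame:
    """Aggregate daily maximum sustained winds into a monthly exposure panel.

    Parameters
    ----------
    daily_winds : DataFrame with columns ``county_id``, ``date`` (ISO-8601
        string or datetime), ``wind_kt`` (non-negative knots).
    start_year, end_year : span of the output panel; default to the span of
        the input dates.  Every county in the input gets a dense,
        contiguous month index over the span (zero-filled).

    Returns
    -------
    DataFrame with columns ``county_id``, ``month_index``, ``year``,
    ``month``, ``exposure_days_total``, ``exposure_days_gale``,
    ``exposure_days_hurricane``.
    """
    df = daily_winds.copy()
    required = {"county_id", "date", "wind_kt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"daily winds missing columns: {sorted(missing)}")
    bad = df.index[df["wind_kt"] < 0]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"negative wind speed {row['wind_kt']} kt at county "
            f"{row['county_id']}, date {row['date']} (row {bad[0]})"
        )
    dates = pd.to_datetime(df["date"])
    if start_year is None:
        start_year = int(dates.dt.year.min())
    if end_year is None:
        end_year = int(dates.dt.year.max())

    df = df.assign(year=dates.dt.year.to_numpy(), month=dates.dt.month.to_numpy())
    df["gale"] = ((df["wind_kt"] >= GALE_MIN_KT) & (df["wind_kt"] < HURRICANE_MIN_KT)).astype(int)
    df["hurricane"] = (df["wind_kt"] >= HURRICANE_MIN_KT).astype(int)
    monthly = (
        df.groupby(["county_id", "year", "month"], sort=True)[["gale", "hurricane"]]
        .sum()
        .reset_index()
    )
    monthly["month_index"] = [
        month_index(y, m, start_year) for y, m in zip(monthly["year"], monthly["month"])
    ]

    counties = sorted(df["county_id"].unique())
    n_months = (end_year - start_year + 1) * 12
    grid = pd.MultiIndex.from_product(
        [counties, range(n_months)], names=["county_id", "month_index"]
    )
    panel = (
        monthly.set_index(["county_id", "month_index"])[["gale", "hurricane"]]
        .reindex(grid, fill_value=0)
        .reset_index()
    )
    panel["year"] = start_year + panel["month_index"] // 12
    panel["month"] = panel["month_index"] % 12 + 1
    panel = panel.rename(
        columns={"gale": "exposure_days_gale", "hurricane": "exposure_days_hurricane"}
    )
    panel["exposure_days_total"] = (
        panel["exposure_days_gale"] + panel["exposure_days_hurricane"]
    )
    cols = [
        "county_id",
        "month_index",
        "year",
        "month",
        "exposure_days_total",
        "exposure_days_gale",
        "exposure_days_hurricane",
    ]
    return panel[cols]


def build_lag_matrix(
    panel: pd.DataFrame,
    L: int = 3,
    column: str = "exposure_days_total",
) -> pd.DataFrame:
    """Attach distributed-lag columns ``lag_0 .. lag_L`` to an exposure panel.

    ``lag_l`` at month index t is the exposure-day count at t - l.  Months
    whose lag window reaches before the start of the county's series are
    flagged ``lag_complete = False``; they stay in the output but the model
    excludes them from fitting.  Lags cross calendar-year boundaries freely.
    """
    if L < 0:
        raise ValueError("lag length L must be non-negative")
    if column not in panel.columns:
        raise ValueError(f"column {column!r} not in panel")
    out = []
    for county, grp in panel.groupby("county_id", sort=True):
        grp = grp.sort_values("month_index").reset_index(drop=True)
        idx = grp["month_index"].to_numpy()
        steps = np.diff(idx)
        if np.any(steps != 1):
            gap_at = int(idx[np.argmax(steps != 1)])
            raise ValueError(
                f"month index of county {county} has a gap after index {gap_at}"
            )
        x = grp[column].to_numpy(dtype=float)
        for lag in range(L + 1):
            shifted = np.full(len(x), np.nan)
            if lag == 0:
                shifted[:] = x
            else:
                shifted[lag:] = x[:-lag]
            grp[f"lag_{lag}"] = shifted
        grp["lag_complete"] = ~np.isnan(grp[[f"lag_{l}" for l in range(L + 1)]]).any(axis=1)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def interpolate_population(
    annual: pd.DataFrame,
    start_year: int | None = None,
    group_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """June-anchored linear interpolation of annual population to months.

    Annual person counts are assigned to June of their year; months between
    consecutive Junes vary linearly; months before the first June and after
    the last June extrapolate the nearest segment's slope, floored at one
    person so log-offsets stay finite.

    ``annual`` needs columns ``county_id``, ``year``, ``population`` plus
    any subgroup columns named in ``group_cols`` (auto-detected from
    ``age_group``/``sex`` if present).  Output covers January of the first
    year through December of the last year.
    """
    for col in ("county_id", "year", "population"):
        if col not in annual.columns:
            raise ValueError(f"annual population missing column {col!r}")
    if (annual["population"] <= 0).any():
        bad = annual.loc[annual["population"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive annual population for county {bad['county_id']}, "
            f"year {int(bad['year'])}"
        )
    if group_cols is None:
        group_cols = tuple(c for c in ("age_group", "sex") if c in annual.columns)
    keys = ["county_id", *group_cols]
    if start_year is None:
        start_year = int(annual["year"].min())
    end_year = int(annual["year"].max())
    months = np.arange((end_year - start_year + 1) * 12)

    frames = []
    for key, grp in annual.groupby(keys, sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if len(years) < 2:
            raise ValueError(
                f"need >=2 annual values per county-subgroup, got {len(years)} for {key}"
            )
        if np.any(np.diff(years) != 1):
            raise ValueError(f"annual series for {key} is not consecutive")
        anchors = np.array([june_index(int(y), start_year) for y in years], dtype=float)
        pops = grp["population"].to_numpy(dtype=float)
        # np.interp clamps outside the anchor span; extend with the edge
        # segment slopes instead, then floor at 1 person.
        interp = np.interp(months, anchors, pops)
        lo_slope = (pops[1] - pops[0]) / (anchors[1] - anchors[0])
        hi_slope = (pops[-1] - pops[-2]) / (anchors[-1] - anchors[-2])
        before = months < anchors[0]
        after = months > anchors[-1]
        interp[before] = pops[0] + lo_slope * (months[before] - anchors[0])
        interp[after] = pops[-1] + hi_slope * (months[after] - anchors[-1])
        interp = np.maximum(interp, 1.0)
        frame = pd.DataFrame({"month_index": months, "population": interp})
        if isinstance(key, tuple):
            for col, val in zip(keys, key):
                frame[col] = val
        else:
            frame[keys[0]] = key
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[[*keys, "month_index", "population"]]


def correlate_years(values_a: pd.Series, values_b: pd.Series) -> float:
    """Pearson correlation between two county-indexed percentage vectors.

    Used to check temporal stability of county covariates measured in two
    different years; vectors are aligned on their county index.
    """
    a, b = values_a.align(values_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError(f"need >=3 aligned counties, got {len(a)}")
    if np.isclose(a.std(ddof=0), 0) or np.isclose(b.std(ddof=0), 0):
        raise ValueError("correlation undefined: zero variance in input")
    return float(stats.pearsonr(a.to_numpy(), b.to_numpy())[0])
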