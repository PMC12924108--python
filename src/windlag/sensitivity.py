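"""Robustness drivers: lag windows, breakpoints, leave-one-state-out,
acute-vs-chronic subcauses, and late-period restriction.

Every variant refits the main model with one controlled change and reuses
the base configuration's seed policy, so differences between rows reflect
the data change, not Monte-Carlo noise.  Grid outputs are row-complete:
a variant that fails to fit appears with its error message rather than
disappearing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import CaseCrossoverModel, ModelConfig, PanelInputs

VARIANTS = ("lag_window", "breakpoint", "leave_one_state_out", "subcause", "period_restrict")


@dataclass
class SensitivitySpec:
    """One requested robustness variant and its parameters."""

    variant: str
    params: dict
    base: ModelConfig

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown sensitivity variant {self.variant!r}")


def _fit(inputs: PanelInputs, config: ModelConfig, **kwargs):
    model = CaseCrossoverModel.from_inputs(inputs, config=config, **kwargs)
    return model.fit()


def run_lag_window_grid(
    inputs: PanelInputs, L_values, config: ModelConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Refit with alternative post-exposure windows; tabulate shared lags."""
    config = config or ModelConfig()
    results: dict[int, object] = {}
    rows = []
    for L in L_values:
        cfg = replace(config, lag=int(L))
        try:
            res = _fit(inputs, cfg)
            results[int(L)] = res
            ci = res.beta_ci
            for l in res.lags:
                rows.append((int(L), int(l), res.beta_mean[l], ci[l, 0], ci[l, 1], "ok"))
        except Exception as exc:  # row-complete grid: record, continue
            results[int(L)] = None
            rows.append((int(L), np.nan, np.nan, np.nan, np.nan, f"error: {exc}"))
    table = pd.DataFrame(rows, columns=["L", "lag", "mean", "lower95", "upper95", "status"])
    return table, results


def leave_one_state_out(
    inputs: PanelInputs,
    config: ModelConfig | None = None,
    influence_fraction: float = 0.5,
) -> pd.DataFrame:
    """Refit omitting one state at a time; flag influential states.

    A state is flagged when its omission moves any lag's posterior mean by
    more than ``influence_fraction`` of the main fit's CrI half-width.
    """
    config = config or ModelConfig()
    if inputs.counties is None or "state" not in inputs.counties.columns:
        raise ValueError("leave-one-state-out needs a county table with states")
    state_of = inputs.counties.set_index("county_id")["state"]
    states = sorted(state_of.unique())
    if len(states) < 2:
        raise ValueError("need >=2 states")
    main = _fit(inputs, config)
    half_width = (main.beta_ci[:, 1] - main.beta_ci[:, 0]) / 2.0
    rows = []
    for st in states:
        keep = state_of.index[state_of != st]
        try:
            res = _fit(inputs, config, counties_include=keep)
            shift = np.abs(res.beta_mean - main.beta_mean)
            flagged = bool(np.any(shift > influence_fraction * half_width))
            for l in res.lags:
                rows.append((st, int(l), res.beta_mean[l], res.beta_ci[l, 0],
                             res.beta_ci[l, 1], flagged, "ok"))
        except RuntimeError as exc:
            for l in main.lags:
                rows.append((st, int(l), np.nan, np.nan, np.nan, False,
                             f"degenerate: {exc}"))
    return pd.DataFrame(
        rows, columns=["omitted_state", "lag", "mean", "lower95", "upper95",
                       "influential", "status"]
    )


def run_subcause(
    inputs: PanelInputs, config: ModelConfig | None = None
) -> dict[str, object]:
    """Separate fits on acute (overdose) vs chronic outcome panels."""
    config = config or ModelConfig()
    out: dict[str, object] = {}
    for subclass in ("acute", "chronic"):
        sub = inputs.mortality.loc[inputs.mortality["subclass"] == subclass]
        if len(sub) == 0 or sub["deaths"].sum() == 0:
            warnings.warn(f"subclass {subclass!r} empty; fit skipped", stacklevel=2)
            out[subclass] = None
            continue
        out[subclass] = _fit(inputs, config, subset={"subclass": subclass})
    return out


def restrict_period(inputs: PanelInputs, start_year: int) -> PanelInputs:
    """Drop all county-months before January of ``start_year``.

    Month indices are rebased to the new start year and lag vectors are
    rebuilt by the subsequent fit, so early months of the restricted panel
    are again flagged lag-incomplete.
    """
    if inputs.start_year is None:
        raise ValueError("inputs.start_year required to restrict the period")
    offset = (start_year - inputs.start_year) * 12
    if offset < 0:
        raise ValueError("start_year precedes the panel start")

    def _cut(df):
        out = df.loc[df["month_index"] >= offset].copy()
        out["month_index"] = out["month_index"] - offset
        return out

    exposure = _cut(inputs.exposure)
    if len(exposure) == 0:
        raise ValueError("period restriction leaves an empty panel")
    mortality = _cut(inputs.mortality)
    temperature = _cut(inputs.temperature) if inputs.temperature is not None else None
    pop = inputs.annual_population.loc[
        inputs.annual_population["year"] >= start_year
    ].copy()
    return PanelInputs(
        mortality=mortality,
        exposure=exposure,
        annual_population=pop,
        temperature=temperature,
        counties=inputs.counties,
        adjacency=inputs.adjacency,
        start_year=start_year,
    )


def run_breakpoint_variants(
    inputs: PanelInputs, breakpoints, config: ModelConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Refit with alternative trend breakpoints at fixed total spline df.

    The total spline flexibility of the base fit is preserved and split
    between the two periods in proportion to their lengths, so rows
    isolate the breakpoint choice rather than a change in smoothness.
    """
    config = config or ModelConfig()
    base_model = CaseCrossoverModel.from_inputs(inputs, config=config)
    total_df = max(len(base_model.design.spline_cols), 4)
    t_min = int(base_model.design.frame["month_index"].min())
    t_max = int(base_model.design.frame["month_index"].max())
    sy = inputs.start_year or 0
    rows = []
    results = {}
    for bp in breakpoints:
        bp = tuple(bp)
        t_bp = (bp[0] - sy) * 12 + bp[1] - 1
        frac = np.clip((t_bp - t_min + 1) / max(t_max - t_min + 1, 1), 0.1, 0.9)
        pre_df = max(2, int(round(total_df * frac)))
        post_df = max(2, total_df - pre_df)
        cfg = replace(config, breakpoint=bp, spline_df=(pre_df, post_df))
        try:
            res = _fit(inputs, cfg)
            results[bp] = res
            for l in res.lags:
                rows.append((f"{bp[0]}-{bp[1]:02d}", int(l), res.beta_mean[l],
                             res.beta_ci[l, 0], res.beta_ci[l, 1], "ok"))
        except Exception as exc:
            results[bp] = None
            rows.append((f"{bp[0]}-{bp[1]:02d}", np.nan, np.nan, np.nan, np.nan,
                         f"error: {exc}"))
    table = pd.DataFrame(rows, columns=["breakpoint", "lag", "mean", "lower95",
                                        "upper95", "status"])
    return table, results
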