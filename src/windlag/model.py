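"""Time-stratified case-crossover model for exposure-day effects on death rates.

The design conditions on county-month strata: every September of one
county across the study years forms one stratum, and a month containing
tropical-cyclone-exposed days (a case) is compared with the same calendar
month of all other years in the same county.  Conditioning on the stratum
total turns the overdispersed Poisson likelihood into a within-stratum
multinomial, removing all time-invariant county characteristics and mean
seasonality.  The linear predictor carries

* unconstrained distributed-lag terms ``beta_0..beta_L`` (log rate ratio
  per additional exposure day, in the exposure month and L months after);
* piecewise natural-cubic-spline long-term trends, fitted separately
  before and after a breakpoint (default December 2015) with no
  continuity constraint across it;
* a second-order random-walk (RW2) effect over binned monthly mean
  temperature with a weakly informative Gamma prior on its precision and
  a sum-to-zero constraint;
* a log monthly-population offset (June-anchored interpolation), so the
  coefficients act on death *rates*;
* overdispersion via a log-normal observation-level random effect
  (default) or a Dirichlet-multinomial conditional (negative-binomial
  mode); optionally an intrinsic-CAR random effect on county-level
  exposure sensitivity to borrow strength between adjacent counties.

Typical use::

    model = CaseCrossoverModel.from_panels(mortality, exposure, population,
                                           temperature, config=ModelConfig())
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy

from . import _fit
from .exposure import build_lag_matrix, interpolate_population
from .timeindex import month_index

__all__ = [
    "ModelConfig",
    "PanelInputs",
    "CaseCrossoverModel",
    "CaseCrossoverResults",
    "build_strata",
]


@dataclass
class PanelInputs:
    """Bundle of the aligned panels one study is fitted from."""

    mortality: pd.DataFrame
    exposure: pd.DataFrame
    annual_population: pd.DataFrame
    temperature: pd.DataFrame | None = None
    counties: pd.DataFrame | None = None  # county_id, state, covariates
    adjacency: object | None = None
    start_year: int | None = None

    @classmethod
    def from_synthetic(cls, panel) -> "PanelInputs":
        """Adapt a generated :class:`~windlag.synthetic.SyntheticPanel`."""
        return cls(
            mortality=panel.deaths,
            exposure=panel.exposure,
            annual_population=panel.counties.population,
            temperature=panel.temperature,
            counties=panel.counties.table,
            adjacency=panel.counties.adjacency,
            start_year=panel.config.start_year if panel.config else None,
        )


@dataclass
class ModelConfig:
    """Specification of the case-crossover fit."""

    lag: int = 3
    exposure_class: str = "total"  # total | gale | hurricane
    breakpoint: tuple[int, int] | None = (2015, 12)  # last month of period 1
    knots_per_years: float = 3.0  # one internal spline knot per this many years
    spline_df: tuple[int, int] | None = None  # explicit (pre, post) override
    use_trend: bool = True
    use_temperature: bool = True
    temperature_bins: int = 20
    rw2_prior: tuple[float, float] = (1.0, 0.01)  # Gamma(shape, rate) on precision
    olre_prior: tuple[float, float] = (1.0, 0.01)
    overdispersion: str = "lognormal_olre"  # lognormal_olre | negative_binomial | none
    inference: str = "map_laplace"  # map_laplace | mcmc
    chains: int = 4
    draws: int = 1000
    warmup: int = 300
    seed: int = 0
    beta_prior_sd: float = 10.0  # np.inf => flat
    spline_prior_sd: float = 10.0
    spatial_pooling: bool = False
    car_prior: tuple[float, float] = (1.0, 0.01)
    drop_noninformative: bool = False

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.temperature_bins < 3:
            raise ValueError("temperature_bins must be >= 3")
        if self.exposure_class not in ("total", "gale", "hurricane"):
            raise ValueError("exposure_class must be total, gale or hurricane")
        if self.overdispersion not in ("lognormal_olre", "negative_binomial", "none"):
            raise ValueError("unknown overdispersion mode")
        if self.inference not in ("map_laplace", "mcmc"):
            raise ValueError("inference must be map_laplace or mcmc")

    @property
    def n_draws_total(self) -> int:
        return self.chains * self.draws


def build_strata(frame: pd.DataFrame) -> pd.DataFrame:
    """Tag county-months with their stratum and exposure-variation status.

    ``frame`` must carry ``county_id``, ``month_index``, ``deaths`` and the
    lag columns ``lag_0..``.  Returns the frame with ``stratum`` (county x
    calendar month code), ``is_case`` (any exposure day in the index
    month), ``informative`` (exposure varies across the stratum members)
    and ``stratum_size`` columns.  Strata with a single member year are
    excluded (their count is reported by the model).
    """
    out = frame.copy()
    out["calendar_month"] = out["month_index"] % 12 + 1
    key = out["county_id"].astype(str) + ":" + out["calendar_month"].astype(str)
    out["stratum"] = pd.Categorical(key).codes
    lag_cols = [c for c in out.columns if c.startswith("lag_")
                and c != "lag_complete"]
    grp = out.groupby("stratum")
    out["stratum_size"] = grp["deaths"].transform("size")
    out["is_case"] = out["lag_0"] > 0
    informative = grp[lag_cols].transform(lambda s: s.nunique() > 1)
    out["informative"] = informative.any(axis=1)
    return out


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray
    groups: _fit.StratumGroups
    lag_cols: np.ndarray
    spline_cols: np.ndarray
    temp_cols: np.ndarray
    car_cols: np.ndarray
    K_temp: np.ndarray | None
    rank_temp: int
    K_car: np.ndarray | None
    rank_car: int
    info: dict
    frame: pd.DataFrame


def _natural_spline(tvals: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic regression spline basis (no intercept column)."""
    uniq = np.unique(tvals)
    # a natural cubic spline without internal knots is a straight line;
    # patsy's cr() also requires df >= 3
    if df < 3 or len(uniq) <= df:
        centered = (tvals - tvals.mean()) / max(tvals.std(), 1.0)
        return centered[:, None]
    return np.asarray(patsy.dmatrix(f"cr(x, df={df}) - 1", {"x": tvals}))


def _sum_zero_basis(B: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^B: (B, B-1)."""
    ones = np.ones((B, 1)) / np.sqrt(B)
    full = np.eye(B) - ones @ ones.T
    w, v = np.linalg.eigh(full)
    return v[:, w > 0.5]


def _second_diff_penalty(B: int) -> np.ndarray:
    D = np.zeros((B - 2, B))
    for i in range(B - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1.0, -2.0, 1.0
    return D.T @ D


def assemble_design(
    frame: pd.DataFrame,
    config: ModelConfig,
    start_year: int,
    adjacency=None,
) -> _Design:
    """Build the numeric design from a merged county-month frame.

    The frame needs ``county_id, month_index, deaths, lag_0..lag_L,
    population`` and (if temperature adjustment is on) ``temp_c``, plus
    the ``lag_complete`` flag from :func:`build_lag_matrix`.  County-months
    with incomplete lag windows are retained in the panel but excluded
    from fitting; non-informative strata are kept by default (they still
    inform trend, temperature, and overdispersion).
    """
    df = frame.copy()
    n_incomplete = int((~df["lag_complete"]).sum()) if "lag_complete" in df else 0
    if "lag_complete" in df:
        df = df.loc[df["lag_complete"]].copy()
    df = build_strata(df)
    n_single = int((df["stratum_size"] < 2).sum())
    df = df.loc[df["stratum_size"] >= 2].copy()
    n_noninf = int((~df["informative"]).sum())
    if config.drop_noninformative:
        df = df.loc[df["informative"]].copy()
    if len(df) == 0:
        raise RuntimeError("no county-months left after stratum construction")
    df["stratum"] = pd.Categorical(df["stratum"]).codes

    lag_cols_names = [f"lag_{l}" for l in range(config.lag + 1)]
    blocks = [df[lag_cols_names].to_numpy(dtype=float)]
    col_labels = list(lag_cols_names)
    spline_cols: list[int] = []

    t = df["month_index"].to_numpy()
    if config.use_trend:
        if config.breakpoint is not None:
            t_bp = month_index(*config.breakpoint, start_year)
        else:
            t_bp = int(t.max())
        pre = t <= t_bp
        post = ~pre
        seg_dfs = config.spline_df
        for seg, mask in (("pre", pre), ("post", post)):
            if mask.sum() == 0:
                continue
            span_years = (t[mask].max() - t[mask].min() + 1) / 12.0
            if seg_dfs is not None:
                df_seg = seg_dfs[0] if seg == "pre" else seg_dfs[1]
            else:
                df_seg = max(2, int(round(span_years / config.knots_per_years)) + 2)
            basis = _natural_spline(t[mask].astype(float), df_seg)
            block = np.zeros((len(df), basis.shape[1]))
            block[mask] = basis
            blocks.append(block)
            start = sum(b.shape[1] for b in blocks[:-1])
            spline_cols.extend(range(start, start + basis.shape[1]))
            col_labels += [f"trend_{seg}_{j}" for j in range(basis.shape[1])]

    temp_cols: list[int] = []
    K_temp = None
    rank_temp = 0
    if config.use_temperature and "temp_c" in df.columns:
        temp = df["temp_c"].to_numpy(dtype=float)
        B = config.temperature_bins
        lo, hi = temp.min(), temp.max()
        if hi > lo:
            edges = np.linspace(lo, hi, B + 1)
            bins = np.clip(np.digitize(temp, edges[1:-1]), 0, B - 1)
            onehot = np.zeros((len(df), B))
            onehot[np.arange(len(df)), bins] = 1.0
            C = _sum_zero_basis(B)
            Z = onehot @ C
            start = sum(b.shape[1] for b in blocks)
            blocks.append(Z)
            temp_cols = list(range(start, start + Z.shape[1]))
            col_labels += [f"temp_{j}" for j in range(Z.shape[1])]
            K_temp = C.T @ _second_diff_penalty(B) @ C
            rank_temp = B - 2
        else:
            warnings.warn("temperature constant; RW2 term dropped", stacklevel=2)

    car_cols: list[int] = []
    K_car = None
    rank_car = 0
    if config.spatial_pooling:
        if adjacency is None:
            raise ValueError("spatial_pooling requires a county adjacency graph")
        import networkx as nx

        counties = sorted(df["county_id"].unique())
        cindex = {c: i for i, c in enumerate(counties)}
        x0 = df["lag_0"].to_numpy(dtype=float)
        Zc = np.zeros((len(df), len(counties)))
        Zc[np.arange(len(df)), df["county_id"].map(cindex).to_numpy()] = x0
        sub = adjacency.subgraph(counties)
        Lap = nx.laplacian_matrix(sub, nodelist=counties).toarray().astype(float)
        # sum-to-zero constraint keeps the county slopes identifiable
        # against the global lag-0 coefficient (ICAR null space)
        C = _sum_zero_basis(len(counties))
        start = sum(b.shape[1] for b in blocks)
        blocks.append(Zc @ C)
        car_cols = list(range(start, start + C.shape[1]))
        col_labels += [f"car_{j}" for j in range(C.shape[1])]
        K_car = C.T @ Lap @ C + 1e-8 * np.eye(C.shape[1])
        rank_car = max(len(counties) - nx.number_connected_components(sub), 1)

    X = np.hstack(blocks)
    y = df["deaths"].to_numpy(dtype=float)
    offset = np.log(df["population"].to_numpy(dtype=float))
    groups = _fit.StratumGroups.from_codes(df["stratum"].to_numpy())
    info = {
        "n_obs": len(df),
        "n_strata": groups.n_strata,
        "n_informative_strata": int(df.loc[df["informative"], "stratum"].nunique()),
        "n_noninformative_obs": n_noninf,
        "n_single_member_excluded": n_single,
        "n_incomplete_lag_excluded": n_incomplete,
        "n_cases": int(df["is_case"].sum()),
        "col_labels": col_labels,
    }
    return _Design(
        y=y,
        X=X,
        offset=offset,
        groups=groups,
        lag_cols=np.arange(config.lag + 1),
        spline_cols=np.array(spline_cols, dtype=int),
        temp_cols=np.array(temp_cols, dtype=int),
        car_cols=np.array(car_cols, dtype=int),
        K_temp=K_temp,
        rank_temp=rank_temp,
        K_car=K_car,
        rank_car=rank_car,
        info=info,
        frame=df,
    )


class CaseCrossoverModel:
    """Bayesian conditional quasi-Poisson case-crossover model.

    Construct directly from a merged frame via :meth:`from_frame`, or from
    the standard panels via :meth:`from_panels`.  ``fit`` returns a
    :class:`CaseCrossoverResults`.
    """

    def __init__(self, design: _Design, config: ModelConfig, adjacency=None):
        self.design = design
        self.config = config
        self.adjacency = adjacency

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: ModelConfig | None = None,
                   start_year: int = 0, adjacency=None) -> "CaseCrossoverModel":
        config = config or ModelConfig()
        design = assemble_design(frame, config, start_year, adjacency)
        return cls(design, config, adjacency)

    @classmethod
    def from_panels(
        cls,
        mortality: pd.DataFrame,
        exposure: pd.DataFrame,
        annual_population: pd.DataFrame,
        temperature: pd.DataFrame | None = None,
        config: ModelConfig | None = None,
        subset: dict | None = None,
        counties_include=None,
        start_year: int | None = None,
        adjacency=None,
    ) -> "CaseCrossoverModel":
        """Assemble the model from mortality/exposure/population panels.

        ``subset`` restricts the outcome panel (keys among ``age_group``,
        ``sex``, ``category``, ``subclass``); population offsets follow the
        demographic part of the subset.  ``counties_include`` restricts to
        a county subset (e.g. one disadvantage category, or all counties
        of the states kept in a leave-one-state-out refit).
        """
        config = config or ModelConfig()
        if start_year is None:
            if "year" not in exposure.columns:
                raise ValueError("pass start_year or an exposure panel with a year column")
            start_year = int(
                (exposure["year"] - exposure["month_index"] // 12).iloc[0]
            )

        mort = mortality.copy()
        if subset:
            for key, val in subset.items():
                if key not in mort.columns:
                    raise ValueError(f"subset key {key!r} not in mortality panel")
                mort = mort.loc[mort[key] == val]
        expo = exposure.copy()
        if counties_include is not None:
            keep = set(counties_include)
            mort = mort.loc[mort["county_id"].isin(keep)]
            expo = expo.loc[expo["county_id"].isin(keep)]
        if len(mort) == 0 or mort["deaths"].sum() == 0:
            raise RuntimeError("no outcome events in the requested subset")

        deaths = mort.groupby(["county_id", "month_index"], sort=True)["deaths"].sum()

        col = {
            "total": "exposure_days_total",
            "gale": "exposure_days_gale",
            "hurricane": "exposure_days_hurricane",
        }[config.exposure_class]
        lagged = build_lag_matrix(expo, L=config.lag, column=col)

        pop = annual_population.copy()
        demo_keys = [k for k in ("age_group", "sex") if subset and k in subset]
        for key in demo_keys:
            pop = pop.loc[pop[key] == subset[key]]
        pop = pop.groupby(["county_id", "year"], sort=True)["population"].sum().reset_index()
        monthly_pop = interpolate_population(pop, start_year=start_year)

        frame = lagged.merge(
            deaths.rename("deaths"), on=["county_id", "month_index"], how="left"
        )
        frame["deaths"] = frame["deaths"].fillna(0).astype(int)
        frame = frame.merge(monthly_pop, on=["county_id", "month_index"], how="inner")
        if temperature is not None and config.use_temperature:
            frame = frame.merge(
                temperature[["county_id", "month_index", "temp_c"]],
                on=["county_id", "month_index"],
                how="left",
            )
            if frame["temp_c"].isna().any():
                raise ValueError("temperature panel does not cover the study panel")
        return cls.from_frame(frame, config, start_year, adjacency)

    @classmethod
    def from_inputs(cls, inputs: PanelInputs, config: ModelConfig | None = None,
                    **kwargs) -> "CaseCrossoverModel":
        return cls.from_panels(
            inputs.mortality,
            inputs.exposure,
            inputs.annual_population,
            temperature=inputs.temperature,
            config=config,
            start_year=inputs.start_year,
            adjacency=inputs.adjacency,
            **kwargs,
        )

    # -- fitting -----------------------------------------------------------

    def _prior_precision(self, tau_rw2: float | None, tau_car: float | None) -> np.ndarray:
        d = self.design
        k = d.X.shape[1]
        P = np.zeros((k, k))
        if np.isfinite(self.config.beta_prior_sd):
            P[d.lag_cols, d.lag_cols] = 1.0 / self.config.beta_prior_sd**2
        if len(d.spline_cols) and np.isfinite(self.config.spline_prior_sd):
            P[d.spline_cols, d.spline_cols] = 1.0 / self.config.spline_prior_sd**2
        if len(d.temp_cols) and tau_rw2 is not None:
            ix = np.ix_(d.temp_cols, d.temp_cols)
            P[ix] = tau_rw2 * d.K_temp + 1e-8 * np.eye(len(d.temp_cols))
        if len(d.car_cols) and tau_car is not None:
            ix = np.ix_(d.car_cols, d.car_cols)
            P[ix] = tau_car * d.K_car
        return P

    def _check_fittable(self) -> None:
        d = self.design
        if d.y.sum() == 0:
            raise RuntimeError("no outcome events")
        if d.info["n_informative_strata"] == 0:
            raise RuntimeError("exposure not identifiable under conditioning")

    def fit(self, method: str | None = None) -> "CaseCrossoverResults":
        """Fit and return posterior summaries for the lag coefficients."""
        self._check_fittable()
        method = method or self.config.inference
        if self.config.overdispersion == "negative_binomial":
            return self._fit_dm(method)
        if method == "map_laplace":
            return self._fit_map()
        if method == "mcmc":
            return self._fit_mcmc()
        raise ValueError(f"unknown inference method {method!r}")

    def _hyper_spec(self):
        """(names, init log-values, (shape, rate)) of active precision hypers."""
        names, init, priors = [], [], []
        if self.config.overdispersion == "lognormal_olre":
            names.append("tau_olre")
            init.append(np.log(20.0))
            priors.append(self.config.olre_prior)
        if len(self.design.temp_cols):
            names.append("tau_rw2")
            init.append(np.log(50.0))
            priors.append(self.config.rw2_prior)
        if len(self.design.car_cols):
            names.append("tau_car")
            init.append(np.log(10.0))
            priors.append(self.config.car_prior)
        return names, np.array(init), priors

    def _taus_from_vec(self, names, vec):
        taus = dict(zip(names, np.exp(np.clip(vec, -10.0, 14.0))))
        return (
            taus.get("tau_olre"),
            taus.get("tau_rw2"),
            taus.get("tau_car"),
            taus,
        )

    def _fit_map(self) -> "CaseCrossoverResults":
        d = self.design
        names, init, priors = self._hyper_spec()
        warm: dict = {}

        def solve(vec, want_cov=False):
            tau_u, tau_rw2, tau_car, taus = self._taus_from_vec(names, vec)
            P = self._prior_precision(tau_rw2, tau_car)
            state = _fit.newton_joint(
                d.X, d.y, d.offset, d.groups, P,
                tau_u=tau_u,
                f0=warm.get("f"), u0=warm.get("u"),
                want_cov=True,
            )
            warm["f"], warm["u"] = state.f, state.u
            logdet_p = 0.0
            if tau_rw2 is not None:
                logdet_p += 0.5 * d.rank_temp * np.log(tau_rw2)
            if tau_car is not None:
                logdet_p += 0.5 * d.rank_car * np.log(tau_car)
            hyper_lp = sum(
                _fit.gamma_logprior(np.exp(v), a, b)
                for v, (a, b) in zip(vec, priors)
            )
            eb = _fit.eb_objective(state, logdet_p, tau_u, d.groups.n_obs, hyper_lp)
            return eb, state, taus

        if names:
            def neg_eb(vec):
                val, _, _ = solve(vec)
                return -val

            opt = _fit_nelder_mead(neg_eb, init)
            vec_hat = opt
        else:
            vec_hat = init
        _, state, taus = solve(vec_hat, want_cov=True)
        if not state.converged:
            warnings.warn("inner Newton did not fully converge; results flagged",
                          stacklevel=2)
        return self._results_from_gaussian(
            mean=state.f, cov=state.cov_f, method="map_laplace",
            converged=state.converged, loglik=state.loglik,
            hyper={**taus, "mode": self.config.overdispersion},
        )

    def _fit_dm(self, method: str) -> "CaseCrossoverResults":
        d = self.design
        # temperature precision fixed at a weakly informative value; the
        # DM dispersion is estimated jointly as log phi
        P = self._prior_precision(tau_rw2=50.0, tau_car=10.0)
        state = _fit.fit_dm_map(d.X, d.y, d.offset, d.groups, P)
        return self._results_from_gaussian(
            mean=state.f, cov=state.cov_f, method="map_laplace",
            converged=state.converged, loglik=state.loglik,
            hyper={"phi": state.extras["phi"], "mode": "negative_binomial"},
        )

    def _fit_mcmc(self) -> "CaseCrossoverResults":
        import emcee

        d = self.design
        cfg = self.config
        names, init, priors = self._hyper_spec()
        base = self._fit_map()  # initialization + fallback covariance
        k = d.X.shape[1]
        dim = k + len(names)
        use_olre = cfg.overdispersion == "lognormal_olre"
        warm_u: dict = {}

        def log_post(theta):
            f = theta[:k]
            vec = theta[k:]
            if np.any(np.abs(vec) > 14.0):
                return -np.inf
            tau_u, tau_rw2, tau_car, _ = self._taus_from_vec(names, vec)
            P = self._prior_precision(tau_rw2, tau_car)
            if use_olre:
                ll, u = _fit.marginal_loglik_olre(
                    d.X, d.y, d.offset, d.groups, f, tau_u, u0=warm_u.get("u")
                )
                warm_u["u"] = u
            else:
                ll = _fit.cond_loglik(d.X @ f + d.offset, d.y, d.groups)
            lp = ll - 0.5 * f @ P @ f
            if tau_rw2 is not None:
                lp += 0.5 * d.rank_temp * np.log(tau_rw2)
            if tau_car is not None:
                lp += 0.5 * d.rank_car * np.log(tau_car)
            lp += sum(
                _fit.gamma_logprior(np.exp(v), a, b)
                for v, (a, b) in zip(vec, priors)
            )
            return lp if np.isfinite(lp) else -np.inf

        rng = np.random.default_rng(cfg.seed)
        nwalkers = max(2 * dim + 2, 16)
        tau_init = [np.log(base.hyper.get(nm, np.exp(v))) for nm, v in zip(names, init)]
        center = np.concatenate([base._mean_full, tau_init])
        scatter = np.concatenate(
            [np.sqrt(np.maximum(np.diag(base._cov_full), 1e-8)), 0.3 * np.ones(len(names))]
        )
        p0 = center + 0.5 * scatter * rng.standard_normal((nwalkers, dim))
        sampler = emcee.EnsembleSampler(nwalkers, dim, log_post)
        nsteps = cfg.warmup + max(int(np.ceil(cfg.n_draws_total / nwalkers)), 20)
        sampler.run_mcmc(p0, nsteps, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=cfg.warmup, flat=True)
        beta_chain = chain[:, : cfg.lag + 1]
        ess = _fit.effective_sample_size(beta_chain)
        converged = bool(np.all(np.nan_to_num(ess, nan=0.0) > 50.0))
        if not converged:
            warnings.warn("MCMC effective sample size low; results flagged", stacklevel=2)
        take = min(cfg.n_draws_total, len(beta_chain))
        sel = rng.choice(len(beta_chain), size=take, replace=False)
        draws = beta_chain[sel]
        hyper = {"mode": cfg.overdispersion}
        for j, nm in enumerate(names):
            hyper[nm] = float(np.exp(chain[:, k + j]).mean())
        return self._make_results(
            draws=draws,
            beta_mean=beta_chain.mean(axis=0),
            method="mcmc",
            converged=converged,
            ess=ess,
            hyper=hyper,
            loglik=float(np.max(sampler.get_log_prob(discard=cfg.warmup, flat=True))),
            mean_full=chain[:, :k].mean(axis=0),
            cov_full=np.cov(chain[:, :k].T),
        )

    # -- results packaging -------------------------------------------------

    def _results_from_gaussian(self, mean, cov, method, converged, loglik, hyper):
        cfg = self.config
        L1 = cfg.lag + 1
        rng = np.random.default_rng(cfg.seed + 1)
        sub_mean = mean[:L1]
        sub_cov = cov[:L1, :L1]
        sub_cov = 0.5 * (sub_cov + sub_cov.T)
        draws = rng.multivariate_normal(sub_mean, sub_cov, size=cfg.n_draws_total,
                                        method="svd")
        res = self._make_results(
            draws=draws,
            beta_mean=sub_mean,
            method=method,
            converged=converged,
            ess=np.full(L1, float(cfg.n_draws_total)),
            hyper=hyper,
            loglik=loglik,
            mean_full=mean,
            cov_full=cov,
        )
        return res

    def _make_results(self, draws, beta_mean, method, converged, ess, hyper,
                      loglik, mean_full, cov_full):
        res = CaseCrossoverResults(
            model=self,
            config=self.config,
            method=method,
            beta_mean=np.asarray(beta_mean, dtype=float),
            draws=np.asarray(draws, dtype=float),
            ess=np.asarray(ess, dtype=float),
            converged=converged,
            hyper=dict(hyper),
            loglik=float(loglik),
            info=dict(self.design.info),
        )
        res._mean_full = np.asarray(mean_full, dtype=float)
        res._cov_full = np.asarray(cov_full, dtype=float)
        return res


def _fit_nelder_mead(fun, x0, maxiter=60):
    from scipy.optimize import minimize

    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 0.03, "fatol": 0.02})
    return res.x


class CaseCrossoverResults:
    """Posterior summaries for the distributed-lag coefficients.

    ``beta_mean``/``beta_ci`` are on the log-rate-ratio scale (per
    additional exposure day); ``draws`` is an ``(ndraws, L+1)`` array used
    by the post-processing transforms.  ``summary()`` renders the standard
    table; ``percent_change()`` and ``effect_summary()`` translate to the
    reported scales.
    """

    def __init__(self, model, config, method, beta_mean, draws, ess, converged,
                 hyper, loglik, info):
        self.model = model
        self.config = config
        self.method = method
        self.beta_mean = beta_mean
        self.draws = draws
        self.ess = ess
        self.converged = converged
        self.hyper = hyper
        self.loglik = loglik
        self.info = info

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.config.lag + 1)

    @property
    def beta_ci(self) -> np.ndarray:
        """Equal-tailed 95% credible intervals, (L+1, 2)."""
        return np.percentile(self.draws, [2.5, 97.5], axis=0).T

    @property
    def beta_sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def summary(self) -> pd.DataFrame:
        ci = self.beta_ci
        tab = pd.DataFrame(
            {
                "lag": self.lags,
                "mean": self.beta_mean,
                "sd": self.beta_sd,
                "lower95": ci[:, 0],
                "upper95": ci[:, 1],
                "ess": self.ess,
            }
        )
        return tab

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"<CaseCrossoverResults method={self.method} "
            f"strata={self.info['n_strata']} "
            f"informative={self.info['n_informative_strata']} "
            f"converged={self.converged}>"
        )
        return head + "\n" + self.summary().to_string(index=False)

    # post-processing hooks (implemented in windlag.effects)

    def percent_change(self):
        from .effects import percent_change

        return [percent_change(self.draws[:, l]) for l in self.lags]

    def effect_summary(self, baseline_dpm: float, group: str = "all",
                       strength: str | None = None) -> pd.DataFrame:
        from .effects import effect_summary

        return effect_summary(self, baseline_dpm, group=group,
                              strength=strength or self.config.exposure_class)

    def to_frame(self) -> pd.DataFrame:
        return self.summary()

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def plot_effects(self, ax=None, baseline_dpm: float | None = None):
        """Point estimates and 95% CrIs per lag, on the percent-change scale."""
        import matplotlib.pyplot as plt

        from .effects import percent_change

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        pts = [percent_change(self.draws[:, l]) for l in self.lags]
        means = [p[0] for p in pts]
        lo = [p[1] for p in pts]
        hi = [p[2] for p in pts]
        ax.errorbar(self.lags, means,
                    yerr=[np.subtract(means, lo), np.subtract(hi, means)],
                    fmt="o", capsize=3)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("months after exposure")
        ax.set_ylabel("% change per exposure day")
        ax.set_xticks(self.lags)
        return ax
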