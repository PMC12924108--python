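"""Numerics for the Bayesian conditional (quasi-)Poisson case-crossover fit.

Conditioning each county-month stratum on its total death count turns the
Poisson likelihood into a within-stratum multinomial whose cell log-odds
are the linear predictor (lags + splines + temperature walk + offset)
relative to the other members of the stratum.  Overdispersion enters as a
log-normal observation-level random effect (OLRE) on the linear predictor,
or alternatively as a Dirichlet-multinomial conditional (the exact
conditional of independent negative-binomial counts sharing a
within-stratum probability parameter).

Fitting machinery:

* ``map_laplace`` — damped Newton on the joint penalized log-likelihood
  over (fixed effects, OLRE), with the OLRE block eliminated stratum by
  stratum via Schur complements (strata are the only coupling between
  observations, so that block is block-diagonal).  Precision
  hyperparameters maximize the Laplace-approximate marginal posterior
  (empirical Bayes).  The Gaussian approximation at the mode supplies
  equal-tailed credible intervals.
* ``mcmc`` — an affine-invariant ensemble sampler (emcee) over the fixed
  effects and log-precisions, with the OLRE integrated out by a
  per-stratum Laplace approximation inside the likelihood.

Strata are batched by member count so every per-stratum operation is a
vectorized ``(S, m, m)`` einsum/solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import digamma, gammaln, logsumexp

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class StratumGroups:
    """Observation indices grouped by stratum, batched by stratum size."""

    idx: list[np.ndarray]  # each (S_g, m_g) of observation indices
    sizes: list[int]
    n_obs: int
    n_strata: int

    @classmethod
    def from_codes(cls, stratum: np.ndarray) -> "StratumGroups":
        order = np.argsort(stratum, kind="stable")
        codes, counts = np.unique(stratum, return_counts=True)
        groups: dict[int, list[np.ndarray]] = {}
        pos = 0
        for _, m in zip(codes, counts):
            members = order[pos : pos + m]
            groups.setdefault(int(m), []).append(members)
            pos += m
        idx = [np.vstack(v) for v in groups.values()]
        sizes = [int(k) for k in groups.keys()]
        return cls(idx=idx, sizes=sizes, n_obs=len(stratum), n_strata=len(codes))


def cond_loglik(eta: np.ndarray, y: np.ndarray, groups: StratumGroups) -> float:
    """Conditional multinomial log-likelihood (up to a data-only constant)."""
    ll = 0.0
    for idx in groups.idx:
        E = eta[idx]
        Y = y[idx]
        Yt = Y.sum(axis=1)
        ll += float((Y * E).sum() - Yt @ logsumexp(E, axis=1))
    return ll


def _grad_W(eta, y, groups):
    """Gradient wrt eta and per-group softmax pieces for Hessian products."""
    g = np.zeros_like(eta)
    pieces = []
    ll = 0.0
    for idx in groups.idx:
        E = eta[idx]
        Y = y[idx]
        Yt = Y.sum(axis=1)
        lse = logsumexp(E, axis=1)
        ll += float((Y * E).sum() - Yt @ lse)
        p = np.exp(E - lse[:, None])
        g[idx] = Y - Yt[:, None] * p
        pieces.append((idx, p, Yt))
    return ll, g, pieces


def _W_blocks(p, Yt):
    """(S, m, m) blocks Yt * (diag(p) - p p^T)."""
    m = p.shape[1]
    W = -Yt[:, None, None] * p[:, :, None] * p[:, None, :]
    W[:, np.arange(m), np.arange(m)] += Yt[:, None] * p
    return W


@dataclass
class FitState:
    f: np.ndarray
    u: np.ndarray
    converged: bool
    n_iter: int
    loglik: float  # conditional log-likelihood at the mode (no penalties)
    objective: float  # penalized objective at the mode
    cov_f: np.ndarray | None = None
    logdet_H: float | None = None
    extras: dict = field(default_factory=dict)


def newton_joint(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    groups: StratumGroups,
    P: np.ndarray,
    tau_u: float | None,
    f0: np.ndarray | None = None,
    u0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 60,
    want_cov: bool = False,
) -> FitState:
    """Damped Newton MAP over (fixed effects f, OLRE u).

    ``tau_u=None`` disables the OLRE (plain conditional Poisson).  ``P`` is
    the prior precision of the fixed effects.  The OLRE block of each
    Newton system is eliminated per stratum (Schur complement), so the
    linear solve is k x k regardless of the number of observations.
    """
    n, k = X.shape
    f = np.zeros(k) if f0 is None else f0.copy()
    u = np.zeros(n) if (u0 is None or tau_u is None) else u0.copy()
    use_u = tau_u is not None

    def objective(fv, uv):
        eta = X @ fv + offset + uv
        ll = cond_loglik(eta, y, groups)
        pen = 0.5 * fv @ P @ fv
        if use_u:
            pen += 0.5 * tau_u * uv @ uv
        return ll - pen, ll

    obj, ll = objective(f, u)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ f + offset + u
        _, g_eta, pieces = _grad_W(eta, y, groups)
        grad_f = X.T @ g_eta - P @ f
        A = P.copy()
        if use_u:
            grad_u = g_eta - tau_u * u
            rhs = grad_f.copy()
            for idx, p, Yt in pieces:
                W = _W_blocks(p, Yt)
                Xs = X[idx]  # (S, m, k)
                WX = np.einsum("sij,sjk->sik", W, Xs)
                A += np.einsum("sik,sij->kj", Xs, WX).T  # X^T W X accumulated
                m = p.shape[1]
                M = np.linalg.inv(W + tau_u * np.eye(m)[None])
                MWX = np.einsum("sij,sjk->sik", M, WX)
                A -= np.einsum("sik,sij->kj", WX, MWX).T
                gu = grad_u[idx]
                rhs -= np.einsum("sik,si->k", WX, np.einsum("sij,sj->si", M, gu))
        else:
            rhs = grad_f
            for idx, p, Yt in pieces:
                W = _W_blocks(p, Yt)
                Xs = X[idx]
                WX = np.einsum("sij,sjk->sik", W, Xs)
                A += np.einsum("sik,sij->kj", Xs, WX).T

        try:
            df = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            df = np.linalg.lstsq(A, rhs, rcond=None)[0]
        du = np.zeros(n)
        if use_u:
            for idx, p, Yt in pieces:
                W = _W_blocks(p, Yt)
                m = p.shape[1]
                M = np.linalg.inv(W + tau_u * np.eye(m)[None])
                resid = grad_u[idx] - np.einsum("sij,sjk,k->si", W, X[idx], df)
                du[idx] = np.einsum("sij,sj->si", M, resid)

        # backtracking line search
        step = 1.0
        for _ in range(30):
            f_new = f + step * df
            u_new = u + step * du if use_u else u
            obj_new, ll_new = objective(f_new, u_new)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            step *= 0.5
        improved = obj_new - obj
        f, u, obj, ll = f_new, u_new, obj_new, ll_new
        gnorm = np.max(np.abs(grad_f)) if not use_u else max(
            np.max(np.abs(grad_f)), np.max(np.abs(grad_u))
        )
        if gnorm < tol * (1.0 + abs(obj)) or (0 <= improved < 1e-12 and step == 1.0):
            converged = True
            break

    state = FitState(f=f, u=u, converged=converged, n_iter=it, loglik=ll, objective=obj)
    if want_cov:
        state.cov_f, state.logdet_H = _laplace_cov(X, y, offset, groups, P, tau_u, f, u)
    return state


def _laplace_cov(X, y, offset, groups, P, tau_u, f, u):
    """Marginal Gaussian covariance of f and log-determinant of the joint
    negative Hessian at the mode (Schur-complement identities)."""
    eta = X @ f + offset + u
    _, _, pieces = _grad_W(eta, y, groups)
    k = X.shape[1]
    A = P.copy()
    logdet_uu = 0.0
    for idx, p, Yt in pieces:
        W = _W_blocks(p, Yt)
        Xs = X[idx]
        WX = np.einsum("sij,sjk->sik", W, Xs)
        A += np.einsum("sik,sij->kj", Xs, WX).T
        if tau_u is not None:
            m = p.shape[1]
            D = W + tau_u * np.eye(m)[None]
            sign, ld = np.linalg.slogdet(D)
            logdet_uu += float(ld.sum())
            M = np.linalg.inv(D)
            MWX = np.einsum("sij,sjk->sik", M, WX)
            A -= np.einsum("sik,sij->kj", WX, MWX).T
    A = 0.5 * (A + A.T)
    # guard against flat directions under flat priors
    jitter = 1e-10 * (1.0 + np.trace(A) / k)
    sign, logdet_A = np.linalg.slogdet(A + jitter * np.eye(k))
    cov = np.linalg.inv(A + jitter * np.eye(k))
    return cov, logdet_uu + float(logdet_A)


def eb_objective(state: FitState, P_taudep_logdet: float, tau_u: float | None,
                 n_obs: int, hyper_logprior: float) -> float:
    """Laplace-approximate log marginal posterior of the hyperparameters.

    ``P_taudep_logdet`` carries the tau-dependent part of the fixed-effect
    prior normalizer (0.5 * rank * log tau per structured block).
    """
    val = state.objective + P_taudep_logdet - 0.5 * state.logdet_H + hyper_logprior
    if tau_u is not None:
        val += 0.5 * n_obs * np.log(tau_u)
    return val


# ---------------------------------------------------------------------------
# Laplace-integrated marginal likelihood over the OLRE (used by MCMC)

def marginal_loglik_olre(
    X, y, offset, groups: StratumGroups, f: np.ndarray, tau_u: float,
    u0: np.ndarray | None = None, max_iter: int = 40, tol: float = 1e-9,
):
    """log integral over u of the stratum likelihood times the OLRE prior.

    Inner per-stratum Newton maximization (batched within size groups)
    followed by a Laplace correction.  Returns (value, u_hat).
    """
    eta0 = X @ f + offset
    n = len(y)
    u = np.zeros(n) if u0 is None else u0.copy()
    for _ in range(max_iter):
        eta = eta0 + u
        _, g_eta, pieces = _grad_W(eta, y, groups)
        grad_u = g_eta - tau_u * u
        du = np.zeros(n)
        for idx, p, Yt in pieces:
            W = _W_blocks(p, Yt)
            m = p.shape[1]
            M = np.linalg.inv(W + tau_u * np.eye(m)[None])
            du[idx] = np.einsum("sij,sj->si", M, grad_u[idx])
        # damped update with halving if objective decreases
        obj_old = cond_loglik(eta0 + u, y, groups) - 0.5 * tau_u * u @ u
        step = 1.0
        for _ in range(20):
            u_new = u + step * du
            obj_new = cond_loglik(eta0 + u_new, y, groups) - 0.5 * tau_u * u_new @ u_new
            if np.isfinite(obj_new) and obj_new >= obj_old - 1e-12:
                break
            step *= 0.5
        u = u_new
        if np.max(np.abs(grad_u)) < tol * (1.0 + abs(obj_new)):
            break
    eta = eta0 + u
    ll, _, pieces = _grad_W(eta, y, groups)
    val = ll - 0.5 * tau_u * u @ u + 0.5 * n * np.log(tau_u)
    for idx, p, Yt in pieces:
        W = _W_blocks(p, Yt)
        m = p.shape[1]
        _, ld = np.linalg.slogdet(W + tau_u * np.eye(m)[None])
        val -= 0.5 * float(ld.sum())
    return val, u


# ---------------------------------------------------------------------------
# Dirichlet-multinomial conditional (negative-binomial overdispersion mode)

def dm_loglik_grad(eta, y, groups: StratumGroups, phi: float):
    """Dirichlet-multinomial conditional log-likelihood and gradients.

    Concentrations alpha_j = exp(eta_j) / phi; as phi -> 0 this approaches
    the plain multinomial conditional.  Returns (ll, grad_eta, grad_logphi).
    """
    ll = 0.0
    g = np.zeros_like(eta)
    g_logphi = 0.0
    for idx in groups.idx:
        E = eta[idx]
        Y = y[idx]
        alpha = np.exp(E) / phi
        A = alpha.sum(axis=1)
        Yt = Y.sum(axis=1)
        ll += float(
            (gammaln(A) - gammaln(A + Yt)).sum()
            + (gammaln(alpha + Y) - gammaln(alpha)).sum()
        )
        core = alpha * (
            digamma(alpha + Y) - digamma(alpha) + (digamma(A) - digamma(A + Yt))[:, None]
        )
        g[idx] = core
        g_logphi -= float(core.sum())
    return ll, g, g_logphi


def fit_dm_map(X, y, offset, groups, P, logphi_prior_sd=1.5, x0=None):
    """MAP fit of the Dirichlet-multinomial conditional via L-BFGS.

    Parameters are (f, log phi); the Gaussian covariance comes from a
    finite-difference Hessian of the analytic gradient.
    """
    n, k = X.shape

    def negpost(theta):
        f, logphi = theta[:k], theta[k]
        phi = np.exp(np.clip(logphi, -12.0, 8.0))
        eta = X @ f + offset
        ll, g_eta, g_logphi = dm_loglik_grad(eta, y, groups, phi)
        lp = ll - 0.5 * f @ P @ f - 0.5 * (logphi / logphi_prior_sd) ** 2
        grad = np.empty(k + 1)
        grad[:k] = X.T @ g_eta - P @ f
        grad[k] = g_logphi - logphi / logphi_prior_sd**2
        return -lp, -grad

    theta0 = np.zeros(k + 1) if x0 is None else x0
    if x0 is None:
        theta0[k] = np.log(0.05)
    res = optimize.minimize(negpost, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    theta = res.x
    # finite-difference Hessian of the gradient
    h = 1e-5
    H = np.zeros((k + 1, k + 1))
    for j in range(k + 1):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (negpost(tp)[1] - negpost(tm)[1]) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H + 1e-10 * np.eye(k + 1))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    f = theta[:k]
    eta = X @ f + offset
    ll, _, _ = dm_loglik_grad(eta, y, groups, np.exp(theta[k]))
    state = FitState(
        f=f, u=np.zeros(n), converged=bool(res.success), n_iter=int(res.nit),
        loglik=ll, objective=-res.fun, cov_f=cov[:k, :k],
        extras={"phi": float(np.exp(theta[k])), "logphi_cov": float(cov[k, k])},
    )
    return state


def gamma_logprior(tau: float, shape: float, rate: float) -> float:
    """Gamma log-prior on a precision, including the log-tau Jacobian for
    sampling/optimizing on the log scale."""
    return shape * np.log(tau) - rate * tau


def effective_sample_size(chain: np.ndarray) -> np.ndarray:
    """Crude ESS per column from the integrated autocorrelation time."""
    import emcee

    n, d = chain.shape
    out = np.empty(d)
    for j in range(d):
        try:
            tau = emcee.autocorr.integrated_time(chain[:, j], quiet=True)[0]
            out[j] = n / max(tau, 1.0)
        except Exception:  # pragma: no cover - emcee raises on tiny chains
            out[j] = np.nan
    return out
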