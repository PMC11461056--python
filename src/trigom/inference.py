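"""Posterior sampling and MCMC post-processing for the joint model.

Conditional on the structural parameters the model is a linear-Gaussian
state-space system: substituting the current-year cod term into the capelin
and polar-cod equations gives a VAR(1) transition ``x_t = d_t + B x_{t-1} +
M eps_t`` with ``M`` unit lower-triangular, plus independent normal
observations.  The latent log abundances are therefore integrated out
exactly with a Kalman filter, and the ~31 structural parameters are sampled
with an affine-invariant ensemble sampler (emcee).  Latent states -- and
hence the per-year process errors the hindcast reuses -- are then drawn
exactly per retained parameter draw by forward-filter backward-sampling, so
retained draws are exact joint-posterior samples of (parameters, states).

"Chains" are independent ensembles; each retained (thinned) iteration of a
chain contributes one walker in round-robin order, which keeps the
retained-draw count at the conventional
``n_chains * (n_iter - n_burnin) / thin``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    COEF_NAMES,
    ModelParams,
    PreparedData,
    PriorConfig,
    initial_state_mean,
    prepare_data,
)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "PARAM_NAMES",
    "sample_posterior",
    "split_rhat",
    "rhat_table",
    "posterior_predictive",
    "bayesian_r2",
    "report_table",
    "sample_ratio_prior",
    "ratio_prior_sensitivity",
]

# natural-scale parameter names, in the layout of the sampled vector
PARAM_NAMES = COEF_NAMES + (
    "sigma_proc_cod", "sigma_proc_cap", "sigma_proc_pcod",
    "rho_cod_cap", "rho_cod_pcod", "rho_cap_pcod",
    "r_obs_cod", "r_obs_cap", "r_obs_pcod",
    "sigma_pcod_1995",
)
N_PARAMS = len(PARAM_NAMES)  # 31
_I_LSIG = slice(21, 24)   # log process-error SDs (sampled on log scale)
_I_RHO = slice(24, 27)
_I_ROBS = slice(27, 30)
_I_LANOM = 30             # log anomalous-year extra SD


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    ``n_iter`` counts ensemble iterations per chain, of which the first
    ``n_burnin`` are discarded and the rest thinned by ``thin``.  Retained
    draws number exactly ``n_chains * (n_iter - n_burnin) / thin``.
    ``n_walkers`` is the ensemble size per chain.  A fit is flagged
    non-convergent when the maximum split R-hat exceeds ``rhat_flag`` or
    mean acceptance falls below ``min_acceptance``.
    """

    n_chains: int = 4
    n_iter: int = 30_000
    n_burnin: int = 20_000
    thin: int = 10
    n_walkers: int = 64
    seed: int = 0
    rhat_flag: float = 1.05
    min_acceptance: float = 0.05

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.n_burnin) % self.thin != 0:
            raise ValueError("(n_iter - n_burnin) must be divisible by thin")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_walkers < 2 * N_PARAMS:
            raise ValueError(f"n_walkers must be >= {2 * N_PARAMS}")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_retained_per_chain


# scaled-down settings for tests and quick exploration
TEST_SAMPLER = SamplerConfig(n_chains=4, n_iter=3000, n_burnin=1500, thin=5)


# --------------------------------------------------------------------------
# parameter-vector packing
# --------------------------------------------------------------------------

def params_to_vector(p: ModelParams) -> np.ndarray:
    """Pack a ModelParams into the sampled (partially log) vector."""
    v = np.empty(N_PARAMS)
    v[:21] = p.coef_vector()
    v[_I_LSIG] = np.log(p.sigma_proc)
    v[_I_RHO] = (p.R_proc[0, 1], p.R_proc[0, 2], p.R_proc[1, 2])
    v[_I_ROBS] = p.r_obs
    v[_I_LANOM] = np.log(max(p.sigma_pcod_1995, 1e-8))
    return v


def vector_to_params(v: np.ndarray) -> ModelParams:
    """Unpack a sampled vector back into a ModelParams."""
    kw = {n: float(v[i]) for i, n in enumerate(COEF_NAMES)}
    r12, r13, r23 = v[_I_RHO]
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    return ModelParams(sigma_proc=np.exp(v[_I_LSIG]), R_proc=R,
                       r_obs=np.array(v[_I_ROBS]),
                       sigma_pcod_1995=float(np.exp(v[_I_LANOM])), **kw)


def natural_scale(theta: np.ndarray) -> np.ndarray:
    """Map sampled vectors (n, 31) to natural-scale values (SDs exponentiated)."""
    nat = np.array(theta, dtype=float, copy=True)
    nat[..., _I_LSIG] = np.exp(nat[..., _I_LSIG])
    nat[..., _I_LANOM] = np.exp(nat[..., _I_LANOM])
    return nat


# --------------------------------------------------------------------------
# batched structural matrices and Kalman filter
# --------------------------------------------------------------------------

def _structure(theta: np.ndarray):
    """Per-walker transition structure from sampled vectors (n, 31).

    Returns (B, Q, M, A_lag, sigma2_proc, valid); invalid rows (non-PD
    correlation) carry identity placeholders and valid=False.
    """
    n = theta.shape[0]
    r12, r13, r23 = theta[:, 24], theta[:, 25], theta[:, 26]
    detR = (1.0 + 2.0 * r12 * r13 * r23 - r12 ** 2 - r13 ** 2 - r23 ** 2)
    valid = ((np.abs(theta[:, _I_RHO]) < 1.0).all(axis=1) & (detR > 1e-10)
             & (theta[:, _I_ROBS] > 0).all(axis=1)
             & (np.abs(theta[:, _I_LSIG]) < 12).all(axis=1)
             & (theta[:, _I_LANOM] < 12))
    r12 = np.where(valid, r12, 0.0)
    r13 = np.where(valid, r13, 0.0)
    r23 = np.where(valid, r23, 0.0)
    sig = np.exp(np.clip(theta[:, _I_LSIG], -12, 12))
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = R[:, 1, 1] = R[:, 2, 2] = 1.0
    R[:, 0, 1] = R[:, 1, 0] = r12
    R[:, 0, 2] = R[:, 2, 0] = r13
    R[:, 1, 2] = R[:, 2, 1] = r23
    Sigma = sig[:, :, None] * R * sig[:, None, :]

    A = np.zeros((n, 3, 3))
    A[:, 0, 0], A[:, 0, 1], A[:, 0, 2] = theta[:, 1], theta[:, 2], theta[:, 3]
    A[:, 1, 1], A[:, 1, 2] = theta[:, 8], theta[:, 9]
    A[:, 2, 1], A[:, 2, 2] = theta[:, 16], theta[:, 15]
    M = np.zeros((n, 3, 3))
    M[:, 0, 0] = M[:, 1, 1] = M[:, 2, 2] = 1.0
    M[:, 1, 0] = theta[:, 10]   # a_cap_cod
    M[:, 2, 0] = theta[:, 17]   # a_pcod_cod
    B = M @ A
    Q = M @ Sigma @ M.transpose(0, 2, 1)
    return B, Q, M, A, sig ** 2, valid


def _covariate_intercepts(theta: np.ndarray, data: PreparedData) -> np.ndarray:
    """Per-equation covariate terms c (n, T-1, 3) before the contemporaneous
    substitution (transition into years[1:])."""
    X_cod, X_cap, X_pcod = data.covariate_rows()
    c1 = theta[:, (0, 4, 5, 6)] @ X_cod.T
    c2 = theta[:, (7, 11, 12, 13)] @ X_cap.T
    c3 = theta[:, (14, 18, 19, 20)] @ X_pcod.T
    return np.stack([c1, c2, c3], axis=2)  # (n, T-1, 3)


def _obs_variances(theta: np.ndarray, data: PreparedData) -> np.ndarray:
    """Observation variances (n, T, 3) including the anomalous-year term."""
    n, T = theta.shape[0], data.n_years
    sig2 = np.exp(np.clip(2 * theta[:, _I_LSIG], -24, 24))
    base = theta[:, _I_ROBS] * sig2   # (n, 3)
    out = np.broadcast_to(base[:, None, :], (n, T, 3)).copy()
    if data.anomaly_index >= 0:
        out[:, data.anomaly_index, 2] += np.exp(
            np.clip(2 * theta[:, _I_LANOM], -24, 24))
    return out


# Optional compiled fast path for the filtering loop (same arithmetic as
# the numpy loop below; the numpy path remains the reference and is always
# used when smoother moments are stored).
try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _kalman_core_fast(y, obs_mask, B, Q, d, Rv, m0, P0):  # pragma: no cover
        n = B.shape[0]
        T = y.shape[0]
        log2pi = np.log(2 * np.pi)
        ll = np.zeros(n)
        for w in range(n):
            m = m0[w].copy()
            P = P0[w].copy()
            ok = True
            for j in range(T):
                for i in range(3):
                    if not obs_mask[j, i]:
                        continue
                    S = P[i, i] + Rv[w, j, i]
                    if S <= 0 or not np.isfinite(S):
                        ok = False
                        break
                    innov = y[j, i] - m[i]
                    ll[w] += -0.5 * (log2pi + np.log(S) + innov * innov / S)
                    K0, K1, K2 = P[0, i] / S, P[1, i] / S, P[2, i] / S
                    m[0] += K0 * innov
                    m[1] += K1 * innov
                    m[2] += K2 * innov
                    Pi0, Pi1, Pi2 = P[i, 0], P[i, 1], P[i, 2]
                    P[0, 0] -= K0 * Pi0
                    P[0, 1] -= K0 * Pi1
                    P[0, 2] -= K0 * Pi2
                    P[1, 0] -= K1 * Pi0
                    P[1, 1] -= K1 * Pi1
                    P[1, 2] -= K1 * Pi2
                    P[2, 0] -= K2 * Pi0
                    P[2, 1] -= K2 * Pi1
                    P[2, 2] -= K2 * Pi2
                    for a in range(3):
                        for b in range(a + 1, 3):
                            s = 0.5 * (P[a, b] + P[b, a])
                            P[a, b] = s
                            P[b, a] = s
                if not ok:
                    break
                if j < T - 1:
                    Bw = B[w]
                    mn = np.empty(3)
                    for a in range(3):
                        mn[a] = (d[w, j, a] + Bw[a, 0] * m[0]
                                 + Bw[a, 1] * m[1] + Bw[a, 2] * m[2])
                    BP = Bw @ P
                    P = BP @ Bw.T + Q[w]
                    m = mn
            if not ok:
                ll[w] = -np.inf
        return ll
except ImportError:  # pragma: no cover
    _kalman_core_fast = None


def kalman_loglik(theta: np.ndarray, data: PreparedData,
                  priors: PriorConfig, store: bool = False):
    """Marginal log likelihood of the data given parameters (latent states
    integrated out), batched over rows of ``theta``.

    With ``store=True`` also returns the filtered and one-step-predicted
    moments needed by the backward sampler.
    """
    theta = np.atleast_2d(theta)
    n, T = theta.shape[0], data.n_years
    B, Q, M, A, sig2p, valid = _structure(theta)
    c = _covariate_intercepts(theta, data)
    d = np.einsum("nij,ntj->nti", M, c)          # (n, T-1, 3)
    Rv = _obs_variances(theta, data)
    obs_mask = ~np.isnan(data.y)

    m = np.broadcast_to(initial_state_mean(data), (n, 3)).copy()
    P = np.broadcast_to(priors.init_state_sd ** 2 * np.eye(3), (n, 3, 3)).copy()
    ll = np.zeros(n)
    if store:
        m_f = np.empty((n, T, 3))
        P_f = np.empty((n, T, 3, 3))
        m_p = np.empty((n, T - 1, 3))
        P_p = np.empty((n, T - 1, 3, 3))

    if not store and _kalman_core_fast is not None:
        ll = _kalman_core_fast(np.ascontiguousarray(data.y),
                               obs_mask, B, Q, d, Rv, m, P)
        return np.where(valid & np.isfinite(ll), ll, -np.inf)

    log2pi = np.log(2 * np.pi)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        for j in range(T):
            for i in range(3):
                if not obs_mask[j, i]:
                    continue
                S = P[:, i, i] + Rv[:, j, i]
                innov = data.y[j, i] - m[:, i]
                ll += -0.5 * (log2pi + np.log(S) + innov ** 2 / S)
                K = P[:, :, i] / S[:, None]
                m = m + K * innov[:, None]
                P = P - K[:, :, None] * P[:, i, None, :]
                P = 0.5 * (P + P.transpose(0, 2, 1))
            if store:
                m_f[:, j] = m
                P_f[:, j] = P
            if j < T - 1:
                m = d[:, j] + np.einsum("nij,nj->ni", B, m)
                P = B @ P @ B.transpose(0, 2, 1) + Q
                if store:
                    m_p[:, j] = m
                    P_p[:, j] = P

    ll = np.where(valid & np.isfinite(ll), ll, -np.inf)
    if store:
        return ll, (m_f, P_f, m_p, P_p, B, d, Q, valid)
    return ll


def log_posterior(theta: np.ndarray, data: PreparedData,
                  priors: PriorConfig) -> np.ndarray:
    """Batched log posterior (marginal likelihood + priors + Jacobians)."""
    theta = np.atleast_2d(theta)
    ll = kalman_loglik(theta, data, priors)
    lp = np.zeros(theta.shape[0])
    lp += -0.5 * np.sum(theta[:, :21] ** 2, axis=1) / priors.coef_sd ** 2
    lsig = np.clip(theta[:, _I_LSIG], -12, 12)
    # half-normal on sigma with the log-scale Jacobian
    lp += np.sum(-0.5 * np.exp(2 * lsig) / priors.sigma_proc_scale ** 2
                 + lsig, axis=1)
    lp += -0.5 * np.sum((theta[:, _I_ROBS] - priors.ratio_mean) ** 2,
                        axis=1) / priors.ratio_sd ** 2
    lanom = np.clip(theta[:, _I_LANOM], -12, 12)
    lp += -0.5 * np.exp(2 * lanom) / priors.sigma_anom_scale ** 2 + lanom
    return ll + lp


# --------------------------------------------------------------------------
# FFBS: exact draws of the latent states per parameter draw
# --------------------------------------------------------------------------

def sample_states(theta: np.ndarray, data: PreparedData, priors: PriorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw latent log-abundance trajectories, one per parameter vector,
    from the exact conditional posterior (simulation smoother)."""
    theta = np.atleast_2d(theta)
    n, T = theta.shape[0], data.n_years
    ll, (m_f, P_f, m_p, P_p, B, d, Q, valid) = kalman_loglik(
        theta, data, priors, store=True)
    if not np.all(np.isfinite(ll)):
        raise ValueError("cannot sample states for invalid parameter vectors")
    x = np.empty((n, T, 3))
    jit = 1e-10 * np.eye(3)
    L = np.linalg.cholesky(P_f[:, T - 1] + jit)
    x[:, T - 1] = m_f[:, T - 1] + np.einsum(
        "nij,nj->ni", L, rng.standard_normal((n, 3)))
    for j in range(T - 2, -1, -1):
        # G = P_f B' P_p^{-1}, computed via a batched solve
        BP = B @ P_f[:, j]                           # (n,3,3) = B P_f
        G = np.linalg.solve(P_p[:, j] + jit, BP).transpose(0, 2, 1)
        mean = m_f[:, j] + np.einsum("nij,nj->ni", G,
                                     x[:, j + 1] - m_p[:, j])
        cov = P_f[:, j] - G @ P_p[:, j] @ G.transpose(0, 2, 1)
        cov = 0.5 * (cov + cov.transpose(0, 2, 1)) + jit
        L = np.linalg.cholesky(cov)
        x[:, j] = mean + np.einsum("nij,nj->ni", L,
                                   rng.standard_normal((n, 3)))
    return x


def conditional_means_batch(theta: np.ndarray, x: np.ndarray,
                            data: PreparedData) -> np.ndarray:
    """Per-equation deterministic predictions for years[1:], batched.

    Row i of the output is the Gompertz-map expectation each process error
    eps_i is measured against (capelin and polar cod conditioned on the
    realized current-year cod state).
    """
    theta = np.atleast_2d(theta)
    c = _covariate_intercepts(theta, data)       # (n, T-1, 3)
    _, _, M, A, _, _ = _structure(theta)
    mu = c + np.einsum("nij,ntj->nti", A, x[:, :-1])
    mu[:, :, 1] += theta[:, 10, None] * x[:, 1:, 0]
    mu[:, :, 2] += theta[:, 17, None] * x[:, 1:, 0]
    return mu


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorDraws:
    """Retained posterior draws of parameters, latent states and process errors.

    ``params`` is (n_draws, 31) on the natural scale in ``PARAM_NAMES``
    order; ``theta`` the same draws on the sampled (log-SD) scale;
    ``states`` (n_draws, T, 3) latent log abundances; ``eps`` (n_draws,
    T-1, 3) the process errors implied by each draw's states (exact
    reconstruction identity).  ``chain``/``iteration`` label provenance.
    """

    param_names: tuple
    params: np.ndarray
    theta: np.ndarray
    chain: np.ndarray
    iteration: np.ndarray
    states: np.ndarray
    eps: np.ndarray
    years: np.ndarray
    diagnostics: dict
    config: SamplerConfig

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    def params_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(self.param_names))
        df.insert(0, "iteration", self.iteration)
        df.insert(0, "chain", self.chain)
        return df

    def tidy_frame(self) -> pd.DataFrame:
        """One row per draw x parameter (chain, iter, name, value), with the
        per-year process errors appended as eps_<species>_<year> entries."""
        species = ("cod", "cap", "pcod")
        recs = [self.params_frame().melt(
            id_vars=["chain", "iteration"], var_name="name")]
        for si, sp in enumerate(species):
            for yi, yr in enumerate(self.years[1:]):
                recs.append(pd.DataFrame({
                    "chain": self.chain, "iteration": self.iteration,
                    "name": f"eps_{sp}_{yr}", "value": self.eps[:, yi, si]}))
        return pd.concat(recs, ignore_index=True)

    def param_set(self, i: int) -> ModelParams:
        return vector_to_params(self.theta[i])

    def by_chain(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-draw vector to (n_chains, n_per_chain) draw order."""
        chains = np.unique(self.chain)
        return np.stack([values[self.chain == c] for c in chains])


# --------------------------------------------------------------------------
# split R-hat
# --------------------------------------------------------------------------

def split_rhat(chains, rank_normalized: bool = False) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws); each chain is split in half and the
    classic between/within variance ratio is computed over the 2m
    half-chains.  ``rank_normalized=True`` applies the rank-normal
    transform first.  Zero within-chain variance returns ``inf`` (reported
    as non-convergent rather than raising).
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim == 1:
        c = c[None, :]
    m, n = c.shape
    if m < 1 or n < 4:
        raise ValueError("need at least one chain with >= 4 draws")
    half = n // 2
    halves = np.concatenate([c[:, :half], c[:, n - half:]], axis=0)
    if rank_normalized:
        flat = halves.ravel()
        ranks = stats.rankdata(flat)
        z = stats.norm.ppf((ranks - 0.375) / (flat.size + 0.25))
        halves = z.reshape(halves.shape)
    W = np.mean(np.var(halves, axis=1, ddof=1))
    if W == 0 or not np.isfinite(W):
        return np.inf
    B_over_n = np.var(np.mean(halves, axis=1), ddof=1)
    # conservative pooled-variance form W + B/n: never below 1, exactly 1
    # when the half-chains share mean and variance
    return float(np.sqrt((W + B_over_n) / W))


def rhat_table(draws: PosteriorDraws, rank_normalized: bool = False
               ) -> pd.Series:
    """Split R-hat per sampled parameter (on the sampled scale)."""
    out = {}
    for k, name in enumerate(draws.param_names):
        out[name] = split_rhat(draws.by_chain(draws.theta[:, k]),
                               rank_normalized=rank_normalized)
    return pd.Series(out)


class _EnsembleRhat:
    """Split R-hat per parameter using *all* walker samples of each chain.

    Each independent ensemble is one chain; its post-burn-in samples are
    split into first/second halves along the iteration axis and pooled
    across walkers.  This is the full-information version of the retained-
    draw diagnostic: same W + B/n formula over the 2m half-chains, but each
    half-chain mean/variance is estimated from every walker sample rather
    than a 1-per-iteration subsample, which removes the subsampling noise
    floor from the estimate.  Accumulates per chain so full chains never
    need to be held simultaneously.
    """

    def __init__(self):
        self.means = []
        self.vars = []

    def add_chain(self, samples: np.ndarray):
        """samples: (n_steps, n_walkers, n_params) post-burn-in."""
        mid = samples.shape[0] // 2
        for half in (samples[:mid], samples[samples.shape[0] - mid:]):
            flat = half.reshape(-1, half.shape[-1])
            self.means.append(flat.mean(axis=0))
            self.vars.append(flat.var(axis=0, ddof=1))

    def result(self, names) -> pd.Series:
        W = np.mean(self.vars, axis=0)
        B_over_n = np.var(self.means, axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rh = np.sqrt((W + B_over_n) / W)
        rh = np.where(W > 0, rh, np.inf)
        return pd.Series(rh, index=list(names))


# --------------------------------------------------------------------------
# sampling driver
# --------------------------------------------------------------------------

def conditional_ls_guess(data: PreparedData, priors: PriorConfig) -> np.ndarray:
    """Cheap starting point: per-equation least squares on the observed log
    abundances (observation error ignored), residual SDs and correlations."""
    y, T = data.y, data.n_years
    X_cod, X_cap, X_pcod = data.covariate_rows()
    designs = (
        np.column_stack([X_cod[:, 0], y[:-1, 0], y[:-1, 1], y[:-1, 2],
                         X_cod[:, 1:]]),
        np.column_stack([X_cap[:, 0], y[:-1, 1], y[:-1, 2], y[1:, 0],
                         X_cap[:, 1:]]),
        np.column_stack([X_pcod[:, 0], y[:-1, 2], y[:-1, 1], y[1:, 0],
                         X_pcod[:, 1:]]),
    )
    v = np.zeros(N_PARAMS)
    resid = np.full((T - 1, 3), np.nan)
    for i, (X, target) in enumerate(zip(designs, (y[1:, 0], y[1:, 1],
                                                  y[1:, 2]))):
        rows = np.all(np.isfinite(X), axis=1) & np.isfinite(target)
        beta = np.zeros(7)
        if rows.sum() >= 8:
            beta, *_ = np.linalg.lstsq(X[rows], target[rows], rcond=None)
            resid[rows, i] = target[rows] - X[rows] @ beta
        v[7 * i: 7 * i + 7] = beta
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(resid, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd) & (sd > 1e-3), sd, 0.3)
    v[_I_LSIG] = np.log(sd)
    ok = np.all(np.isfinite(resid), axis=1)
    if ok.sum() >= 8:
        C = np.corrcoef(resid[ok].T)
        v[_I_RHO] = np.clip([C[0, 1], C[0, 2], C[1, 2]], -0.6, 0.6)
    v[_I_ROBS] = priors.ratio_mean
    v[_I_LANOM] = np.log(0.2)
    return v


def _init_walkers(guess: np.ndarray, n_walkers: int, logpost, rng) -> np.ndarray:
    def propose(k):
        q = guess[None, :] + 0.05 * rng.standard_normal((k, N_PARAMS))
        q[:, _I_ROBS] = np.abs(q[:, _I_ROBS]) + 0.05
        return q

    p0 = propose(n_walkers)
    bad = ~np.isfinite(logpost(p0))
    tries = 0
    while bad.any() and tries < 100:
        p0[bad] = propose(int(bad.sum()))
        bad = ~np.isfinite(logpost(p0))
        tries += 1
    if bad.any():
        raise RuntimeError("could not initialize walkers at finite density")
    return p0


def sample_posterior(data, priors: PriorConfig | None = None,
                     config: SamplerConfig | None = None) -> PosteriorDraws:
    """Sample the joint posterior of parameters, latent states and process
    errors.

    ``data`` is a PreparedData (or an ``(AbundanceTable, ClimateSeries)``
    pair).  Runs ``n_chains`` independent ensembles, retains thinned
    post-burn-in iterations (one walker per retained iteration, round-robin),
    then draws latent states exactly per retained draw and reconstructs the
    process errors.  Fully reproducible under ``config.seed``.
    """
    import emcee

    if isinstance(data, tuple):
        data = prepare_data(*data)
    priors = priors or PriorConfig()
    config = config or SamplerConfig()
    if data.n_years < 4:
        raise ValueError("need at least 4 years of data")

    def logpost(th):
        return log_posterior(th, data, priors)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.generate_state(config.n_chains + 1, dtype=np.uint32)
    guess = conditional_ls_guess(data, priors)

    all_theta, all_chain, all_iter, acc = [], [], [], []
    ens_rhat = _EnsembleRhat()
    for ci in range(config.n_chains):
        rs = np.random.RandomState(int(chain_seeds[ci]) % (2 ** 31))
        rng = np.random.default_rng(int(chain_seeds[ci]))
        moves = [(emcee.moves.DEMove(), 0.8),
                 (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(config.n_walkers, N_PARAMS, logpost,
                                        vectorize=True, moves=moves)
        sampler.random_state = rs.get_state()
        p0 = _init_walkers(guess, config.n_walkers, logpost, rng)
        sampler.run_mcmc(p0, config.n_iter, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain()           # (n_iter, n_walkers, P)
        steps = np.arange(config.n_burnin + config.thin - 1, config.n_iter,
                          config.thin)
        walkers = (np.arange(steps.size) + ci) % config.n_walkers
        all_theta.append(chain[steps, walkers, :])
        all_chain.append(np.full(steps.size, ci))
        all_iter.append(steps + 1)
        acc.append(float(np.mean(sampler.acceptance_fraction)))
        ens_rhat.add_chain(chain[config.n_burnin:])
        del chain, sampler

    theta = np.concatenate(all_theta)
    chain_id = np.concatenate(all_chain)
    iteration = np.concatenate(all_iter)

    state_rng = np.random.default_rng(int(chain_seeds[-1]))
    states = sample_states(theta, data, priors, state_rng)
    mu = conditional_means_batch(theta, states, data)
    eps = states[:, 1:] - mu

    draws = PosteriorDraws(
        param_names=PARAM_NAMES, params=natural_scale(theta), theta=theta,
        chain=chain_id, iteration=iteration, states=states, eps=eps,
        years=data.years.copy(), diagnostics={}, config=config)

    diag = {"acceptance_fraction": acc, "n_retained": draws.n_draws,
            "divergences": 0}
    if config.n_chains >= 2 and draws.n_draws // config.n_chains >= 4:
        rh = ens_rhat.result(PARAM_NAMES)
        diag["rhat"] = {k: float(val) for k, val in rh.items()}
        diag["max_rhat"] = float(rh.max())
        flags = []
        if rh.max() > config.rhat_flag:
            flags.append(f"max split R-hat {rh.max():.4f} exceeds "
                         f"{config.rhat_flag}")
        if min(acc) < config.min_acceptance:
            flags.append(f"mean acceptance {min(acc):.3f} below "
                         f"{config.min_acceptance}")
        diag["flags"] = flags
        diag["converged"] = not flags
    return replace(draws, diagnostics=diag)


# --------------------------------------------------------------------------
# post-processing
# --------------------------------------------------------------------------

def posterior_predictive(draws: PosteriorDraws, data: PreparedData,
                         rng: np.random.Generator | None = None) -> dict:
    """Replicate observations from the observation model per retained draw.

    Each replicated set adds independent normal noise (with the
    anomalous-year polar-cod inflation) around the draw's latent states.
    Returns the replicates and per-year/species envelope summaries (median,
    2.5 and 97.5 percentiles) plus the empirical coverage of the 95%
    envelope over the observed points.
    """
    rng = rng or np.random.default_rng(0)
    Rv = _obs_variances(draws.theta, data)           # (n, T, 3)
    y_rep = draws.states + np.sqrt(Rv) * rng.standard_normal(Rv.shape)
    lo, med, hi = np.percentile(y_rep, [2.5, 50.0, 97.5], axis=0)
    obs = ~np.isnan(data.y)
    covered = (data.y >= lo) & (data.y <= hi) & obs
    return {
        "y_rep": y_rep,
        "median": med,
        "lower": lo,
        "upper": hi,
        "coverage": float(covered.sum() / obs.sum()),
    }


def bayesian_r2(draws: PosteriorDraws, data: PreparedData) -> np.ndarray:
    """Variance-explained R^2 per draw and species on the process scale.

    For each draw, the fitted deterministic one-step predictions mu_t (the
    Gompertz map evaluated at the draw's latent states) are compared with
    the draw's process-error variance: R^2 = Var(mu) / (Var(mu) +
    sigma_proc^2).  Returns an (n_draws, 3) array with values in [0, 1].
    """
    mu = conditional_means_batch(draws.theta, draws.states, data)
    var_pred = np.var(mu, axis=1, ddof=1)            # (n, 3)
    sig2 = draws.params[:, 21:24] ** 2
    total = var_pred + sig2
    if np.any(total <= 0):
        raise ValueError("zero total variance in R^2 computation")
    return var_pred / total


def report_table(draws: PosteriorDraws, explanatory_sds: dict | None = None,
                 data: PreparedData | None = None) -> pd.DataFrame:
    """Coefficient summary: median, 5%, 95% and effect strength.

    Effect strength divides each coefficient median by the SD of its
    explanatory variable; coefficients on z-scored covariates (ST, ice, F)
    are left unchanged.  The SDs come from ``explanatory_sds`` (mapping
    coefficient name to SD, or None for z-scored) or, if ``data`` is given,
    from the SDs of the log-abundance/log-herring regressors; intercepts
    get no scaling (NaN) unless an SD is supplied explicitly.
    """
    from .model_core import effect_strength

    if explanatory_sds is None:
        explanatory_sds = {}
        if data is not None:
            sds = dict(zip(("cod", "cap", "pcod", "herring"), data.log_sds))
            for name in COEF_NAMES:
                driver = name.rsplit("_", 1)[1]
                if driver in sds:
                    explanatory_sds[name] = sds[driver]
                elif driver in ("st", "ice", "F"):
                    explanatory_sds[name] = None
    rows = []
    for k, name in enumerate(draws.param_names[:21]):
        med, q5, q95 = np.percentile(draws.params[:, k], [50, 5, 95])
        if name in explanatory_sds:
            sd = explanatory_sds[name]
            eff = effect_strength(med, sd, is_zscored=sd is None)
        else:
            driver = name.rsplit("_", 1)[1]
            eff = med if driver in ("st", "ice", "F") else np.nan
        rows.append({"parameter": name, "median": med, "q5": q5,
                     "q95": q95, "effect_strength": eff})
    return pd.DataFrame(rows)


def sample_ratio_prior(n: int, seed: int | None = None, mean: float = 2.0,
                       sd: float = 0.5) -> np.ndarray:
    """Draw from the observation/process variance-ratio prior: a
    Normal(mean, sd) truncated at zero (truncation shifts the mean by a
    negligible ~3e-4 at the default 2 +/- 0.5)."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=np.random.default_rng(seed))


def ratio_prior_sensitivity(data, config: SamplerConfig,
                            ratio_means=(1.0, 2.0, 3.0),
                            priors: PriorConfig | None = None) -> pd.DataFrame:
    """Refit under alternative variance-ratio prior centres and tabulate the
    coefficient medians side by side (the model's prior-sensitivity check)."""
    priors = priors or PriorConfig()
    frames = {}
    for m in ratio_means:
        d = sample_posterior(data, replace(priors, ratio_mean=m), config)
        frames[m] = report_table(d).set_index("parameter")["median"]
    out = pd.DataFrame({f"ratio_mean={m}": s for m, s in frames.items()})
    return out
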