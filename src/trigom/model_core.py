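"""Data model and joint density of the three-species Gompertz state-space model.

The model describes the coupled dynamics of three Barents Sea fish
populations -- northeast Arctic cod (a boreal piscivore), capelin (a boreal
forage fish) and polar cod (an Arctic, ice-associated forage fish) -- on the
natural-log abundance scale.  Each species follows a Gompertz (log-linear)
map driven by its own lagged abundance, the other two species, young herring
biomass, a fishing-mortality index and one climate covariate (Kola-transect
sea temperature for cod and capelin, the winter sea-ice index for polar
cod).  Because the cod, herring and ice observations fall between successive
capelin / polar-cod surveys, the capelin and polar-cod equations use the
*current-year* cod, herring and ice values; everything else enters at a one
year lag.

Process errors of the three equations are jointly multivariate normal;
observed log abundances carry independent normal observation error whose
variance is tied to the process-error variance through a per-species ratio
parameter.  One anomalously low polar-cod survey year may carry an extra
observation-error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SPECIES = ("cod", "cap", "pcod")

__all__ = [
    "SPECIES",
    "AbundanceTable",
    "ClimateSeries",
    "ModelParams",
    "LatentStates",
    "ProcessErrors",
    "PriorConfig",
    "PreparedData",
    "zscore",
    "inverse_zscore",
    "fishing_proxy",
    "effect_strength",
    "gompertz_step",
    "joint_log_density",
    "prepare_data",
    "COEF_NAMES",
]


class DegenerateInputError(ValueError):
    """Raised when an input series has no variance or an empty range."""


# --------------------------------------------------------------------------
# preprocessing transforms
# --------------------------------------------------------------------------

def zscore(series: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Standardize a series to mean 0, SD 1 (sample SD, denominator n-1).

    Returns ``(standardized, mean, sd)`` so the transform can be inverted or
    re-applied to new data (e.g. scenario covariates are standardized with
    the mean/SD of the observed series they replace).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("zscore needs a 1-d series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("zscore input must be finite")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("constant series cannot be z-scored")
    return (x - mean) / sd, mean, sd


def inverse_zscore(z: Sequence[float], mean: float, sd: float) -> np.ndarray:
    """Undo :func:`zscore` given the stored mean and SD."""
    return np.asarray(z, dtype=float) * sd + mean


def fishing_proxy(landings: float, biomass: float) -> float:
    """Instantaneous fishing-mortality proxy ``-ln(1 - landings/biomass)``.

    Valid for ``0 <= landings < biomass``; monotone increasing in landings
    and zero when nothing is landed.
    """
    landings = np.asarray(landings, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    if np.any(biomass <= 0):
        raise ValueError("biomass must be strictly positive")
    if np.any(landings < 0):
        raise ValueError("landings must be non-negative")
    if np.any(landings >= biomass):
        raise ValueError("landings must be strictly below biomass")
    out = -np.log1p(-(landings / biomass))
    return float(out) if out.ndim == 0 else out


def effect_strength(coef_median: float, explanatory_sd: float | None = None,
                    is_zscored: bool = False) -> float:
    """Scale a coefficient by the SD of its explanatory variable.

    Coefficients on already z-scored covariates are returned unchanged;
    otherwise the posterior median is divided by the explanatory variable's
    standard deviation so effects on differently scaled regressors become
    comparable.
    """
    if is_zscored:
        return float(coef_median)
    if explanatory_sd is None or explanatory_sd == 0:
        raise ValueError("explanatory_sd must be nonzero for a non-z-scored covariate")
    return float(coef_median) / float(explanatory_sd)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

def _as_float_array(x, name: str, n: int | None = None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if n is not None and a.size != n:
        raise ValueError(f"{name} has length {a.size}, expected {n}")
    return a


@dataclass(frozen=True)
class AbundanceTable:
    """Annual observed abundances plus exogenous biological series.

    Units: cod in 10^6 individuals, capelin and polar cod in 10^9
    individuals, herring in 10^6 tonnes; the three fishing columns are
    dimensionless mortality indices.  Missing survey values are NaN.
    """

    years: np.ndarray
    cod: np.ndarray
    cap: np.ndarray
    pcod: np.ndarray
    herring: np.ndarray
    f_cod: np.ndarray
    f_cap: np.ndarray
    f_pcod: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "years", years)
        if years.size < 2 or np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive calendar years (step 1)")
        n = years.size
        for name in ("cod", "cap", "pcod", "herring", "f_cod", "f_cap", "f_pcod"):
            a = _as_float_array(getattr(self, name), name, n)
            object.__setattr__(self, name, a)
        for name in ("cod", "cap", "pcod", "herring"):
            a = getattr(self, name)
            obs = a[~np.isnan(a)]
            if np.any(obs <= 0):
                raise ValueError(f"{name} must be strictly positive where observed")
        for name in ("f_cod", "f_cap", "f_pcod"):
            if np.any(np.isnan(getattr(self, name))):
                raise ValueError(f"{name} may not contain missing values")

    @property
    def n_years(self) -> int:
        return self.years.size

    def missing_mask(self) -> np.ndarray:
        """Boolean (T, 3) mask, True where a species observation is missing."""
        return np.column_stack([np.isnan(self.cod), np.isnan(self.cap),
                                np.isnan(self.pcod)])


@dataclass(frozen=True)
class ClimateSeries:
    """Annual winter sea-ice index (10^5 km^2) and Kola sea temperature (degC).

    ``z_ice``/``z_st`` are the standardized versions actually entering the
    model; they are recomputed from ``ice``/``st`` if not supplied.
    """

    years: np.ndarray
    ice: np.ndarray
    st: np.ndarray
    z_ice: np.ndarray | None = None
    z_st: np.ndarray | None = None
    ice_mean: float = field(default=np.nan)
    ice_sd: float = field(default=np.nan)
    st_mean: float = field(default=np.nan)
    st_sd: float = field(default=np.nan)

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "years", years)
        if years.size < 2 or np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive calendar years (step 1)")
        n = years.size
        ice = _as_float_array(self.ice, "ice", n)
        st = _as_float_array(self.st, "st", n)
        if np.any(~np.isfinite(ice)) or np.any(ice <= 0):
            raise ValueError("ice must be finite and strictly positive")
        if np.any(~np.isfinite(st)):
            raise ValueError("st must be finite")
        object.__setattr__(self, "ice", ice)
        object.__setattr__(self, "st", st)
        if self.z_ice is None:
            z, m, s = zscore(ice)
            object.__setattr__(self, "z_ice", z)
            object.__setattr__(self, "ice_mean", m)
            object.__setattr__(self, "ice_sd", s)
        else:
            object.__setattr__(self, "z_ice", _as_float_array(self.z_ice, "z_ice", n))
        if self.z_st is None:
            z, m, s = zscore(st)
            object.__setattr__(self, "z_st", z)
            object.__setattr__(self, "st_mean", m)
            object.__setattr__(self, "st_sd", s)
        else:
            object.__setattr__(self, "z_st", _as_float_array(self.z_st, "z_st", n))

    @property
    def n_years(self) -> int:
        return self.years.size


# Flat coefficient order used throughout inference and reporting.
COEF_NAMES = (
    "a_cod_0", "a_cod_cod", "a_cod_cap", "a_cod_pcod",
    "a_cod_herring", "a_cod_st", "a_cod_F",
    "a_cap_0", "a_cap_cap", "a_cap_pcod", "a_cap_cod",
    "a_cap_herring", "a_cap_st", "a_cap_F",
    "a_pcod_0", "a_pcod_pcod", "a_pcod_cap", "a_pcod_cod",
    "a_pcod_herring", "a_pcod_ice", "a_pcod_F",
)


@dataclass(frozen=True)
class ModelParams:
    """All structural parameters of the joint model.

    Coefficient naming is ``a_<response>_<driver>``; ``a_cap_cod`` and
    ``a_pcod_cod`` multiply *current-year* cod log abundance, every other
    species/herring/climate/fishing driver is timed as described in the
    module docstring.  ``sigma_proc`` are marginal process-error SDs and
    ``R_proc`` their correlation matrix; observation variances are
    ``r_obs[i] * sigma_proc[i]**2``.  ``sigma_pcod_1995`` is the extra SD on
    the designated anomalous polar-cod observation.
    """

    a_cod_0: float = 0.0
    a_cod_cod: float = 0.0
    a_cod_cap: float = 0.0
    a_cod_pcod: float = 0.0
    a_cod_herring: float = 0.0
    a_cod_st: float = 0.0
    a_cod_F: float = 0.0
    a_cap_0: float = 0.0
    a_cap_cap: float = 0.0
    a_cap_pcod: float = 0.0
    a_cap_cod: float = 0.0
    a_cap_herring: float = 0.0
    a_cap_st: float = 0.0
    a_cap_F: float = 0.0
    a_pcod_0: float = 0.0
    a_pcod_pcod: float = 0.0
    a_pcod_cap: float = 0.0
    a_pcod_cod: float = 0.0
    a_pcod_herring: float = 0.0
    a_pcod_ice: float = 0.0
    a_pcod_F: float = 0.0
    sigma_proc: np.ndarray = field(default_factory=lambda: np.ones(3))
    R_proc: np.ndarray = field(default_factory=lambda: np.eye(3))
    r_obs: np.ndarray = field(default_factory=lambda: 2.0 * np.ones(3))
    sigma_pcod_1995: float = 0.0

    def __post_init__(self):
        sp = np.asarray(self.sigma_proc, dtype=float)
        R = np.asarray(self.R_proc, dtype=float)
        ro = np.asarray(self.r_obs, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError("sigma_proc must be a positive 3-vector")
        if ro.shape != (3,) or np.any(ro <= 0):
            raise ValueError("r_obs must be a positive 3-vector")
        if R.shape != (3, 3) or not np.allclose(R, R.T, atol=1e-12) \
                or not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("R_proc must be symmetric with unit diagonal")
        if np.any(np.linalg.eigvalsh(R) <= 0):
            raise ValueError("R_proc must be positive-definite")
        if self.sigma_pcod_1995 < 0:
            raise ValueError("sigma_pcod_1995 must be non-negative")
        object.__setattr__(self, "sigma_proc", sp)
        object.__setattr__(self, "R_proc", R)
        object.__setattr__(self, "r_obs", ro)

    # -- derived structural matrices ------------------------------------

    @property
    def Sigma_proc(self) -> np.ndarray:
        """Process-error covariance diag(sigma) R diag(sigma)."""
        d = np.diag(self.sigma_proc)
        return d @ self.R_proc @ d

    @property
    def sigma_obs2(self) -> np.ndarray:
        """Per-species observation variances r_obs * sigma_proc^2."""
        return self.r_obs * self.sigma_proc ** 2

    @property
    def lag_matrix(self) -> np.ndarray:
        """Coefficients on lagged log abundances, species order (cod, cap, pcod)."""
        return np.array([
            [self.a_cod_cod, self.a_cod_cap, self.a_cod_pcod],
            [0.0, self.a_cap_cap, self.a_cap_pcod],
            [0.0, self.a_pcod_cap, self.a_pcod_pcod],
        ])

    @property
    def contemporaneous_matrix(self) -> np.ndarray:
        """Unit lower-triangular map routing current-year cod into cap/pcod."""
        M = np.eye(3)
        M[1, 0] = self.a_cap_cod
        M[2, 0] = self.a_pcod_cod
        return M

    @property
    def transition_matrix(self) -> np.ndarray:
        """Implied lag-1 (VAR) transition matrix after substituting the
        contemporaneous cod term into the capelin and polar-cod rows."""
        return self.contemporaneous_matrix @ self.lag_matrix

    @property
    def innovation_cov(self) -> np.ndarray:
        """Covariance of the effective VAR innovation M eps."""
        M = self.contemporaneous_matrix
        return M @ self.Sigma_proc @ M.T

    def coef_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COEF_NAMES])

    def with_coefs(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatentStates:
    """True log abundances, shape (T, 3), species order (cod, cap, pcod)."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3 or not np.all(np.isfinite(x)):
            raise ValueError("x must be a finite (T, 3) matrix")
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class ProcessErrors:
    """Process-error realisations, one row per transition year, shape (T-1, 3)."""

    eps: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.eps, dtype=float)
        if e.ndim != 2 or e.shape[1] != 3 or not np.all(np.isfinite(e)):
            raise ValueError("eps must be a finite (T-1, 3) matrix")
        object.__setattr__(self, "eps", e)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors; every entry is overridable from the run config.

    Coefficients get Normal(0, coef_sd); process-error SDs half-Normal(0,
    sigma_proc_scale); the process-error correlation matrix a flat prior
    over the valid (positive-definite) region; the per-species
    observation/process variance ratio Normal(ratio_mean, ratio_sd)
    truncated at zero; the extra anomalous-year polar-cod observation SD
    half-Normal(0, sigma_anom_scale).  The initial latent state is a priori
    normal around the first log observation per species with SD
    ``init_state_sd``.
    """

    coef_sd: float = 5.0
    sigma_proc_scale: float = 2.0
    ratio_mean: float = 2.0
    ratio_sd: float = 0.5
    sigma_anom_scale: float = 2.0
    init_state_sd: float = 5.0


# --------------------------------------------------------------------------
# prepared (design-matrix) view of a dataset
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PreparedData:
    """Model-ready arrays derived from an AbundanceTable + ClimateSeries.

    ``y`` holds observed log abundances (NaN where missing); covariates are
    standardized exactly as the model consumes them.  ``anomaly_index`` is
    the row of the designated anomalous polar-cod observation year (or -1).
    The stored z-transform means/SDs let scenario covariates be standardized
    with the observed series' transform.
    """

    years: np.ndarray
    y: np.ndarray                # (T, 3) log observed abundances, NaN = missing
    herring_ln: np.ndarray       # (T,)
    st_z: np.ndarray             # (T,)
    ice_z: np.ndarray            # (T,)
    F_z: np.ndarray              # (T, 3) z-scored fishing indices
    anomaly_index: int
    ice_mean: float
    ice_sd: float
    st_mean: float
    st_sd: float
    log_sds: np.ndarray          # (T-agnostic) SD of each ln-abundance + ln-herring column

    @property
    def n_years(self) -> int:
        return self.years.size

    def covariate_rows(self):
        """Design rows for transitions into years[1:].

        Returns (X_cod, X_cap, X_pcod), each (T-1, 4) with columns
        [1, ln herring, climate, fishing] at the timing each equation uses:
        cod everything lagged; capelin current herring, lagged ST/F;
        polar cod current herring and ice, lagged F.
        """
        lag = slice(0, -1)
        cur = slice(1, None)
        ones = np.ones(self.n_years - 1)
        X_cod = np.column_stack([ones, self.herring_ln[lag], self.st_z[lag],
                                 self.F_z[lag, 0]])
        X_cap = np.column_stack([ones, self.herring_ln[cur], self.st_z[lag],
                                 self.F_z[lag, 1]])
        X_pcod = np.column_stack([ones, self.herring_ln[cur], self.ice_z[cur],
                                  self.F_z[lag, 2]])
        return X_cod, X_cap, X_pcod


def prepare_data(abund: AbundanceTable, climate: ClimateSeries,
                 anomaly_year: int | None = 1995) -> PreparedData:
    """Assemble model-ready arrays; z-scores ST, ice and fishing indices."""
    if not np.array_equal(abund.years, climate.years):
        raise ValueError("abundance and climate tables must cover the same years")
    y = np.column_stack([
        np.log(abund.cod), np.log(abund.cap), np.log(abund.pcod)
    ])
    herring_ln = np.log(abund.herring)
    st_z, st_mean, st_sd = zscore(climate.st)
    ice_z, ice_mean, ice_sd = zscore(np.asarray(climate.ice))
    F_z = np.column_stack([zscore(f)[0] for f in
                           (abund.f_cod, abund.f_cap, abund.f_pcod)])
    if anomaly_year is not None and anomaly_year in abund.years:
        anomaly_index = int(np.flatnonzero(abund.years == anomaly_year)[0])
    else:
        anomaly_index = -1
    log_sds = np.array([
        np.nanstd(y[:, 0], ddof=1), np.nanstd(y[:, 1], ddof=1),
        np.nanstd(y[:, 2], ddof=1), np.std(herring_ln, ddof=1),
    ])
    return PreparedData(
        years=abund.years.copy(), y=y, herring_ln=herring_ln,
        st_z=st_z, ice_z=ice_z, F_z=F_z, anomaly_index=anomaly_index,
        ice_mean=ice_mean, ice_sd=ice_sd, st_mean=st_mean, st_sd=st_sd,
        log_sds=log_sds,
    )


# --------------------------------------------------------------------------
# the Gompertz map and the joint density
# --------------------------------------------------------------------------

def gompertz_step(x_prev, cod_t, herring_lag, herring_t, st_lag, ice_t,
                  F_lag, params: ModelParams) -> np.ndarray:
    """Deterministic part of the one-year update of all three equations.

    ``x_prev`` holds last year's log abundances (cod, cap, pcod); ``cod_t``
    is the current-year cod log abundance entering the capelin and polar-cod
    equations (ignored by the cod equation itself).  Herring enters lagged
    (ln scale) for cod and current-year for the other two; ST lagged
    (z-scored) for cod and capelin; ice current-year (z-scored) for polar
    cod; fishing indices (z-scored 3-vector) lagged for all.  Returns the
    expected log abundances without process error.
    """
    x_prev = np.asarray(x_prev, dtype=float)
    F_lag = np.asarray(F_lag, dtype=float)
    vals = np.concatenate([x_prev, [cod_t, herring_lag, herring_t, st_lag,
                                    ice_t], F_lag])
    if x_prev.shape != (3,) or F_lag.shape != (3,) or not np.all(np.isfinite(vals)):
        raise ValueError("gompertz_step requires finite inputs of the right shape")
    p = params
    cod = (p.a_cod_0 + p.a_cod_cod * x_prev[0] + p.a_cod_cap * x_prev[1]
           + p.a_cod_pcod * x_prev[2] + p.a_cod_herring * herring_lag
           + p.a_cod_st * st_lag + p.a_cod_F * F_lag[0])
    cap = (p.a_cap_0 + p.a_cap_cap * x_prev[1] + p.a_cap_pcod * x_prev[2]
           + p.a_cap_cod * cod_t + p.a_cap_herring * herring_t
           + p.a_cap_st * st_lag + p.a_cap_F * F_lag[1])
    pcod = (p.a_pcod_0 + p.a_pcod_pcod * x_prev[2] + p.a_pcod_cap * x_prev[1]
            + p.a_pcod_cod * cod_t + p.a_pcod_herring * herring_t
            + p.a_pcod_ice * ice_t + p.a_pcod_F * F_lag[2])
    return np.array([cod, cap, pcod])


def conditional_means(params: ModelParams, states: LatentStates,
                      data: PreparedData) -> np.ndarray:
    """Expected log abundances for years[1:], given states and covariates.

    Row t is gompertz_step evaluated at the latent state of year t-1 with
    the latent current-year cod of year t -- the deterministic part each
    process error is measured against.
    """
    x = states.x
    T = data.n_years
    out = np.empty((T - 1, 3))
    for j in range(1, T):
        out[j - 1] = gompertz_step(
            x[j - 1], x[j, 0], data.herring_ln[j - 1], data.herring_ln[j],
            data.st_z[j - 1], data.ice_z[j], data.F_z[j - 1], params)
    return out


def _mvn_logpdf(resid: np.ndarray, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive-definite")
    sol = np.linalg.solve(cov, resid.T)
    quad = np.einsum("ij,ji->i", resid, sol)
    k = cov.shape[0]
    return float(np.sum(-0.5 * (k * np.log(2 * np.pi) + logdet + quad)))


def _normal_logpdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def log_prior(params: ModelParams, priors: PriorConfig) -> float:
    """Log prior density of a parameter set (unnormalized where harmless).

    The truncated-normal ratio prior and the flat correlation prior are
    evaluated up to constants that do not depend on the parameters.
    """
    lp = float(np.sum(_normal_logpdf(params.coef_vector(), 0.0,
                                     priors.coef_sd ** 2)))
    lp += float(np.sum(-0.5 * params.sigma_proc ** 2
                       / priors.sigma_proc_scale ** 2))
    lp += float(np.sum(_normal_logpdf(params.r_obs, priors.ratio_mean,
                                      priors.ratio_sd ** 2)))
    if params.sigma_pcod_1995 > 0:
        lp += -0.5 * params.sigma_pcod_1995 ** 2 / priors.sigma_anom_scale ** 2
    return lp


def joint_log_density(params: ModelParams, states: LatentStates,
                      data: PreparedData,
                      priors: PriorConfig | None = None) -> float:
    """Joint log density: process + observation + initial state + priors.

    The process term is the multivariate-normal density of the three process
    errors per transition under Sigma_proc; the observation term is
    independent normals of each observed log abundance around its latent
    state (the anomalous polar-cod year gets variance sigma_obs^2 +
    sigma_pcod_1995^2; missing observations contribute nothing); the initial
    state is normal around the first observation per species.  With
    ``priors=None`` only the data terms are returned.
    """
    x = states.x
    if x.shape[0] != data.n_years:
        raise ValueError("states not dimensioned to the data")
    mu = conditional_means(params, states, data)
    # process errors of the three equations: cap/pcod rows are conditioned on
    # current-year cod, so residuals against conditional_means ARE the eps
    eps = x[1:] - mu
    ld = _mvn_logpdf(eps, params.Sigma_proc)

    # observation model
    sobs2 = params.sigma_obs2
    for i in range(3):
        obs = ~np.isnan(data.y[:, i])
        var = np.full(data.n_years, sobs2[i])
        if i == 2 and data.anomaly_index >= 0:
            var[data.anomaly_index] += params.sigma_pcod_1995 ** 2
        ld += float(np.sum(_normal_logpdf(data.y[obs, i], x[obs, i], var[obs])))

    # initial state
    if priors is not None:
        m0 = initial_state_mean(data)
        ld += float(np.sum(_normal_logpdf(x[0], m0, priors.init_state_sd ** 2)))
        ld += log_prior(params, priors)
    return ld


def initial_state_mean(data: PreparedData) -> np.ndarray:
    """Prior mean of the initial latent state: first observed log abundance
    per species (column mean as fallback if the first year is missing)."""
    m0 = np.empty(3)
    for i in range(3):
        col = data.y[:, i]
        obs = np.flatnonzero(~np.isnan(col))
        m0[i] = col[obs[0]] if obs.size else 0.0
    return m0
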