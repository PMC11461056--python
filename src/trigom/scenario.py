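"""Hindcast scenario engine: counterfactual climate, re-simulation, filtering.

The hindcast asks what the three populations would have done over the
observed window under a different climate state.  The low-sea-ice scenario
replaces the winter sea-ice series by a flatter declining log-linear trend
(anchored at the recorded first-year value and passing through the original
trend's end-year prediction), with the original trend residuals shrunk by
30% to keep the year-to-year variation pattern; sea temperature follows via
the fitted ST~ice linear relation, with parameter uncertainty propagated by
bootstrap and collapsed to per-year medians.

Per posterior draw, trajectories are then re-simulated forward from the
draw's first-year latent state under the scenario covariates, adding back
the draw's own historically estimated process errors so that the realized
"unexplained" dynamics are preserved.  Draws whose implied lag-1 transition
matrix is non-stationary (spectral radius >= 1) are excluded from scenario
summaries.  An unperturbed scenario reproduces each draw's baseline latent
trajectory exactly, which is the engine's master consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model_core import SPECIES, ClimateSeries, PreparedData
from .inference import (
    PosteriorDraws,
    _covariate_intercepts,
    _structure,
    conditional_means_batch,
)

__all__ = [
    "IceTrendFit",
    "StIceFit",
    "ScenarioSpec",
    "HindcastResult",
    "fit_ice_trend",
    "build_scenario_ice",
    "fit_st_ice",
    "ice_to_st",
    "scenario_climate",
    "extract_process_errors",
    "hindcast",
    "stationarity_filter",
    "transition_radii",
    "compare_medians",
]


@dataclass(frozen=True)
class IceTrendFit:
    """OLS fit of ln(ice) on calendar year."""

    years: np.ndarray
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residuals: np.ndarray
    r_squared: float

    def predict(self, year) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


@dataclass(frozen=True)
class StIceFit:
    """OLS fit of z-scored sea temperature on z-scored ice, with SEs."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residuals: np.ndarray
    resid_sd: float
    r_squared: float

    def predict(self, ice_z) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ice_z, dtype=float)


@dataclass(frozen=True)
class ScenarioSpec:
    """Settings of the low-ice scenario construction.

    ``residual_shrink`` is the fraction removed from the ice-trend residuals
    (0.30 keeps 70% of each residual); the scenario line runs from the
    recorded first-year ln(ice) to the original trend's end-year prediction
    and is anchored through the recorded end-year ln(ice); ``n_boot``
    bootstrap replicates propagate the ST~ice parameter uncertainty.
    ``st_residual_noise`` optionally resamples residual noise as well.
    """

    residual_shrink: float = 0.30
    n_boot: int = 100
    seed: int = 0
    st_residual_noise: bool = False
    split_year: int = 2005      # era boundary for the slope comparison

    def __post_init__(self):
        if not 0.0 <= self.residual_shrink < 1.0:
            raise ValueError("residual_shrink must be in [0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


# --------------------------------------------------------------------------
# scenario covariate construction
# --------------------------------------------------------------------------

def fit_ice_trend(climate: ClimateSeries) -> IceTrendFit:
    """OLS regression of ln(ice) on calendar year; residuals kept for reuse."""
    years = np.asarray(climate.years, dtype=float)
    if years.size < 3 or np.ptp(years) == 0:
        raise ValueError("need at least 3 distinct years")
    ln_ice = np.log(climate.ice)
    res = sm.OLS(ln_ice, sm.add_constant(years)).fit()
    return IceTrendFit(
        years=climate.years.copy(),
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        residuals=np.asarray(res.resid), r_squared=float(res.rsquared))


def build_scenario_ice(climate: ClimateSeries, fit: IceTrendFit,
                       spec: ScenarioSpec | None = None) -> np.ndarray:
    """Construct the low-ice scenario series on the natural scale.

    The new line's slope runs from the recorded first-year ln(ice) to the
    original fit's prediction for the last year, and its intercept makes it
    pass through the recorded last-year ln(ice).  Shrunk residuals
    (``1 - residual_shrink`` of the originals) are added on, and the first
    year is reset to the recorded value.
    """
    spec = spec or ScenarioSpec()
    if not np.array_equal(fit.years, climate.years):
        raise ValueError("fit must come from the same ice series")
    years = np.asarray(climate.years, dtype=float)
    y0, y1 = years[0], years[-1]
    if y1 == y0:
        raise ValueError("degenerate year range")
    ln_ice = np.log(climate.ice)
    new_slope = (fit.predict(y1) - ln_ice[0]) / (y1 - y0)
    new_intercept = ln_ice[-1] - new_slope * y1
    line = new_intercept + new_slope * years
    scen = line + (1.0 - spec.residual_shrink) * fit.residuals
    scen[0] = ln_ice[0]
    early = slice(1, years.size // 2)
    if np.any(scen[early] > ln_ice[early] + 1e-12):
        warnings.warn("scenario ln(ice) exceeds the observed series in "
                      "high-ice years; the scenario may not represent a "
                      "low-ice state for this dataset", stacklevel=2)
    return np.exp(scen)


def fit_st_ice(climate: ClimateSeries) -> StIceFit:
    """OLS of z-scored sea temperature on z-scored ice with coefficient SEs."""
    if climate.n_years < 3:
        raise ValueError("need at least 3 years")
    x, y = climate.z_ice, climate.z_st
    if np.ptp(x) == 0:
        raise ValueError("degenerate ice series")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(res.resid)
    return StIceFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        residuals=resid, resid_sd=float(np.std(resid, ddof=1)),
        r_squared=float(res.rsquared))


def ice_to_st(scenario_ice_z: np.ndarray, fit: StIceFit, n_boot: int = 100,
              seed: int | None = 0, residual_noise: bool = False
              ) -> np.ndarray:
    """Scenario sea temperature (z-scale) from scenario ice (z-scale).

    Each bootstrap replicate draws the slope and intercept from independent
    normals centred at the OLS estimates with their standard errors,
    predicts ST for every year, and the per-year median across replicates
    is returned.  ``residual_noise=True`` additionally resamples normal
    residual noise around the line.  Deterministic under ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ice_z = np.asarray(scenario_ice_z, dtype=float)
    rng = np.random.default_rng(seed)
    slopes = rng.normal(fit.slope, fit.slope_se, size=n_boot)
    intercepts = rng.normal(fit.intercept, fit.intercept_se, size=n_boot)
    pred = intercepts[:, None] + slopes[:, None] * ice_z[None, :]
    if residual_noise:
        pred = pred + rng.normal(0.0, fit.resid_sd, size=pred.shape)
    return np.median(pred, axis=0)


def scenario_climate(data: PreparedData, climate: ClimateSeries,
                     spec: ScenarioSpec | None = None) -> dict:
    """Full low-ice covariate construction for a dataset.

    Fits the ice trend, builds the scenario ice, maps it to scenario sea
    temperature via the bootstrapped ST~ice relation, and standardizes both
    with the observed series' z-transforms (so model coefficients keep
    their meaning).  Returns a dict with the scenario series on natural and
    z scales plus the two fits.
    """
    spec = spec or ScenarioSpec()
    trend = fit_ice_trend(climate)
    ice_scen = build_scenario_ice(climate, trend, spec)
    ice_z_scen = (ice_scen - data.ice_mean) / data.ice_sd
    st_fit = fit_st_ice(climate)
    st_z_scen = ice_to_st(ice_z_scen, st_fit, n_boot=spec.n_boot,
                          seed=spec.seed, residual_noise=spec.st_residual_noise)
    return {
        "ice": ice_scen, "ice_z": ice_z_scen, "st_z": st_z_scen,
        "st": st_z_scen * data.st_sd + data.st_mean,
        "ice_trend": trend, "st_fit": st_fit,
    }


# --------------------------------------------------------------------------
# process errors, forward re-simulation, stationarity
# --------------------------------------------------------------------------

def extract_process_errors(draws: PosteriorDraws, data: PreparedData
                           ) -> np.ndarray:
    """Per-draw process errors implied by the draw's latent states.

    Recomputed from scratch as the residual of each latent state against
    the Gompertz-map expectation (capelin and polar cod conditioned on the
    draw's current-year cod state): the reconstruction identity
    ``x_t = gompertz_step(...) + eps_t`` holds exactly.
    """
    if draws.states is None:
        raise ValueError("draws carry no latent states")
    mu = conditional_means_batch(draws.theta, draws.states, data)
    return draws.states[:, 1:] - mu


def transition_radii(theta: np.ndarray) -> np.ndarray:
    """Spectral radius of the implied lag-1 transition matrix per draw."""
    B, *_ = _structure(np.atleast_2d(theta))
    return np.max(np.abs(np.linalg.eigvals(B)), axis=1)


def stationarity_filter(draws) -> np.ndarray:
    """Boolean mask of draws whose implied VAR(1) dynamics are stationary.

    The lag-1 matrix substitutes the contemporaneous cod term into the
    capelin and polar-cod rows; a draw is kept iff its spectral radius is
    strictly below 1.
    """
    theta = draws.theta if isinstance(draws, PosteriorDraws) else draws
    return transition_radii(theta) < 1.0


@dataclass(frozen=True)
class HindcastResult:
    """Per-draw scenario trajectories with stationarity mask and baselines.

    ``scenario`` and ``baseline`` are (n_draws, T, 3) log abundances;
    summaries are computed over stationary draws only.
    """

    years: np.ndarray
    scenario: np.ndarray
    baseline: np.ndarray
    stationary: np.ndarray
    n_removed: int

    def median_summary(self, log_scale: bool = False) -> pd.DataFrame:
        """Tidy per-year/species medians and 95% envelopes over stationary
        draws for both runs (natural abundance scale by default)."""
        keep = self.stationary
        if keep.sum() == 0:
            raise ValueError("no stationary draws to summarise")
        rows = []
        for si, sp in enumerate(SPECIES):
            for run, traj in (("baseline", self.baseline),
                              ("scenario", self.scenario)):
                lo, med, hi = np.percentile(traj[keep, :, si],
                                            [2.5, 50.0, 97.5], axis=0)
                if not log_scale:
                    lo, med, hi = np.exp(lo), np.exp(med), np.exp(hi)
                for yi, yr in enumerate(self.years):
                    rows.append({"year": int(yr), "species": sp, "run": run,
                                 "median": med[yi], "lower": lo[yi],
                                 "upper": hi[yi]})
        return pd.DataFrame(rows)

    def medians(self, log_scale: bool = False):
        """(baseline_medians, scenario_medians), each (T, 3), over
        stationary draws."""
        keep = self.stationary
        b = np.median(self.baseline[keep], axis=0)
        s = np.median(self.scenario[keep], axis=0)
        if not log_scale:
            b, s = np.exp(b), np.exp(s)
        return b, s


def hindcast(draws: PosteriorDraws, data: PreparedData,
             st_z: np.ndarray | None = None,
             ice_z: np.ndarray | None = None,
             process_errors: np.ndarray | None = None,
             filter_stationary: bool = True) -> HindcastResult:
    """Re-simulate every posterior draw under scenario climate covariates.

    Starting from each draw's own first-year latent state, trajectories are
    rebuilt forward with the draw's parameters and the scenario sea
    temperature / ice (z-scale; observed values are used where ``None``),
    keeping the observed herring and fishing series, and adding back the
    draw's extracted process errors year by year (current-year cod feeding
    the capelin and polar-cod equations, as in the fitted model).  With
    unperturbed covariates this reproduces the baseline latent trajectories
    exactly.
    """
    T = data.n_years
    for name, arr in (("st_z", st_z), ("ice_z", ice_z)):
        if arr is not None and np.asarray(arr).shape != (T,):
            raise ValueError(f"{name} must cover the full year range ({T})")
    eps = draws.eps if process_errors is None else np.asarray(process_errors)
    if eps.shape != (draws.n_draws, T - 1, 3):
        raise ValueError("process errors not aligned with draws")

    sdata = data
    if st_z is not None:
        sdata = replace(sdata, st_z=np.asarray(st_z, dtype=float))
    if ice_z is not None:
        sdata = replace(sdata, ice_z=np.asarray(ice_z, dtype=float))

    theta = draws.theta
    B, Q, M, A, _, _ = _structure(theta)
    c = _covariate_intercepts(theta, sdata)
    d = np.einsum("nij,ntj->nti", M, c)
    Meps = np.einsum("nij,ntj->nti", M, eps)

    x = np.empty_like(draws.states)
    x[:, 0] = draws.states[:, 0]
    for j in range(1, T):
        x[:, j] = (d[:, j - 1] + np.einsum("nij,nj->ni", B, x[:, j - 1])
                   + Meps[:, j - 1])

    mask = (stationarity_filter(draws) if filter_stationary
            else np.ones(draws.n_draws, dtype=bool))
    return HindcastResult(years=data.years.copy(), scenario=x,
                          baseline=draws.states.copy(), stationary=mask,
                          n_removed=int((~mask).sum()))


# --------------------------------------------------------------------------
# scenario vs baseline comparison
# --------------------------------------------------------------------------

def _through_origin_slope(baseline: np.ndarray, scenario: np.ndarray) -> float:
    b = np.asarray(baseline, dtype=float)
    s = np.asarray(scenario, dtype=float)
    if b.size == 0:
        raise ValueError("empty period in slope comparison")
    return float(np.sum(s * b) / np.sum(b * b))


def compare_medians(baseline_medians: np.ndarray, scenario_medians: np.ndarray,
                    years: np.ndarray, split_year: int = 2005) -> pd.DataFrame:
    """Through-origin slopes of scenario vs baseline medians per species.

    Least-squares slopes through the origin are computed separately for
    years up to and including ``split_year`` (the strongly perturbed
    high-ice era) and after it, per species, together with their
    difference (early minus late).  Inputs are (T, 3) median series on a
    common year axis.
    """
    b = np.atleast_2d(np.asarray(baseline_medians, dtype=float))
    s = np.atleast_2d(np.asarray(scenario_medians, dtype=float))
    years = np.asarray(years)
    if b.shape != s.shape or b.shape[0] != years.size:
        raise ValueError("median series must share shape and years")
    early = years <= split_year
    late = ~early
    if not early.any() or not late.any():
        raise ValueError("split year leaves an empty period")
    rows = []
    for si in range(b.shape[1]):
        s_early = _through_origin_slope(b[early, si], s[early, si])
        s_late = _through_origin_slope(b[late, si], s[late, si])
        rows.append({"species": SPECIES[si] if b.shape[1] == 3 else str(si),
                     "slope_early": s_early, "slope_late": s_late,
                     "slope_diff": s_early - s_late})
    return pd.DataFrame(rows)
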