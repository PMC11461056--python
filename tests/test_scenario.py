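import numpy as np
import pytest

from trigom.model_core import ClimateSeries, PreparedData, prepare_data
from trigom.inference import params_to_vector
from trigom.scenario import (
    ScenarioSpec,
    build_scenario_ice,
    compare_medians,
    extract_process_errors,
    fit_ice_trend,
    fit_st_ice,
    hindcast,
    ice_to_st,
    scenario_climate,
    stationarity_filter,
    transition_radii,
)
from trigom.synthetic import default_params


def _climate_from_ln_ice(years, ln_ice, rng=None, st=None):
    rng = rng or np.random.default_rng(0)
    st = rng.normal(4, 0.5, len(years)) if st is None else st
    return ClimateSeries(years=np.asarray(years), ice=np.exp(ln_ice), st=st)


# ------------------------------------------------------------ ice trend

def test_fit_ice_trend_recovers_exact_line():
    years = np.arange(1986, 2018)
    f = fit_ice_trend(_climate_from_ln_ice(years, 40.0 - 0.02 * years))
    assert f.slope == pytest.approx(-0.02, abs=1e-10)
    assert f.intercept == pytest.approx(40.0, abs=1e-7)
    np.testing.assert_allclose(f.residuals, 0.0, atol=1e-10)


def test_fit_ice_trend_statistical_recovery(rng):
    years = np.arange(1986, 2018)
    ln = 128.37 - 0.064 * years + rng.normal(0, 0.3, years.size)
    f = fit_ice_trend(_climate_from_ln_ice(years, ln))
    assert abs(f.slope - (-0.064)) < 2 * f.slope_se
    assert f.residuals.sum() == pytest.approx(0.0, abs=1e-9)
    # fitted + residuals reproduce ln(ice) exactly
    np.testing.assert_allclose(f.predict(years) + f.residuals, ln, atol=1e-9)


# ------------------------------------------------------ scenario ice

def _anchored_orthogonal_residuals(years):
    """Residuals that are exactly OLS residuals of a linear trend (orthogonal
    to [1, year]) and vanish at both anchor years."""
    t = np.linspace(0, np.pi, years.size)
    modes = np.stack([np.sin(t), np.sin(2 * t), np.sin(3 * t)], axis=1)
    modes[0] = modes[-1] = 0.0
    X = np.column_stack([np.ones_like(years, dtype=float), years])
    # choose mode weights so the combination is orthogonal to the design
    A = X.T @ modes[:, :2]
    b = -X.T @ modes[:, 2]
    w = np.linalg.solve(A, b)
    r = modes[:, :2] @ w + modes[:, 2]
    return 0.1 * r


def test_build_scenario_ice_identity_configuration():
    years = np.arange(2000, 2010)
    resid = _anchored_orthogonal_residuals(years)
    clim = _climate_from_ln_ice(years, 30.0 - 0.015 * years + resid)
    f = fit_ice_trend(clim)
    np.testing.assert_allclose(f.residuals, resid, atol=1e-9)
    # anchor residuals are 0, so the new line coincides with the fitted one;
    # with no shrink the construction returns the original series exactly
    scen = build_scenario_ice(clim, f, ScenarioSpec(residual_shrink=0.0))
    np.testing.assert_allclose(scen, clim.ice, rtol=1e-8)


def test_build_scenario_ice_zero_residuals_pure_line():
    years = np.arange(2000, 2012)
    clim = _climate_from_ln_ice(years, 25.0 - 0.01 * years)
    f = fit_ice_trend(clim)
    scen = build_scenario_ice(clim, f, ScenarioSpec(residual_shrink=0.3))
    assert np.all(np.diff(np.log(scen)) < 0)      # monotone declining line
    np.testing.assert_allclose(np.diff(np.log(scen))[1:], -0.01, atol=1e-9)


def test_build_scenario_ice_matches_hand_construction(rng):
    years = np.arange(1990, 2000)
    ln = 20.0 - 0.03 * years + rng.normal(0, 0.2, 10)
    clim = _climate_from_ln_ice(years, ln)
    f = fit_ice_trend(clim)
    spec = ScenarioSpec(residual_shrink=0.30)
    got = np.log(build_scenario_ice(clim, f, spec))
    # hand construction, step by step
    new_slope = ((f.intercept + f.slope * 1999) - ln[0]) / (1999 - 1990)
    new_intercept = ln[-1] - new_slope * 1999
    line = new_intercept + new_slope * years
    want = line + 0.7 * f.residuals
    want[0] = ln[0]
    np.testing.assert_allclose(got, want, atol=1e-10)
    # residual dispersion about the new line shrinks by exactly 30%
    sd_new = np.std(got[1:] - line[1:], ddof=1)
    sd_old = np.std(f.residuals[1:], ddof=1)
    assert sd_new / sd_old == pytest.approx(0.7, abs=1e-10)


def test_build_scenario_ice_warns_when_not_lower(rng):
    # an *increasing* ice trend makes the "low-ice" construction sit above
    # the observed early years -> validation warning
    years = np.arange(2000, 2012)
    ln = -66.0 + 0.03 * years + 0.05 * rng.normal(size=12)
    clim = _climate_from_ln_ice(years, ln)
    f = fit_ice_trend(clim)
    with pytest.warns(UserWarning):
        build_scenario_ice(clim, f, ScenarioSpec())


# ------------------------------------------------------------- ST ~ ice

def test_fit_st_ice_exact_line():
    years = np.arange(2000, 2020)
    rng = np.random.default_rng(4)
    ice = np.exp(rng.normal(0, 0.4, 20))
    clim = ClimateSeries(years=years, ice=ice, st=5.0 - 2.0 * ice)
    f = fit_st_ice(clim)
    # on the z-scale an exact linear anti-correlation has slope -1
    assert f.slope == pytest.approx(-1.0, abs=1e-9)
    assert f.intercept == pytest.approx(0.0, abs=1e-9)
    assert f.slope_se == pytest.approx(0.0, abs=1e-7)


def test_fit_st_ice_negative_correlation_recovered(rng):
    years = np.arange(1900, 2100)
    z = rng.normal(0, 1, years.size)
    ice = np.exp(0.3 * z)
    z_ice = (ice - ice.mean()) / ice.std(ddof=1)
    st = 4.0 + 0.5 * (-0.75 * z_ice + np.sqrt(1 - 0.75 ** 2)
                      * rng.normal(0, 1, years.size))
    f = fit_st_ice(ClimateSeries(years=years, ice=ice, st=st))
    assert f.slope == pytest.approx(-0.75, abs=0.1)
    assert f.r_squared == pytest.approx(0.5625, abs=0.1)


def test_fit_st_ice_se_scales_with_residuals(rng):
    years = np.arange(2000, 2030)
    ice = np.exp(rng.normal(0, 0.3, 30))
    noise = rng.normal(0, 1, 30)
    noise -= noise.mean()
    base_st = 5.0 - 1.2 * ice
    f1 = fit_st_ice(ClimateSeries(years=years, ice=ice, st=base_st + 0.2 * noise))
    # doubling residuals on the raw scale changes the z-transform too, so
    # compare fits built on identical z-scored variables directly
    z_ice = (ice - ice.mean()) / ice.std(ddof=1)
    import statsmodels.api as sm
    r1 = sm.OLS(0.2 * noise, sm.add_constant(z_ice)).fit()
    r2 = sm.OLS(0.4 * noise, sm.add_constant(z_ice)).fit()
    assert r2.bse[1] == pytest.approx(2 * r1.bse[1], rel=1e-9)
    assert f1.slope_se > 0


# ------------------------------------------------------------- ice -> ST

def test_ice_to_st_degenerate_se_is_deterministic():
    from trigom.scenario import StIceFit
    f = StIceFit(slope=-0.75, intercept=0.05, slope_se=0.0,
                 intercept_se=0.0, residuals=np.zeros(5), resid_sd=0.0,
                 r_squared=1.0)
    ice_z = np.linspace(-2, 2, 7)
    for nb in (1, 10, 100):
        np.testing.assert_allclose(ice_to_st(ice_z, f, n_boot=nb, seed=1),
                                   0.05 - 0.75 * ice_z, atol=1e-12)


def test_ice_to_st_reproducible_and_convergent():
    from trigom.scenario import StIceFit
    f = StIceFit(slope=-0.75, intercept=0.05, slope_se=0.12,
                 intercept_se=0.11, residuals=np.zeros(5), resid_sd=0.3,
                 r_squared=0.56)
    ice_z = np.linspace(-2, 2, 9)
    a = ice_to_st(ice_z, f, n_boot=1, seed=42)
    b = ice_to_st(ice_z, f, n_boot=1, seed=42)
    np.testing.assert_array_equal(a, b)
    big = ice_to_st(ice_z, f, n_boot=20000, seed=0)
    np.testing.assert_allclose(big, 0.05 - 0.75 * ice_z, atol=0.01)


# ------------------------------------------------- process-error extraction

def test_extract_process_errors_reconstruction(small_fit, prepared32):
    eps = extract_process_errors(small_fit, prepared32)
    np.testing.assert_allclose(eps, small_fit.eps, atol=1e-10)
    # independent residual oracle on one draw
    from trigom.model_core import gompertz_step
    i = 3
    p = small_fit.param_set(i)
    x = small_fit.states[i]
    for j in (1, 10, prepared32.n_years - 1):
        mu = gompertz_step(x[j - 1], x[j, 0], prepared32.herring_ln[j - 1],
                           prepared32.herring_ln[j], prepared32.st_z[j - 1],
                           prepared32.ice_z[j], prepared32.F_z[j - 1], p)
        np.testing.assert_allclose(eps[i, j - 1], x[j] - mu, atol=1e-10)


def test_extract_process_errors_near_zero_for_deterministic_system():
    from trigom.synthetic import GeneratorConfig, generate, default_params
    import dataclasses
    p = dataclasses.replace(default_params(),
                            sigma_proc=np.full(3, 1e-8),
                            r_obs=np.full(3, 1e-6))
    ds = generate(GeneratorConfig(n_years=12, params=p, seed=3))
    assert np.max(np.abs(ds.eps.eps)) < 1e-6


# ----------------------------------------------------------- hindcast

def test_hindcast_identity_reproduces_baseline(small_fit, prepared32):
    res = hindcast(small_fit, prepared32)
    np.testing.assert_allclose(res.scenario, res.baseline, atol=1e-10)
    assert res.stationary.shape == (small_fit.n_draws,)
    assert res.n_removed == int((~res.stationary).sum())


def test_hindcast_warmer_scenario_raises_capelin(small_fit, prepared32):
    # a_cap_st > 0 for essentially all draws near the generating truth, so a
    # uniformly warmer ST must weakly raise capelin in the first perturbed year
    st_up = prepared32.st_z + 1.0
    res = hindcast(small_fit, prepared32, st_z=st_up)
    first = 1  # first transition uses lagged ST
    delta = res.scenario[:, first, 1] - res.baseline[:, first, 1]
    # by linearity: direct ST effect plus the cod-mediated contemporaneous one
    a_cod_st = small_fit.params[:, 5]
    a_cap_cod = small_fit.params[:, 10]
    a_cap_st = small_fit.params[:, 12]
    np.testing.assert_allclose(delta, a_cap_st + a_cap_cod * a_cod_st,
                               atol=1e-10)
    # the cod response itself is exactly its temperature coefficient
    delta_cod = res.scenario[:, first, 0] - res.baseline[:, first, 0]
    np.testing.assert_allclose(delta_cod, a_cod_st, atol=1e-10)
    # draws with a positive direct + mediated effect are weakly raised
    up = (a_cap_st + a_cap_cod * a_cod_st) >= 0
    assert np.all(delta[up] >= 0)


def test_hindcast_single_draw_hand_computation(small_fit):
    # T = 3, hand-computable coefficients on a minimal PreparedData
    T = 3
    data = PreparedData(
        years=np.arange(2000, 2003), y=np.zeros((T, 3)),
        herring_ln=np.array([0.1, 0.2, 0.3]), st_z=np.array([1.0, -1.0, 0.5]),
        ice_z=np.array([0.2, 0.1, -0.3]), F_z=np.zeros((T, 3)),
        anomaly_index=-1, ice_mean=1, ice_sd=1, st_mean=0, st_sd=1,
        log_sds=np.ones(4))
    p = default_params()
    theta = params_to_vector(p)[None, :]
    x0 = np.array([1.0, 2.0, 3.0])
    eps = np.array([[[0.1, -0.2, 0.05], [0.0, 0.1, -0.1]]])
    d = small_fit
    fake = type(d)(**{**d.__dict__, "theta": theta, "params": theta,
                      "chain": np.zeros(1), "iteration": np.zeros(1),
                      "states": np.tile(x0, (1, T, 1)),
                      "eps": eps, "years": data.years})
    res = hindcast(fake, data, process_errors=eps, filter_stationary=False)
    # hand forward simulation
    from trigom.model_core import gompertz_step
    x = np.empty((T, 3))
    x[0] = x0
    for j in (1, 2):
        cod = gompertz_step(x[j - 1], 0.0, data.herring_ln[j - 1],
                            data.herring_ln[j], data.st_z[j - 1],
                            data.ice_z[j], data.F_z[j - 1], p)[0] \
            + eps[0, j - 1, 0]
        full = gompertz_step(x[j - 1], cod, data.herring_ln[j - 1],
                             data.herring_ln[j], data.st_z[j - 1],
                             data.ice_z[j], data.F_z[j - 1], p)
        x[j] = full + eps[0, j - 1] * [1, 1, 1]
        x[j, 0] = cod
    np.testing.assert_allclose(res.scenario[0], x, atol=1e-10)


def test_hindcast_rejects_misaligned_covariates(small_fit, prepared32):
    with pytest.raises(ValueError):
        hindcast(small_fit, prepared32, st_z=np.zeros(5))


# ---------------------------------------------------- stationarity filter

def test_stationarity_filter_simple_cases():
    from trigom.model_core import ModelParams
    diag = params_to_vector(ModelParams(a_cod_cod=0.5, a_cap_cap=0.5,
                                        a_pcod_pcod=0.5))
    explosive = params_to_vector(ModelParams(a_cod_cod=1.2))
    mask = stationarity_filter(np.stack([diag, explosive]))
    assert mask.tolist() == [True, False]
    radii = transition_radii(np.stack([diag, explosive]))
    np.testing.assert_allclose(radii, [0.5, 1.2], atol=1e-12)


def test_stationarity_filter_agrees_with_simulation_oracle(rng):
    """Spectral-radius classification vs long-run boundedness of the
    deterministic map under constant covariates."""
    n = 60
    theta = np.zeros((n, 31))
    theta[:, 1:4] = rng.uniform(-0.8, 0.8, (n, 3))     # cod row
    theta[:, 8:10] = rng.uniform(-0.8, 0.8, (n, 2))    # cap lag terms
    theta[:, 10] = rng.uniform(-0.8, 0.8, n)           # contemporaneous cod
    theta[:, 15:17] = rng.uniform(-0.8, 0.8, (n, 2))
    theta[:, 17] = rng.uniform(-0.8, 0.8, n)
    theta[:, 27:30] = 2.0
    radii = transition_radii(theta)
    keep = np.abs(radii - 1.0) > 0.01
    mask = stationarity_filter(theta)
    from trigom.inference import _structure
    B = _structure(theta)[0]
    x = np.tile(np.array([1.0, 1.0, 1.0]), (n, 1))
    bounded = np.ones(n, dtype=bool)
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(4000):
            x = np.einsum("nij,nj->ni", B, x)
            norm = np.abs(x).max(axis=1)
            bounded &= norm < 1e12
    assert np.array_equal(mask[keep], bounded[keep])


# ----------------------------------------------------- median comparison

def test_compare_medians_identity_and_scaling():
    years = np.arange(1986, 2018)
    base = np.abs(np.sin(years / 3.0)[:, None]) + np.array([[1.0, 2.0, 3.0]])
    out = compare_medians(base, base, years)
    np.testing.assert_allclose(out["slope_early"], 1.0, atol=1e-12)
    np.testing.assert_allclose(out["slope_late"], 1.0, atol=1e-12)
    np.testing.assert_allclose(out["slope_diff"], 0.0, atol=1e-12)
    scen = base.copy()
    scen[years <= 2005] *= 2.0
    out = compare_medians(base, scen, years)
    np.testing.assert_allclose(out["slope_early"], 2.0, atol=1e-12)
    np.testing.assert_allclose(out["slope_late"], 1.0, atol=1e-12)
    np.testing.assert_allclose(out["slope_diff"], 1.0, atol=1e-12)


def test_compare_medians_closed_form(rng):
    years = np.arange(1990, 2020)
    b = rng.uniform(0.5, 3.0, (30, 3))
    s = rng.uniform(0.5, 3.0, (30, 3))
    out = compare_medians(b, s, years, split_year=2004)
    early = years <= 2004
    for si in range(3):
        want = np.sum(s[early, si] * b[early, si]) / np.sum(b[early, si] ** 2)
        assert out.loc[si, "slope_early"] == pytest.approx(want, abs=1e-12)


def test_compare_medians_empty_period_errors():
    years = np.arange(1986, 1990)
    b = np.ones((4, 3))
    with pytest.raises(ValueError):
        compare_medians(b, b, years, split_year=1900)


# -------------------------------------------- full scenario construction

def test_scenario_climate_end_to_end(default32, prepared32):
    scen = scenario_climate(prepared32, default32.climate,
                            ScenarioSpec(seed=9))
    assert set(scen) >= {"ice", "ice_z", "st_z", "st", "ice_trend", "st_fit"}
    assert np.all(scen["ice"] > 0)
    # the construction anchors at the recorded first-year value, is linear
    # once the (shrunk) residual pattern is removed, and preserves that
    # pattern exactly at 70% amplitude
    ln_obs = np.log(default32.climate.ice)
    ln_scen = np.log(scen["ice"])
    trend = scen["ice_trend"]
    assert ln_scen[0] == pytest.approx(ln_obs[0], abs=1e-12)
    line_part = ln_scen[1:] - 0.7 * trend.residuals[1:]
    np.testing.assert_allclose(np.diff(line_part, 2), 0.0, atol=1e-10)
    new_slope = np.diff(line_part)[0]
    want_slope = (trend.predict(default32.climate.years[-1]) - ln_obs[0]) \
        / (default32.climate.years[-1] - default32.climate.years[0])
    assert new_slope == pytest.approx(want_slope, abs=1e-10)
    # scenario ST is (up to bootstrap noise) a negative linear map of ice
    corr = np.corrcoef(scen["st_z"], scen["ice_z"])[0, 1]
    assert corr < -0.95
    # the default fixture's anchor configuration makes this a genuine
    # low-ice scenario: below the observed series through the high-ice era
    early = slice(1, prepared32.n_years // 2)
    assert np.all(scen["ice"][early] < default32.climate.ice[early])


def test_full_pipeline_low_ice_depresses_polar_cod(small_fit, default32,
                                                   prepared32):
    """Directional smoke test: fit -> low-ice hindcast; with a positive
    generating ice effect on polar cod, the scenario's median polar-cod
    trajectory sits below the baseline in most strongly perturbed years."""
    assert default32.params.a_pcod_ice > 0
    scen = scenario_climate(prepared32, default32.climate,
                            ScenarioSpec(seed=4))
    res = hindcast(small_fit, prepared32, st_z=scen["st_z"],
                   ice_z=scen["ice_z"])
    base, scenario = res.medians(log_scale=True)
    early = res.years <= 2005
    frac_down = np.mean(scenario[early, 2] <= base[early, 2])
    assert frac_down > 0.5
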