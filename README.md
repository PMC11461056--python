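# trigom

Joint Bayesian modelling of three interacting Barents Sea fish populations
— northeast Arctic cod (*Gadus morhua*), capelin (*Mallotus villosus*) and
polar cod (*Boreogadus saida*) — and hindcast projection of their dynamics
under reduced winter sea ice.

The Arctic part of the Barents Sea is "borealizing": winter sea ice is
declining, boreal cod and capelin expand north-east, and the ice-associated
polar cod loses habitat while gaining predators and competitors. `trigom`
is for quantitative ecologists who want to (i) estimate the inter- and
intraspecific interactions of this triangle jointly from annual survey
series and (ii) ask what the historical period would have looked like under
a different climate state.

## The model

A multivariate **Gompertz state-space model** on log abundances
`x_t = (ln Cod_t, ln Cap_t, ln Pcod_t)`:

- process: each species is linear in its own lagged log abundance
  (density dependence `a_{i,i} < 1` means compensation), the other two
  species, ln herring biomass, a z-scored climate covariate (Kola-transect
  sea temperature for cod/capelin, the winter sea-ice index for polar cod)
  and a z-scored fishing index `F` (for capelin and polar cod derived as
  `−ln(1 − Landings/Biomass)`); process errors `eps_t ~ MVN(0, Sigma)`
  are correlated across species. Survey timing puts the *current-year*
  cod, herring and ice values into the capelin and polar-cod equations.
- observation: surveys observe `x_t` with independent log-scale normal
  noise; the observation variance is tied to the process variance by a
  per-species ratio with prior `Normal(2, 0.5)` (sensitivity refits at 1
  and 3 are one call away), and one anomalously low polar-cod year (1995)
  carries an extra error term.

Conditional on parameters the model is linear-Gaussian, so inference
marginalizes the latent states exactly (Kalman filter), samples the ~31
structural parameters with an ensemble MCMC sampler in independent chains,
and recovers latent states and per-year process errors exactly per draw
(forward-filter backward-sampling). The **low-ice hindcast** rebuilds the
ice series with a flattened log-linear trend (30%-shrunk residuals,
anchored at the recorded endpoints), maps it to sea temperature through the
bootstrapped ST~ice regression, re-simulates every posterior draw under the
new climate with its own process errors added back, drops draws whose
implied VAR(1) dynamics are non-stationary (spectral radius ≥ 1), and
compares scenario vs baseline median abundances by through-origin slopes
split at 2005.

Because the real survey tables live in assessment-report PDFs, the package
ships a **synthetic-data generator** that reproduces the statistical
structure of those series (declining autocorrelated ice, anti-correlated
temperature, exogenous herring/fishing, Gompertz population dynamics) with
known generating parameters, so every stage is testable end to end.
See `docs/methods.md` for the full model description and design choices.

## A worked example

```python
from trigom import (PriorConfig, SamplerConfig, ScenarioSpec, compare_medians,
                    hindcast, make_fixture, prepare_data, sample_posterior,
                    scenario_climate)

ds = make_fixture("default32")              # 32-year synthetic dataset + truth
data = prepare_data(ds.abundance, ds.climate)
draws = sample_posterior(data, PriorConfig(),
                         SamplerConfig(n_chains=2, n_iter=1500,
                                       n_burnin=500, thin=5, seed=2))
scen = scenario_climate(data, ds.climate, ScenarioSpec(seed=2))
res = hindcast(draws, data, st_z=scen["st_z"], ice_z=scen["ice_z"])
base, scenario = res.medians()
print(compare_medians(base, scenario, res.years, split_year=2005))
```

Running `python examples/03_low_ice_hindcast.py` (this code with printing)
gives:

```
observed ln(ice) trend: slope -0.0537 +/- 0.0096 per year (R^2 = 0.51)
ST ~ ice (z-scored):    slope -0.786 +/- 0.113
non-stationary draws removed: 1 / 400

through-origin slopes of scenario vs baseline median abundance
(1 = no change; the early period is where the scenario moves ice most):
species  slope_early  slope_late  slope_diff
    cod        0.380       0.759      -0.378
    cap        1.066       1.037       0.029
   pcod        0.435       0.799      -0.364
  median log-abundance shift, early years, cod       : -0.938
  median log-abundance shift, early years, capelin   : +0.191
  median log-abundance shift, early years, polar cod : -0.876
```

Read: the fitted ice trend declines ~5.4%/yr on the log scale and sea
temperature moves opposite to ice; 1 of 400 posterior draws implied
non-stationary dynamics and was excluded. A slope of 1 would mean the
scenario leaves median abundance unchanged: under low ice the polar-cod
median collapses in the strongly perturbed early era (slope 0.44, i.e. the
scenario median is less than half the baseline), capelin gains (slope
1.07, via the concomitant warming), and cod declines too — not directly
(its temperature coefficient is near zero) but through the drop of its
polar-cod prey. The effect weakens after 2005, when observed ice was
already low. On synthetic data the magnitudes track the generating
parameters, not the real Barents Sea.

The other examples: `01_simulate_dataset.py` (what the generator emulates),
`02_fit_posterior.py` (coefficient recovery and effect strengths),
`04_model_checks.py` (posterior predictive coverage, Bayesian R², prior
sensitivity). A thin CLI mirrors the pipeline:
`trigom --config run.yaml simulate|fit|diagnose|hindcast|report`.

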