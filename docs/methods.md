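# Methods

## The model

`trigom` models the joint dynamics of three interacting Barents Sea fish
populations — northeast Arctic cod (boreal predator), capelin (boreal
forage fish) and polar cod (Arctic, ice-associated forage fish) — with a
multivariate Gompertz state-space model on the natural-log abundance scale.
Writing `x_t = (ln Cod_t, ln Cap_t, ln Pcod_t)` for the *true* (latent) log
abundances:

**Process model.** Each species follows a log-linear map in its own lagged
abundance (density dependence), the other two species, ln herring biomass,
one z-scored climate covariate and a z-scored fishing index:

```
ln Cod_t  = a_cod,0  + a_cod,cod ln Cod_{t-1} + a_cod,cap ln Cap_{t-1}
          + a_cod,pcod ln Pcod_{t-1} + a_cod,her ln Her_{t-1}
          + a_cod,st ST_{t-1} + a_cod,F F_{t-1} + eps_cod,t
ln Cap_t  = a_cap,0  + a_cap,cap ln Cap_{t-1} + a_cap,pcod ln Pcod_{t-1}
          + a_cap,cod ln Cod_t + a_cap,her ln Her_t
          + a_cap,st ST_{t-1} + a_cap,F F_{t-1} + eps_cap,t
ln Pcod_t = a_pcod,0 + a_pcod,pcod ln Pcod_{t-1} + a_pcod,cap ln Cap_{t-1}
          + a_pcod,cod ln Cod_t + a_pcod,her ln Her_t
          + a_pcod,ice Ice_t + a_pcod,F F_{t-1} + eps_pcod,t
```

The *current-year* cod, herring and ice terms in the capelin and polar-cod
equations reflect survey timing: those series are measured between
successive capelin/polar-cod surveys. Sea temperature (Kola transect) drives
cod and capelin; the winter sea-ice index drives polar cod; the two are too
collinear (r ≈ −0.75) to use both in one equation. The process errors
`eps_t` are jointly trivariate normal with covariance
`Sigma_proc = diag(sigma) R diag(sigma)`, capturing correlated unmeasured
forcing.

**Observation model.** Observed log abundances are the latent values plus
independent normal noise with variance `sigma_obs,i^2`. Because process and
observation variances are not jointly identifiable from one series per
species, the observation variance is tied to the process variance through a
per-species ratio `sigma_obs,i^2 = r_i · sigma_proc,i^2` with an informative
prior `r_i ~ Normal(2, 0.5)` truncated at 0 (truncation shifts the mean by
~3·10⁻⁴; prior-sensitivity refits with centres 1 and 3 are built in). One
designated polar-cod survey year (1995 by default, an anomalously low
value) carries an extra observation SD `sigma_pcod,1995`. Missing
observations simply drop out of the likelihood; the latent process is
unbroken.

**Priors.** Coefficients `a ~ Normal(0, 5)`; `sigma_proc,i ~
half-Normal(0, 2)`; the correlation matrix `R` flat over its
positive-definite region; `sigma_pcod,1995 ~ half-Normal(0, 2)`; initial
latent state normal around the first observed log abundance per species
with SD 5. All are configurable. The exact weakly-informative choices are
this package's decisions — the approach only requires that the data
dominate them.

## Inference

Substituting the contemporaneous cod term into the capelin/polar-cod rows
turns the process model into a VAR(1), `x_t = d_t + B x_{t-1} + M eps_t`,
with `M` unit lower-triangular (unit Jacobian). Conditional on the ~31
structural parameters the model is linear-Gaussian, so the latent states
are integrated out **exactly** with a Kalman filter (scalar sequential
updates; a compiled fast path mirrors the reference numpy loop bit-for-bit
in ordering). Sampling then happens on the marginal posterior of the
parameters with an affine-invariant ensemble sampler (emcee; 80%
differential-evolution moves, 20% snooker moves), which handles the hard
constraints (positive-definite correlations, positive variance ratios) by
rejection. Scale parameters are sampled on the log scale with the Jacobian
included.

"Chains" are independent ensembles (default 64 walkers each). Retained
draws are thinned post-burn-in iterations, one walker per retained
iteration in round-robin order, so the bookkeeping
`n_chains × (n_iter − n_burnin)/thin` holds exactly (4 × (30000 −
20000)/10 = 4000 under the reference settings). Per retained parameter
draw, the latent trajectory is drawn *exactly* from its conditional
posterior by forward-filter backward-sampling, making each retained draw an
exact joint-posterior sample of (parameters, states); process errors follow
from the reconstruction identity `eps_t = x_t − gompertz_step(x_{t−1},
…)`, which holds to machine precision by construction and is verified in
tests.

**Diagnostics.** Split R-hat per parameter uses the conservative pooled
form `sqrt((W + B/n)/W)` over half-chains — never below 1, exactly 1 when
half-chains match, within O(1/n) of the classic formulation; a
rank-normalized variant is available behind a flag (cross-checked against
arviz). A fit's own diagnostics compute it per independent ensemble from
*all* walker samples (halves along the iteration axis pooled across
walkers) — the full-information form for ensemble MCMC; the retained-draw
form serves when only a posterior CSV is available (`diagnose`). Ensemble MCMC has no divergent transitions; the diagnostics report
instead carries acceptance fractions, and a fit is flagged (never silently
ignored) when max R-hat exceeds a configurable bound (default 1.05) or
acceptance collapses. Posterior predictive checks replicate observations
per draw (anomalous-year inflation included) and report 95% envelopes and
their empirical coverage. Bayesian R² is the per-draw variance-explained
ratio `Var(mu)/(Var(mu) + sigma_proc,i²)` on the process scale, where `mu`
are the Gompertz-map one-step predictions at the draw's latent states —
the model names this quantity but a definition had to be fixed here.

**Effect strengths** divide each coefficient median by the SD of its
explanatory variable so differently scaled regressors compare; z-scored
covariates (ST, ice, F) pass through unchanged. The denominator for
intercepts is not well defined and is left to the caller.

## The low-ice hindcast scenario

The hindcast re-simulates the observed window under a counterfactual
climate while preserving each draw's historically estimated "unexplained"
dynamics:

1. **Scenario ice.** OLS of ln(ice) on calendar year gives trend +
   residuals. The scenario line runs from the *recorded* first-year
   ln(ice) to the original trend's *predicted* end-year value, with its
   intercept forcing passage through the recorded end-year value; the
   original residuals, shrunk by 30% (`residual_shrink = 0.30`), are added
   back to keep the year-to-year variation pattern, and the first year is
   reset to the recorded value. The shrink is exact: residual dispersion
   about the new line is 70% of the original over non-anchored years. The
   construction is not clamped; if it fails to sit below the observed
   series in the high-ice years a validation warning is emitted.
2. **Scenario temperature.** OLS of z-scored ST on z-scored ice with
   coefficient SEs; 100 bootstrap replicates draw slope and intercept from
   normals centred at the estimates with those SEs (parameter uncertainty,
   not residual resampling — a config switch enables the latter), predict
   ST per year, and the per-year median is kept.
3. **Re-simulation.** Per posterior draw, trajectories restart from the
   draw's first-year latent state and run the Gompertz map forward under
   the scenario covariates (cod first, then capelin/polar cod given the
   newly simulated cod), adding back the draw's own process errors; herring
   and fishing stay at observed values. Scenario covariates are z-scored
   with the observed series' transforms so coefficients keep their meaning.
   With unperturbed covariates the result reproduces the baseline latent
   trajectories to machine precision — the engine's master regression test.
4. **Stationarity filter.** Draws whose implied lag-1 matrix `B = M A` has
   spectral radius ≥ 1 are removed before summarising (the standard
   stationarity criterion for a log-linear VAR; verified against a
   long-simulation boundedness oracle). The removed count is data-dependent
   and reported, never asserted.
5. **Comparison.** Per species, through-origin least-squares slopes of
   scenario vs baseline median abundance, split at 2005 (the approximate
   boundary between the high-ice era the scenario alters strongly and the
   later low-ice era), plus their difference.

## Synthetic data

The generator is the package's study-condition stand-in for the survey
tables (1986–2017 style, default T = 32): ln-linear declining ice
(slope −0.0642/yr) with AR(1) residuals (coefficient 0.3, marginal SD
0.35 — the autocorrelation magnitude is this package's choice, as is the
residual SD, picked to give visible but trend-dominated variation). The
first year's ln(ice) is pinned 0.155 above the trend's end-year value
(`ice_anchor_above_end`): the scenario line runs from this recorded start
value to the end-of-trend prediction, so the anchor configuration decides
whether the construction is a genuine low-ice perturbation at all. This
pinning gives a scenario slope of about −0.005/yr on the default window
and a scenario series below the observed one throughout the high-ice era,
which is the configuration the hindcast is designed around. ST is
linearly anti-correlated with ice (design correlation −0.75); log-AR(1)
herring and fishing series; populations simulated from the Gompertz map
with MVN process noise and log-normal observation error, using generating
coefficients representative of the system (strong positive density
dependence, negative cod effect on capelin, positive ice effect on polar
cod; stationarity enforced). Fixtures: `default32`, `tiny8`, and
`anomaly1995` (polar-cod 1995 observation drawn with inflated SD). One
master seed drives all sub-streams via spawned seed sequences.

What the generator does **not** emulate: age structure, other predators or
prey (marine mammals, zooplankton), observation-effort changes, non-linear
climate responses, and the real survey values themselves. Passing recovery
and coverage tests therefore demonstrate the *method's* correctness and
calibration under the model's own assumptions, not that the model is
adequate for the real Barents Sea series.

## Numerical choices and problem sizes

- Kalman updates are scalar-sequential per species (diagonal observation
  covariance), with covariance symmetrization each step; FFBS adds 1e-10
  jitter before Cholesky.
- Invalid parameter vectors (non-PD correlations, r ≤ 0, |log sigma| > 12)
  get log-density −inf and are rejected by the sampler.
- Degenerate inputs raise informative errors: constant series cannot be
  z-scored, landings ≥ biomass is outside the mortality proxy's domain,
  non-PD covariances are refused.
- Test-scale runs use 2–4 chains with 300–1500 iterations; the convergence
  check uses 4 chains of 128 walkers × 14000 iterations (12000 post-warmup,
  thinned by 4) on the 32-year fixture; parameter recovery uses 20
  replicates at 2 × 1200 iterations. These sizes are chosen so the full
  suite runs comfortably on one CPU while leaving clear convergence
  margins; production analyses should use the reference 4 × 30000 settings.
- Identity-type checks (hindcast under unperturbed covariates,
  process-error reconstruction) are asserted at 1e-10; density oracles at
  1e-10; exact arithmetic (retained counts, residual shrink) exactly.

## Known limitations

- At the study scale (T = 32, observation variance tied to twice the
  process variance, climate covariates collinear with the time trend),
  posterior *medians* of the density-dependence terms are noticeably
  attenuated on individual synthetic realizations — least squares on the
  true latent states misses by similar margins, so this is an
  identification limit of the data regime, not of the sampler (interval
  coverage stays near nominal). Point estimates of density dependence from
  a single 32-year series should be read with their full intervals.
- The ensemble sampler explores a 31-dimensional correlated posterior;
  short chains (as in the scaled-down tests) give usable point summaries
  but should not be used for tail quantities.
- The marginal-likelihood/FFBS scheme relies on the model being
  linear-Gaussian given parameters; adding non-linear terms would require a
  different sampler.
- Effect-strength denominators for intercepts and the non-z-scored
  log-abundance regressors depend on which SD the analyst considers
  meaningful; the API takes them as arguments rather than guessing.
- The stationarity filter classifies by the spectral radius of the mean
  dynamics; it does not test for explosive behaviour induced by covariate
  trends.
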