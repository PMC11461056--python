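"""Posterior predictive checks, Bayesian R^2 and prior sensitivity.

Model criticism for the fitted state-space model: replicate observations
from the observation model per posterior draw and compare their 95%
envelope with the data; summarise per-species variance explained on the
process scale; and refit under alternative centres of the
observation/process variance-ratio prior to see how little the
coefficients move.
"""

import numpy as np

from trigom import (PriorConfig, SamplerConfig, bayesian_r2, make_fixture,
                    posterior_predictive, prepare_data, sample_posterior)
from trigom.inference import ratio_prior_sensitivity

ds = make_fixture("tiny8")
data = prepare_data(ds.abundance, ds.climate, anomaly_year=None)
cfg = SamplerConfig(n_chains=2, n_iter=800, n_burnin=300, thin=5, seed=3)
draws = sample_posterior(data, PriorConfig(), cfg)

ppc = posterior_predictive(draws, data, np.random.default_rng(3))
print(f"95% posterior predictive envelope covers "
      f"{100 * ppc['coverage']:.0f}% of the observed log abundances")

r2 = bayesian_r2(draws, data)
for i, sp in enumerate(("cod", "capelin", "polar cod")):
    print(f"median Bayesian R^2, {sp:10s}: {np.median(r2[:, i]):.2f} "
          "(share of process-scale variance explained by the fitted map)")

print("\nrefits under variance-ratio priors centred at 1, 2 and 3")
print("(posterior coefficient medians; columns should be similar):")
table = ratio_prior_sensitivity(data, cfg, ratio_means=(1.0, 2.0, 3.0))
print(table.loc[["a_cod_cod", "a_cap_cap", "a_pcod_pcod",
                 "a_cap_cod"]].round(2).to_string())
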