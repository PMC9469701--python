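"""Compare two- vs one-compartment fits with PSIS-LOO.

Data are simulated from the two-compartment model, both candidate models
are fitted, and leave-one-out expected log predictive density decides
which generalizes better. Pareto k-hat values diagnose whether the
importance-sampling estimate can be trusted.
"""

import warnings

import numpy as np

from pmxbayes import (TwoCptParams, build_tutorial_regimen, sample_hmc,
                      simulate_dataset)
from pmxbayes.loo import elpd_compare, psis_loo
from pmxbayes.paramspace import init_from_prior
from pmxbayes.posterior import (build_pk_posterior, observed_rows,
                                pk_concentrations_batch)

warnings.filterwarnings("ignore")
truth = TwoCptParams(CL=10, Q=15, Vcent=35, Vperi=105, ka=2.0)
data = simulate_dataset(build_tutorial_regimen(), truth, sigma=0.2, seed=42)
idx, dv = observed_rows(data)

results = {}
for model in ("twocpt", "onecpt"):
    post = build_pk_posterior(data, model=model)
    draws = sample_hmc(post, n_chains=2, inits=init_from_prior(post.space, 2, 1),
                       n_warmup=500, n_sampling=500, seed=1)
    flat = draws.draws.reshape(-1, draws.draws.shape[-1])
    values = {n: flat[:, j] for j, n in enumerate(draws.names)}
    conc = pk_concentrations_batch(data, values, model)
    sigma = np.atleast_1d(values["sigma"])[:, None]
    z = np.log(dv)[None, :] - np.log(conc)
    ll = (-np.log(dv)[None, :] - np.log(sigma) - 0.5 * np.log(2 * np.pi)
          - z * z / (2 * sigma**2))
    results[model] = psis_loo(ll)
    print(f"{model}: elpd_loo = {results[model].elpd_loo:7.2f} "
          f"(se {results[model].se:.2f}), "
          f"{results[model].n_bad_k} observations with k-hat > 0.7")

diff, se = elpd_compare(results["twocpt"], results["onecpt"])
print(f"\nelpd difference (two - one): {diff:.2f} +/- {se:.2f}")
print("a difference beyond ~2 se is decisive; the data were generated by the "
      "two-compartment model, and LOO should (and does) recover that ordering")
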