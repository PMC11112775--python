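"""Run the three simulation-based sensitivity analyses at reduced size.

Each analysis perturbs the generative model on a synthetic admixed sibling
population and reports the resulting bias of the Delta-Y (model 1a) and
Delta-G (model 1b) estimators.
"""

import numpy as np

from admixsib import (
    default_sibling_data,
    sim_env_interaction,
    sim_participation_bias,
    sim_q_error,
)

sibs, pairs = default_sibling_data(n_families=200, seed=1)
print(f"population: {len(sibs)} siblings, {len(pairs)} informative pairs\n")

env = sim_env_interaction("family", e_anc_grid=[0.0, 1.0, 2.0], n_reps=5000,
                          sibs=sibs, pairs=pairs, seed=2)
print("ancestry-by-environment interaction (family level):")
print(env.table[["e_anc", "mean_dy_hat", "mean_dg_hat"]].round(3).to_string(index=False))
print("-> Delta-Y absorbs the environmental gradient; Delta-G does not.\n")

part = sim_participation_bias(threshold_quantiles=[0.5, 0.7, 0.9], n_reps=2000,
                              sibs=sibs, pairs=pairs, seed=3)
print("participation bias (high phenotype -> 20% chance of not participating):")
print(part.table[["threshold_quantile", "mean_dy_hat", "mean_dg_hat"]].round(3)
      .to_string(index=False))
print("-> |Delta-Y| is underestimated; Delta-G is nearly unbiased.\n")

qerr = sim_q_error(sigma_grid=np.linspace(0, 0.05, 6), n_reps=20_000,
                   sibs=sibs, pairs=pairs, seed=4)
print("ancestry-estimation error (per-individual N(0, sigma^2)):")
print(qerr.table[["sigma_qerror", "mean_dg_hat", "mean_abs_dq_error",
                  "predicted_attenuation"]].round(3).to_string(index=False))
print("-> classical attenuation: Delta-G shrinks by Var(dQ)/(Var(dQ)+2 sigma^2).")
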