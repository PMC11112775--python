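"""Estimate the difference in mean genotypic value (Delta-G) between ancestries.

Simulates phenotypes with a known genotypic-value difference plus a
family-correlated environmental gradient, then contrasts the three
estimators: the individual-level regression (model 1a) absorbs the
environment into its Delta-Y estimate, while the sibling-difference
regression (model 1b) and the within-family mixed model (model 2) recover
Delta-G.
"""

from admixsib import (
    PhenotypeGenConfig,
    SibPair,
    estimate_effects,
    simulate_phenotypes,
    simulate_population,
)

DG_TRUE = 1.0

pop = simulate_population(n_families=500, seed=11)
ped = pop.pedigree_frame()
off = [i.iid for i in pop.offspring]
sibs = ped.loc[off].copy()
cfg = PhenotypeGenConfig(dg=DG_TRUE, sigma=0.5, e_anc=2.0, e_anc_mode="family",
                         seed=12)
sibs = simulate_phenotypes(sibs, cfg).rename(columns={"q_true": "q"})

pairs = [SibPair(a, b) for a, b in pop.sibling_pairs()]
table = sibs.set_index("iid", drop=False)
res = estimate_effects(table, pairs, phenotypes=["y"])
print(res[["model", "n", "effect_raw", "se_raw", "p", "p_fdr"]].to_string(index=False))
print(f"\ntrue Delta-G = {DG_TRUE}; the family-level environment (E_anc = 2)")
print("inflates the 1a and 2-between (Delta-Y) estimates, while the 1b and")
print("2-within (Delta-G) estimates stay near the truth: family environment")
print("cancels in within-sibling contrasts.")
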