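# Methods

## The design

Let *G* denote the genotypic value of a phenotype — the summed effect of all
causal alleles an individual carries — and *Q* the proportion of an
individual's genome derived from ancestral population 1. Across individuals
of a two-way admixed population, the regression of phenotype on *Q* (model
1a) estimates the difference in mean phenotype value between the ancestral
populations, ΔY; this estimate absorbs every environmental exposure
correlated with ancestry. Within a pair of full siblings, however, the
expected ancestry of both siblings is the mean of their parents' ancestries,
and the realised difference *∂Q* arises purely from random recombination and
segregation, independent of the family's environment. The regression of the
within-pair phenotype difference *∂y* on *∂Q* (model 1b) therefore estimates
the difference in mean genotypic value, ΔG, robust to family-level
environmental confounding. A family random-intercept mixed model (model 2)
estimates both quantities at once — the within-family slope β_W (ΔG) and the
between-family slope β_B (ΔY) — while accounting for the correlation of
multiple sibling pairs drawn from one family.

## Generative model (simpop)

The simulator produces the data structure this design needs, with ground
truth retained at every level.

**Genetic map.** 22 autosomes with human-like lengths summing to ≈35.4
Morgans. Only the total length and its split across chromosomes matter for
the variance of *∂Q*; positions are continuous (Morgans), so tract
arithmetic is exact.

**Founders.** Each founder haplotype is a stationary admixture mosaic:
tract boundaries follow a Poisson process with rate `admix_generations` per
Morgan (default 5, a stand-in for recent admixture over a handful of
generations) and each tract's ancestry is population 1 with probability
`q_target`. Founder composition defaults to 20% unadmixed population 1, 8%
unadmixed population 2, and 72% admixed with q ~ Beta(5.68, 2.32) (mean
0.71, matching a population that is on average ~71% ancestry 1 with wide
individual variation). The mix deliberately includes unadmixed-unadmixed
and F1-producing (unadmixed × unadmixed, discordant) matings so the
downstream filters have real work to do.

**Meiosis.** Haldane model: per chromosome, crossover count ~
Poisson(length in Morgans), positions uniform, no interference, starting
haplotype fair. Each transmitted gamete records both its ancestry tracts
and its *origin* tracts (which parental haplotype each segment came from);
origin tracts are the identity-by-descent ground truth, and offspring of an
unadmixed-1 × unadmixed-2 mating have ancestry exactly 0.5 by construction.

**Genotypes.** Ancestral allele frequencies follow the Balding–Nichols
model: for a base frequency p (uniform on [0.05, 0.95]), each population's
frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F (default FST
0.12 — large enough that two-way ancestry estimation is accurate, the
regime the design requires). Founder haplotypes receive allele copies
Bernoulli(f_ancestry at locus); offspring inherit their parents' actual
alleles along the recorded crossover patterns. This allelic transmission is
what makes relatives share alleles identical by descent; simulating each
individual's alleles independently given ancestry would silently destroy
the relatedness signal.

**Phenotypes.** y_ij = α + Q_ij·ΔG + env + γ_j + β_age·Age + β_sex·Sex + ε,
with γ_j ~ N(0, σ_γ²) a family effect, ε ~ N(0, σ²), and env either
E_anc·Q̄_j (family mode: environment tracks the family's mean sibling
ancestry) or E_anc·Q_ij (individual mode). Ages are uniform 18–80 and sexes
fair coin; covariate effects default to zero — they exist to exercise the
model formulas, not to carry signal.

**What the generator does not emulate.** Linkage disequilibrium beyond
ancestry structure, genotyping error, phenotype measurement error,
assortative mating, inbreeding, X chromosome, and age/cohort structure in
ancestry. Passing tests therefore demonstrate correctness of the method
under the stated model, not robustness to every feature of real cohort
data.

## Ancestry estimation

The K=2 admixture likelihood treats genotype g_il as Binomial(2, π_il) with
π_il = q_i f1_l + (1−q_i) f2_l. The supervised estimator maximises over
q_i ∈ [0, 1] alone (bounded 1-D optimisation, tolerance 1e-10), given
frequencies. The unsupervised estimator runs block EM over all q and both
frequency vectors, accelerated by SQUAREM (each cycle: two EM steps plus an
extrapolated candidate, kept only if it improves the likelihood, then one
stabilising EM step — so the log-likelihood path is non-decreasing, which
tests assert). Frequencies are clamped to [1e-6, 1−1e-6]; convergence is a
log-likelihood gain below 1e-6 (max 2,000 cycles). Initialisation: q ~
uniform(0.2, 0.8), frequencies = perturbed sample frequencies, fixed seed.

Component labels are aligned through an anchor set of individuals of known
ancestry (the analogue of including a reference panel); without anchors the
labelling is deterministic but arbitrary (population 1 = majority) and a
warning is issued. Note that unsupervised estimation needs individuals near
both ends of the ancestry range in the sample: an offspring-only sample of
admixed families contains no unadmixed population-2 members and the
estimated scale stretches. Pipelines therefore estimate ancestry on the
full genotyped sample (founders included), mirroring cohort practice.

Variant QC removes loci with MAF < 0.05 or missingness > 0.05 and greedily
prunes one locus of any pair with r² > 0.8 in a sliding window of 50 loci,
step 5 (a PLINK-like dialect; window/step are configurable since the
convention is not unique).

## Relatedness and sibling identification

Pairwise relatedness is the MLE of (k0, k1, k2) — genome fractions sharing
0/1/2 alleles IBD — under per-locus mixture likelihoods
Σ_m k_m·P(g1, g2 | IBD=m), fitted by EM on the probability simplex (the
iterates stay on the simplex and the log-likelihood is non-decreasing; both
are tested). Admixture awareness enters through individual-specific allele
frequencies π_il = q_i f1_l + (1−q_i) f2_l in the genotype-pair
probabilities; the shared allele in the IBD=1 and IBD=2 terms uses the pair
mean (π_1+π_2)/2. This is a deliberate simplification of haplotype-level
joint ancestry/IBD models: it captures the correction that stops admixture
masquerading as relatedness, at desk scale, and within families (where
q_1 ≈ q_2) it coincides with the standard homogeneous-population model.
Estimates with fewer than 200 informative loci are refused as unstable.

Full siblings are the pairs with 0.25 < k1 < 0.75 and 0.15 < k2 < 0.5; a
boundary pair with 0.4 < k1 < 0.6 and k2 > 0.125 is rescued when both of
its members already have a primary-set sibling. Sibships are connected
components of the accepted-pair graph. Two filters then remove pairs whose
ancestry contrast is uninformative: (i) both members above 95% of the same
ancestry; (ii) both members inside a central band around Q = 0.5 (default
[0.40, 0.60], configurable) whose parents are unadmixed and discordant —
F1 pairs, whose true *∂Q* is exactly 0. Parental ancestry comes from
simulation truth or a user-supplied table; central-band pairs without
parental information default to conservative exclusion. Because every F1
sibling has true Q = 0.5, the mean |∂Q̂| over F1 pairs is a direct estimate
of the average *∂Q* estimation error (with independent N(0, σ²) errors its
expectation is 2σ/√π).

## Estimation details

Sibling order within a pair is lexicographic by id; model 1b is invariant
to the convention (tested). Sibships with more than two siblings contribute
all unordered pairs to model 1b; the induced correlation between pairs
sharing a sibling makes model 1b's OLS confidence intervals anticonservative
(measured coverage ≈0.90 at nominal 95% under the default family-size mix),
which is precisely what model 2's family random intercept repairs — the
nominal-coverage property is verified on single-pair families. Model 2 is
fitted by REML (statsmodels MixedLM); a singular or non-converging
random-effect fit falls back to the σ_γ = 0 OLS fit with a warning.

P-values are computed on rank-based inverse-normal transformed phenotypes,
z = Φ⁻¹((r − 3/8)/(n + 1/4)) (Blom offset; ties share average ranks), with
effect sizes reported from the raw-scale fit — the dual convention of the
design's results tables. Individuals are transformed first and pair
differences taken on transformed values. FDR correction is
Benjamini–Hochberg step-up across phenotypes within each model. Note that
BH re-application is not idempotent (re-adjusting adjusted values inflates
them); only monotonicity is a valid invariant. Per-phenotype inclusion
rules (e.g. treatment exclusions) are declarative boolean masks, not code.

## Sensitivity analyses

All three analyses keep a population of siblings fixed (default: a
synthetic admixed population of ≥500 informative pairs, built with the
generator's defaults and filtered by the same rules as real data) and
simulate phenotypes repeatedly.

* **Ancestry-by-environment.** Family mode adds E_anc·Q̄_j; the
  within-pair difference removes it exactly, so model 1b stays centred on
  ΔG while model 1a drifts. Individual mode adds E_anc·Q_ij, and *∂y* =
  (ΔG + E_anc)·∂Q: the bias of model 1b equals E_anc exactly in the
  noiseless limit (tested to 1e-8), and is small relative to the
  estimator's spread at realistic ∂Q variance.
* **Participation bias.** Phenotypes y ~ N(Q·ΔG, σ²); individuals above a
  quantile threshold fail to participate with probability 0.2 ("self"
  mode). Non-participants are replaced by redrawing their phenotype below
  the threshold (rejection sampling), holding individuals and pairs
  constant; both estimators are refitted. The truncation attenuates |ΔY|
  but barely moves ΔG, which uses only within-pair contrasts. In "mother"
  mode participation depends on the mother's phenotype (simulated from her
  ancestry); affected families drop out entirely, without replacement —
  replacement would be a no-op there because the mother's phenotype never
  enters the regressions.
* **Ancestry-error attenuation.** Phenotypes are generated from true Q;
  independent ε_Q ~ N(0, σ_Qerror²) is added per individual before fitting
  model 1b (a per-pair error mode is available, since error correlation
  within pairs is not identifiable from the design itself). The mean
  estimate shrinks by the classical errors-in-variables factor
  Var(∂Q)/(Var(∂Q) + 2σ_Qerror²), and the induced mean absolute ∂Q error
  (2σ_Qerror/√π) is reported per grid point so results can be indexed by
  the observable error scale. Replicates share each draw of phenotype and
  unit ancestry noise across the grid (common random numbers) and the
  slope is extracted by Frisch–Waugh–Lovell residualisation — numerically
  identical to the full OLS coefficient (asserted in tests) but cheap
  enough to run tens of thousands of replicates, which is what makes the
  attenuation curve's Monte-Carlo error small relative to the comparison
  bands. Grid values are the error SD on [0, 0.05], which brackets
  realistic ancestry-estimation error by an order of magnitude.

## Problem sizes and reproducibility

Default test and acceptance problem sizes are chosen for desk-scale runs on
one CPU: 2,000–2,500 sibling pairs for IBD expectations; 450 families
(≈650 informative pairs) for sensitivity populations; 5,000 post-QC loci,
FST 0.12 and ≈240 genotyped individuals for the end-to-end recovery run;
1,000–20,000 replicates depending on how tight the Monte-Carlo error must
be relative to the property being checked. Every stochastic routine takes
an explicit seed (numpy Generator); pipeline outputs embed the seed,
package version and a config hash, and fixed-seed runs are byte-stable.

## Known limitations

The relatedness model is a simplification of haplotype-level joint
ancestry/IBD estimators and is not calibrated for pairs with strongly
discordant ancestry; the unsupervised EM is plain (accelerated) EM, not a
quasi-Newton admixture optimiser, and needs anchors for label assignment;
phenotype models are Gaussian with linear ancestry effects only; the
simulator omits LD beyond ancestry structure, so QC's LD pruning is
exercised mainly by duplicated loci in tests; and real-data headline
estimates of the original study design (controlled-access cohort data)
are out of scope — the package reproduces the design's statistical
properties on synthetic data, not those estimates.
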