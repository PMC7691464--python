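# oakforge

**In-situ quantitative genetics of contemporary selection in mixed oak
stands.**

Naturally regenerating forests are shaped by both natural selection
(competition for light, water, nutrients) and human-mediated selection
(thinning under even-aged silviculture).  Whether those pressures produce
*heritable* phenotypic change over a single generation can be asked directly
in the field: map every adult (G1) and a systematic sample of the recruited
sapling cohort (G2) in one stand, genotype both, measure phenotypes, and
connect trait variation to realized fitness.  `oakforge` implements that
analysis pipeline for the two-species setting of European white oaks
(*Quercus petraea* and *Q. robur* growing in sympatry), together with a
fully synthetic stand generator so that every stage is testable by parameter
recovery.  It is aimed at evolutionary ecologists and forest geneticists
working with mapped, genotyped, naturally regenerating stands.

## What it computes

1. **Fitness.**  Per-adult reproductive success from sapling genotypes:
   *realized* (likelihood-based categorical parentage over an SNP panel) or
   *effective* (a spatially explicit mating model with fixed exponential
   seed/pollen dispersal kernels, fitted by a monotone EM/MM algorithm).
   Relative fitness w = RS / mean(RS) per species; its variance is the
   opportunity for selection *I*.
2. **Stand covariates.**  Hegyi competition index
   C_j = Σ_i D_i / (D_j · d_ij) within 10 m; an environment index E (first
   PC of soil/topography variables); a spatial covariate P (the PCNM
   eigenvector minimizing the AIC of a fitness regression).
3. **Phenotypic selection gradients** (Lande–Arnold):
   w = μ + C + E + P + β·x + γ·x² + ε with SD-standardized x, so β is the
   selection intensity; with no covariates β equals the selection
   differential x* − x̄.
4. **Genetic covariances and predicted responses** (Robertson–Price second
   theorem of selection): a bivariate REML animal model
   [w, x] = Xb + Za + e with a ~ N(0, G₀ ⊗ G) structured by a relatedness
   matrix — genomic (VanRaden G = (M−P)(M−P)′ / 2Σp(1−p)), pedigree
   (tabular NRM), or hybrid (genomic parents + pedigree-propagated
   offspring).  The predicted per-generation change of a trait is
   R_e = Cov(w_a, x_a), back-transformed to the data scale by exact
   lognormal closed forms when fitness is analysed on the log scale.
5. **Observed responses.**  BLUP breeding-value shifts between generations
   (univariate two-generation model with a generation fixed effect), and the
   empirical parental-fitness split: Δ% contrast of sapling phenotypes
   between offspring of top-50% and bottom-50% fitness parents.  Predicted
   and observed shifts are compared by *sign* (concordance report).

A synthetic-stand generator (`simulate_stand`) produces mapped two-species
stands, 82-SNP and dense SNP panels, dispersal-limited mating, heritable
traits genetically tied to fecundity, and a spatially autocorrelated
microenvironment — with full ground truth for recovery tests.

## Worked example

Simulate a 60-parent stand with 400 saplings, where a growth trait (named
CIRC, heritability 0.5) is genetically correlated (r = 0.6) with fecundity,
then run the pipeline:

```python
import pandas as pd
import oakforge as of

cfg = of.SimConfig(
    n_parents_per_species=30, n_snps_small=82, n_snps_large=2000,
    n_offspring=400, fecundity_cv=1.0,
    trait_specs=[of.TraitSpec("CIRC", mean=190.0, additive_variance=300.0,
                              residual_variance=300.0,
                              genetic_correlation_with_fitness=0.6)],
    rng_seed=42)
stand, snp82, snp_large, traits, env, truth = of.simulate_stand(cfg)
st = stand.set_index("tree_id")
g1 = stand.loc[stand.generation == "G1", "tree_id"]
g2 = stand.loc[stand.generation == "G2", "tree_id"]

# 1. effective fitness from the 82-SNP panel and the mapped stand
rs = of.effective_fecundities_em(
    snp82.subset(g2), snp82.subset(g1),
    st.loc[g2, ["x", "y"]].to_numpy(), st.loc[g1, ["x", "y"]].to_numpy(),
    seed_kernel_scale=15.0, pollen_kernel_scale=40.0)
fit = of.relative_fitness(rs, st["species"])

# 2. phenotypic selection gradient for CIRC (sessile oak G1)
pet = stand[(stand.generation == "G1") & (stand.species == "petraea")]
covs = of.build_covariates(pet, env, fit["w"])
g = of.fit_selection_gradient(fit["w"].loc[pet["tree_id"]],
                              traits.loc[pet["tree_id"], "CIRC"],
                              covs.table, trait_name="CIRC")

# 3. two-generation animal model: hybrid relatedness, BLUP shift
grm = of.vanraden_grm(snp_large.subset(g1))
H = of.hybrid_relatedness(grm, truth.pedigree)
blup = of.breeding_values(traits[["CIRC"]], H, st["generation"])

# 4. observed phenotypic response: parental-fitness split of the saplings
m, p, d = of.parental_split_response(traits.loc[g2, "CIRC"], fit["w"],
                                     truth.pedigree, st["species"])
```

Output:

```
opportunity for selection I per species:
petraea    0.869
robur      0.664
selection gradient beta = 0.385 (SE 0.164, p = 0.0272)
estimated h2(CIRC) = 0.42
BLUP shift G1 -> G2 = +0.25 SD (p = 0.117)
G2- mean 190.11, G2+ mean 195.10  (Delta% = 2.59)
```

Read: relative fitness is strongly dispersed (I near the upper range
reported for trees); selection on the growth trait is positive and
significant at the phenotypic level (β ≈ 0.39 SD); the REML heritability
(0.42) is close to the generating value 0.5; and both the genetic (BLUP,
+0.25 SD) and phenotypic (Δ% = +2.6) between-generation shifts agree in
sign with the planted positive fitness–trait covariance.  Note that a
bivariate fitness–trait animal model fitted on the parental generation
alone is only as informative as the variance of relatedness among those
adults — with unrelated founders the additive covariance is weakly
identified (large or undefined standard errors), the same constraint that
limits such analyses in real stands.

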