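# Methods

`oakforge` implements an in-situ quantitative-genetic analysis of contemporary
selection in a mixed, naturally regenerating oak stand (*Quercus petraea* /
*Q. robur* type setting): from a mapped two-generation stand, SNP genotypes
and phenotypes to phenotypic selection gradients, additive fitness-trait
covariances (second theorem of selection) and predicted vs observed
inter-generational responses.  This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## The synthetic stand generator

The generator is the package's definition of the study conditions; every
validation result in the test suite and acceptance battery is computed on its
output.

**Layout.** G1 parents (default 100 per species on a ~220 x 220 m plot) are
placed with mild Neyman-Scott clustering (Gaussian scatter around a few
uniformly placed centres; out-of-plot draws are resampled and near-coincident
trees jittered apart so pairwise distances stay positive).  G2 saplings sit
on a square grid of pitch 4.5 m jittered uniformly within the 3-6 m spacing
band, mirroring systematic-but-irregular field sampling of one sapling every
3-6 m.

**Mating.** A sapling's mother is drawn with probability proportional to her
female fecundity times an exponential seed kernel `exp(-d/seed_scale)`
(default scale 15 m) evaluated at the sapling site; given the mother, the
father is drawn proportional to his male fecundity times an exponential
pollen kernel (default scale 40 m) from the mother.  Mating is within
species, selfing is excluded, and there is no immigration (the config
exposes an immigration fraction fixed at 0 rather than guessing an
unreported rate).  Exponential kernels are a fixed family choice; real
dispersal kernels are often fat-tailed, and the field estimates them jointly
with fecundities — both are out of scope here, so kernel scales are always
explicit configuration, never hidden "calibrated" values.

**Genetics.** Two SNP panels are drawn with independent loci (no linkage
map): a small parentage panel (default 82 loci) and a large relatedness
panel (default 15,000), allele frequencies uniform on (0.1, 0.9), founders
at Hardy-Weinberg, offspring by Mendelian gamete sampling.  Trait
architecture is one-factor: a latent additive log-fitness value plus one
additive value per trait, with correlation loadings
`genetic_correlation_with_fitness`; two traits with loadings r1, r2 have
additive correlation r1*r2, which keeps any loading combination positive
semi-definite.  Founder breeding values are i.i.d. multivariate normal;
offspring get the mid-parent value plus Mendelian-sampling noise with half
the founder covariance (exact for non-inbred parents; inbreeding accrued in
later generations is not modelled since only two generations exist).

**Fecundity and fitness.** Log fecundity is the latent additive fitness
value plus a Gaussian residual; the additive share defaults to 0.5
(`fitness_heritability`) of the total log-variance `log(1 + CV^2)` implied by
the configured coefficient of variation (default CV = 1, a strongly skewed,
zero-inflated-looking distribution as observed for effective reproductive
success in trees).  Female and male fecundities share the additive part and
draw independent residuals; both are normalized to mean 1 within species.

**Environment.** Three smooth surfaces (sums of 10 Gaussian bumps with
length-scale `env_autocorr_range`, default 40 m) are mixed into five
ecological variables (altitude, pH, soil moisture, C/N, organic matter) with
small independent noise.  The surfaces create genuine spatial autocorrelation
but, unlike a real stand, the microenvironment is independent of the genetic
values — so simulations in which environmental and genetic effects covary
must construct that covariance explicitly (as the covariance-decomposition
tests do).

**Reproducibility.** One `rng_seed` drives eight spawned substreams in a
fixed order (layout, environment, allele frequencies, genotypes, breeding
values, fecundities, mating, trait residuals); every dataset is
bit-reproducible.

## Relatedness matrices

* **Genomic**: VanRaden's first estimator
  `G = (M-P)(M-P)'/(2 * sum p_i(1-p_i))` with genotypes recoded -1/0/1 and
  `P = 2(p_i - 0.5)`.  The recoding is fixed as dosage of the alternate
  allele; `G` is invariant to a consistent allele flip.  Allele frequencies
  default to observed sample frequencies (a `supplied` mode exists for
  recovery tests).  Missing genotypes are mean-imputed per locus;
  missingness ceilings (20% per locus and per individual) drop loci and flag
  individuals.  Monomorphic loci are dropped.  The variance of off-diagonal
  relatedness is reported because it governs the precision of REML
  (co)variances.
* **Pedigree**: classical tabular recursion, founders unrelated and
  non-inbred, self-relatedness `1 + F`.
* **Hybrid**: the parental block is the realized genomic GRM; offspring
  rows are propagated by the pedigree recursions using the genomic block as
  founder relatedness; unknown parents contribute 0.
* **Conditioning**: if the smallest eigenvalue falls below a floor (default
  1e-8) the matrix is bent by adding `floor - lambda_min` to the diagonal.
  Bending (rather than eigenvalue truncation) keeps off-diagonal entries
  exact.

## Stand covariates

Three fixed-effect covariates enter every fitness/trait model:

* **C**, the Hegyi competition index: sum over neighbours within a *closed*
  10 m ball of `D_i / (D_j * d_ij)`.  The closed-ball convention at the
  boundary is this package's documented choice; no edge correction is
  applied for trees near the plot border.
* **E**, the first principal component of the z-scored ecological variables
  (correlation-matrix PCA), sign-fixed to correlate positively with the
  first listed variable.
* **P**, a single spatial eigenvector from principal coordinates of
  neighbour matrices: distances above a threshold `t` are replaced by `4t`,
  `-D^2/2` is Gower double-centered and eigendecomposed, and positive-
  eigenvalue vectors are kept.  With the default `t` equal to the maximum
  pairwise distance the truncation is a no-op and the analysis reduces to a
  plain principal-coordinates analysis of the stand geometry (two
  eigenvectors for planar coordinates); a smaller `t` yields the richer
  classical PCNM basis.  The eigenvector minimizing the AIC of a simple
  regression of relative fitness is selected — one vector only, to avoid
  overparameterization.  AIC uses the Gaussian profile form
  `n ln(RSS/n) + 2k` with `k = 3` counting the residual variance; any
  consistent convention gives the same argmin, which is all that is used.
  Ties go to the lowest-ranked eigenvector.  Moran's I with inverse-distance
  weights (10 m cap) is provided as a diagnostic that the selected vector
  absorbs the spatial autocorrelation of fitness.

## Fitness

Adults are monoecious: reproductive success RS is the equal-weight average
of a tree's female and male components, relative fitness is `w = RS /
mean(RS)` within species, and the opportunity for selection `I = var(w)`
uses the sample (n-1) denominator, the standard convention in
opportunity-for-selection reporting.

* **Realized RS** comes from categorical parentage: every unordered
  candidate pair is scored by the Mendelian transmission likelihood over the
  shared loci; genotyping error is modelled at the gamete level (with
  probability eps the transmitted allele is a population draw), which keeps
  the pair likelihood factorizable and excludes opposing-homozygote pairs
  exactly at eps = 0.  A pair is assigned when its log-likelihood beats the
  Hardy-Weinberg "both parents unknown" background (a simplified CERVUS-like
  criterion; the threshold is configurable, default 0).
* **Effective RS** comes from a simplified spatially explicit mating model
  with *fixed* exponential kernels: sapling genotypes are a mixture over
  (mother, father) pairs weighted by fecundities and kernels.  Fecundities
  are estimated by alternating minorize-maximize updates — the EM posterior
  weights combined with a linearization of the normalizing constants (the
  standard MM treatment of Luce-type normalizers) — which makes the observed
  log-likelihood provably non-decreasing at every iteration.  Estimates are
  normalized to mean 1; boundary estimates that underflow to zero are floored
  at 1e-6 so the downstream log-fitness stays defined.  The full Bayesian
  machinery that additionally estimates kernel parameters, immigration and
  selfing is deliberately out of scope.

The log transform of fitness uses `ln(w + delta)` with `delta = 0` for
strictly positive effective fecundities; for realized counts (which contain
zeros) the recommended offset is `1/(2 * n_offspring)`.

## Selection gradients

Ordinary least squares of relative fitness on `[1, C, E, P, x_std]`
(optionally `x_std^2`), with the trait SD-standardized so beta is the
selection intensity in SD units; with no covariates beta equals the
selection differential `cov(w, x_std)/var(x_std)` exactly.  Fitness enters
untransformed by default (the linear-model definition); a `log_fitness`
flag fits ln(w) instead, since skewed fitness data are often analysed on
the log scale — both modes are exposed rather than guessing.  For quadratic
gradients both the raw `x^2` coefficient and its doubled (Stinchcombe)
value are reported because both conventions circulate.  The per-trait
screen reports unadjusted p-values plus a Benjamini-Hochberg column, skips
traits with > 50% missingness, and never imputes covariates
(complete-case analysis, logged).  Collinear designs (condition number
above 1e8) fail loudly listing the columns.

## The animal model

The (bi)variate mixed model `y = Xb + Za + e` with `a ~ N(0, G0 (x) G)`,
`e ~ N(0, R0 (x) I)` and one record per tree is estimated by REML:

* A single eigendecomposition `G = U D U'` (after PD conditioning) rotates
  the data so the restricted likelihood factorizes into per-tree 1x1 or 2x2
  blocks `d_i G0 + R0`, making each likelihood evaluation O(n).
* `(G0, R0)` are Cholesky-parameterized (log-diagonal), so estimates are PSD
  by construction; the criterion is maximized by Nelder-Mead simplex from 3
  starting additive fractions (0.25/0.5/0.75 of the OLS residual
  covariance) to dodge local optima; convergence tolerance 1e-8 on the
  criterion.  Deterministic given data.
* Fixed-effect covariates enter as measured (not re-standardized).
* Standard errors come from the numerical curvature (observed information)
  of the restricted log-likelihood at the optimum with respect to the
  covariance components; covariance significance is the Wald flag
  |estimate| > 1.96 SE.  Non-convergence and boundary estimates (a variance
  pinned near zero) are flagged, never silent.

Validated against: the closed-form ANOVA estimator on a balanced paternal
half-sib design (agreement to 1e-6 in h2 — the two parameterizations span
the same covariance family there), a dense brute-force restricted-likelihood
oracle, and parameter recovery on simulated cohorts (h2 in {0.2, 0.5, 0.8}
and a planted additive covariance of 0.3 recovered without bias within
Monte-Carlo error at n = 400, 20 replicates).

**Response prediction.**  The second theorem of selection predicts the
per-generation genetic change of a trait as its additive covariance with
relative fitness, `Re = Cov(w_a, x_a)`, reported alongside the standardized
covariance `Re / sigma_p`.  For variables analysed on the log scale, exact
lognormal closed forms back-transform means, variances and covariances to
the data scale (including the mixed lognormal-Gaussian covariance via the
Stein identity); these reproduce Monte-Carlo integrals to well under 1%.

**Breeding values.**  BLUPs at the REML estimates,
`a_hat = s2a G V^{-1}(y - Xb_gls)`, for the pooled two-generation data with
a generation fixed effect and the hybrid relatedness matrix.  Including
generation as a fixed effect absorbs part of any true genetic shift, so the
between-generation BLUP comparison (standardized scale, Welch t test) is a
conservative, qualitative indicator.  With zero additive variance all BLUPs
shrink to exactly 0.

**Covariance decomposition.**  In simulation, where the additive and
environmental components of fitness and trait are known, the phenotypic
covariance decomposes exactly into the four cross-component covariances.
This supports the diagnostic for sign conflicts between phenotypic
gradients and genetic covariances: opposite signs of the additive and
environmental terms.

## Response tables

`Re% = (G2_pred - G1) * 100 / G1` with `G2_pred = G1 + Re_data_scale`;
`Delta% = (G2+ - G2-) * 100 / mean(G2+, G2-)` where G1 parents are split at
the within-species median of observed fitness (a tree exactly at the median
goes to the bottom class) and offspring are classed by their parents'
classes.  When the two parents disagree, the default policy classes the
offspring by the mean of the parental fitness values relative to the
median; mother-only and exclusion policies are available.  The signed class
mean is kept in the Delta% denominator; for traits with negative means
(isotope compositions) the percentage's sign then opposes the raw shift's
direction, and a warning points this out — published tables for such traits
follow an absolute-denominator convention, so the built-in verification of
the published worked examples compares magnitudes there.  That verification
recomputes every published percentage cell from the printed class/generation
means and checks agreement within the propagated half-ulp rounding of the
printed inputs; 21 of the 42 recomputable cells agree exactly at two
decimals, and 12 of those are pinned in the acceptance battery.

Only the *signs* of predicted and observed responses are compared (the
concordance report): the two routes rest on different machinery and scales,
so absolute agreement is not meaningful.

## Problem sizes in the validation battery

Parameter-recovery runs use cohorts of 400 saplings from 50 parents (20
replicate seeds), a 200 x 5,000 panel for relatedness diagnostics, 1,000
null replicates at n = 200 for gradient calibration, and 1,500 saplings
from 60 parents on the 82-SNP panel for the mating model and parentage —
sizes chosen to keep Monte-Carlo error comfortably inside the stated
tolerances while the whole battery completes in minutes.

## Known limitations

* Generations are discrete and non-overlapping; no mortality process beyond
  the sampling design; no immigration or selfing.
* Loci are independent (no linkage map, no LD pruning), so marker-based
  relatedness is more informative per locus than in real panels with LD.
* The mating model fixes its dispersal kernels; misspecified kernels bias
  effective fecundities in ways the synthetic tests (which share the
  generating kernel family) do not expose.
* The environment is independent of genotype in the generator, so
  confounding of environmental and genetic effects — a central concern in
  real stands — enters only through explicitly constructed scenarios.
* Only 1- and 2-trait animal models; no dominance, maternal, or Bayesian
  variants.
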