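"""Synthetic two-species oak stand with dispersal-limited mating.

Generates complete datasets with the statistical structure the downstream
analysis assumes, together with the ground truth needed for parameter-recovery
tests:

* a mapped parental stand (G1) of two interfertile species with mild spatial
  clustering and positive stem diameters;
* two SNP panels (a small parentage panel, default 82 loci, and a large
  relatedness panel, default 15,000 loci) with Hardy-Weinberg founders and
  Mendelian transmission to offspring;
* a naturally regenerated cohort (G2) sampled on a jittered grid with one
  sapling every 3-6 m, produced by dispersal-limited mating: the mother of a
  sapling is drawn proportional to female fecundity times an exponential seed
  kernel to the sapling site, the father proportional to male fecundity times
  an exponential pollen kernel from the mother (mating within species, no
  selfing);
* heritable traits with a one-factor additive architecture tying each trait
  to a latent additive fitness value, so that fecundity is genetically
  correlated with the selected traits;
* a smooth spatially autocorrelated microenvironment (sum of Gaussian bumps)
  yielding per-tree ecological variables.

All randomness flows from a single ``rng_seed`` through a fixed
stream-splitting order (layout, environment, allele frequencies, genotypes,
breeding values, fecundities, mating, trait residuals), so every dataset is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["TraitSpec", "SimConfig", "SimTruth", "simulate_stand"]


@dataclass
class TraitSpec:
    """One heritable trait: phenotype = mean + breeding value + residual.

    ``genetic_correlation_with_fitness`` is the additive correlation between
    the trait and the latent log-fitness factor (one-factor architecture, so
    two traits with loadings r1 and r2 have additive correlation r1*r2).
    """

    name: str
    mean: float = 0.0
    additive_variance: float = 1.0
    residual_variance: float = 1.0
    genetic_correlation_with_fitness: float = 0.0

    def __post_init__(self):
        if self.additive_variance < 0 or self.residual_variance < 0:
            raise ValueError(f"trait {self.name!r}: variances must be >= 0")
        if not -1.0 <= self.genetic_correlation_with_fitness <= 1.0:
            raise ValueError(f"trait {self.name!r}: genetic correlation outside [-1, 1]")


@dataclass
class SimConfig:
    """Study conditions of the synthetic stand.

    Defaults mirror the field setting the pipeline was built for: a few
    hundred mapped parents of two species in a ~5 ha plot, an 82-SNP
    parentage panel, a large relatedness panel, offspring sampled on a
    3-6 m grid, and moderately dispersal-limited mating.
    """

    n_parents_per_species: int = 100
    plot_width: float = 220.0
    plot_height: float = 220.0
    n_snps_small: int = 82
    n_snps_large: int = 15000
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    seed_kernel_scale: float = 15.0
    pollen_kernel_scale: float = 40.0
    fecundity_cv: float = 1.0
    fitness_heritability: float = 0.5
    n_offspring: int = 1000
    sapling_spacing: tuple[float, float] = (3.0, 6.0)
    trait_specs: list[TraitSpec] = field(default_factory=lambda: [
        TraitSpec("trait1", 0.0, 0.5, 0.5, 0.6),
    ])
    env_autocorr_range: float = 40.0
    immigration_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot dimensions must be positive")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        if self.n_offspring > 0:
            if self.seed_kernel_scale <= 0:
                raise ValueError("seed_kernel_scale must be > 0 to produce offspring")
            if self.pollen_kernel_scale <= 0:
                raise ValueError("pollen_kernel_scale must be > 0 to produce offspring")
        if self.fecundity_cv < 0:
            raise ValueError("fecundity_cv must be >= 0")
        if not 0 <= self.fitness_heritability <= 1:
            raise ValueError("fitness_heritability must be in [0, 1]")
        if self.immigration_fraction != 0.0:
            raise ValueError("immigration is not modelled; immigration_fraction must be 0")
        for spec in self.trait_specs:
            if not isinstance(spec, TraitSpec):
                raise ValueError("trait_specs entries must be TraitSpec")


@dataclass
class SimTruth:
    """Ground truth of one simulated stand."""

    breeding_values: pd.DataFrame       # index tree_id; latent 'fitness' + traits
    fecundity_female: pd.Series         # per G1 parent, unit mean within species
    fecundity_male: pd.Series
    pedigree: pd.DataFrame              # tree_id, mother_id, father_id (G2 rows)
    additive_covariance: pd.DataFrame   # traits x traits incl. latent fitness
    config: SimConfig


def _parent_positions(rng, n, width, height, min_sep=0.5):
    """Neyman-Scott style mild clustering: Gaussian scatter around a few centres.

    Out-of-plot draws are resampled (not clipped, which would pile trees up on
    the border), and near-coincident trees are jittered apart so pairwise
    distances stay positive for the competition index.
    """
    n_centres = max(3, n // 25)
    centres = rng.uniform([0, 0], [width, height], size=(n_centres, 2))
    which = rng.integers(0, n_centres, size=n)
    sd = 0.18 * min(width, height)
    xy = np.empty((n, 2))
    todo = np.arange(n)
    for _ in range(200):
        xy[todo] = centres[which[todo]] + rng.normal(0.0, sd, size=(len(todo), 2))
        inside = ((xy[todo, 0] >= 0) & (xy[todo, 0] <= width)
                  & (xy[todo, 1] >= 0) & (xy[todo, 1] <= height))
        todo = todo[~inside]
        if len(todo) == 0:
            break
    else:
        xy[todo] = rng.uniform([0, 0], [width, height], size=(len(todo), 2))
    for _ in range(50):
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        close = np.unique(np.argwhere(d < min_sep)[:, 1])
        close = close[close > 0]
        if len(close) == 0:
            break
        xy[close] += rng.uniform(-min_sep, min_sep, size=(len(close), 2))
        xy[close] = np.clip(xy[close], [0, 0], [width, height])
    return xy


def _gaussian_bump_surface(rng, width, height, length_scale, n_bumps=10):
    centres = rng.uniform([0, 0], [width, height], size=(n_bumps, 2))
    amps = rng.normal(0.0, 1.0, size=n_bumps)

    def surface(xy):
        d2 = ((xy[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        return (amps * np.exp(-d2 / (2.0 * length_scale ** 2))).sum(axis=1)

    return surface


def _additive_covariance(cfg: SimConfig) -> pd.DataFrame:
    """One-factor additive covariance across [latent fitness, traits]."""
    names = ["fitness"] + [t.name for t in cfg.trait_specs]
    sd = np.array([np.sqrt(cfg.fitness_heritability * np.log1p(cfg.fecundity_cv ** 2))]
                  + [np.sqrt(t.additive_variance) for t in cfg.trait_specs])
    load = np.array([1.0] + [t.genetic_correlation_with_fitness for t in cfg.trait_specs])
    corr = np.outer(load, load)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sd, sd)
    return pd.DataFrame(cov, index=names, columns=names)


def _draw_genotypes(rng, n, freqs):
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(float)


def _mendelian_gametes(rng, parent_dosage):
    """One gamete per locus from a 0/1/2 parent (independent loci)."""
    het = parent_dosage == 1
    gam = (parent_dosage / 2.0).astype(float)
    gam[het] = rng.integers(0, 2, size=het.sum())
    return gam


def simulate_stand(config: SimConfig):
    """Generate one synthetic stand.

    Returns
    -------
    stand : pandas.DataFrame
        tree_id, species, generation, x, y, dbh.
    geno_small, geno_large : GenotypeMatrix
        Parentage and relatedness SNP panels (all trees; panels share trees
        but not loci).
    traits : pandas.DataFrame
        tree_id plus one column per trait.
    env : pandas.DataFrame
        tree_id plus altitude, pH, soil_moisture, CN_ratio, organic_matter.
    truth : SimTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    (r_layout, r_env, r_freq, r_geno, r_bv,
     r_fec, r_mating, r_resid) = rng.spawn(8)

    species = ["petraea", "robur"]
    n_par = 2 * cfg.n_parents_per_species

    # --- G1 layout ------------------------------------------------------
    xy = np.vstack([_parent_positions(r_layout, cfg.n_parents_per_species,
                                      cfg.plot_width, cfg.plot_height)
                    for _ in species])
    sp = np.repeat(species, cfg.n_parents_per_species)
    dbh = np.exp(r_layout.normal(np.log(40.0), 0.25, size=n_par))  # cm
    g1_ids = [f"G1_{i:04d}" for i in range(n_par)]

    # --- environment ----------------------------------------------------
    surfaces = [_gaussian_bump_surface(r_env, cfg.plot_width, cfg.plot_height,
                                       cfg.env_autocorr_range) for _ in range(3)]

    def env_table(xy_all, ids):
        s = np.column_stack([f(xy_all) for f in surfaces])
        noise = r_env.normal(0, 0.3, size=(len(ids), 5))
        cols = {
            "altitude": 120.0 + 5.0 * s[:, 0] + noise[:, 0],
            "pH": 5.5 + 0.3 * s[:, 1] + 0.1 * s[:, 0] + 0.1 * noise[:, 1],
            "soil_moisture": 30.0 + 4.0 * s[:, 2] + noise[:, 2],
            "CN_ratio": 15.0 + 2.0 * s[:, 1] - 1.0 * s[:, 2] + 0.5 * noise[:, 3],
            "organic_matter": 8.0 + 1.5 * s[:, 0] + 0.5 * s[:, 2] + 0.3 * noise[:, 4],
        }
        return pd.DataFrame(cols, index=pd.Index(ids, name="tree_id"))

    # --- SNP panels (G1) ------------------------------------------------
    lo, hi = cfg.allele_freq_range
    p_small = r_freq.uniform(lo, hi, size=cfg.n_snps_small)
    p_large = r_freq.uniform(lo, hi, size=cfg.n_snps_large)
    g1_small = _draw_genotypes(r_geno, n_par, p_small)
    g1_large = _draw_genotypes(r_geno, n_par, p_large)

    # --- breeding values (founders iid; offspring by Mendelian sampling) -
    Sigma_A = _additive_covariance(cfg)
    L = np.linalg.cholesky(Sigma_A.to_numpy() + 1e-12 * np.eye(len(Sigma_A)))
    bv_g1 = r_bv.normal(size=(n_par, len(Sigma_A))) @ L.T

    # --- fecundities ----------------------------------------------------
    sigma2_log = np.log1p(cfg.fecundity_cv ** 2)
    sigma2_e = (1.0 - cfg.fitness_heritability) * sigma2_log
    a_w = bv_g1[:, 0]
    fec = {}
    for sex, r in (("female", r_fec), ("male", r_fec)):
        e_w = r.normal(0.0, np.sqrt(sigma2_e), size=n_par)
        raw = np.exp(a_w + e_w)
        f = raw.copy()
        for s in species:
            m = sp == s
            f[m] = raw[m] / raw[m].mean()      # unit mean within species
        fec[sex] = f
    fec_f, fec_m = fec["female"], fec["male"]

    # --- G2 sapling sites: jittered grid, one sapling per 3-6 m ---------
    lo_sp, hi_sp = cfg.sapling_spacing
    pitch = 0.5 * (lo_sp + hi_sp)
    gx = np.arange(pitch / 2, cfg.plot_width, pitch)
    gy = np.arange(pitch / 2, cfg.plot_height, pitch)
    grid = np.array([(a, b) for a in gx for b in gy])
    jit_r = r_mating.uniform(0.0, (hi_sp - lo_sp) / 2.0, size=len(grid))
    jit_t = r_mating.uniform(0, 2 * np.pi, size=len(grid))
    grid = grid + np.column_stack([jit_r * np.cos(jit_t), jit_r * np.sin(jit_t)])
    grid = np.clip(grid, [0, 0], [cfg.plot_width, cfg.plot_height])
    if cfg.n_offspring > len(grid):
        raise ValueError(
            f"n_offspring={cfg.n_offspring} exceeds the {len(grid)} sapling grid "
            "sites; enlarge the plot or reduce n_offspring")
    sites = grid[r_mating.choice(len(grid), size=cfg.n_offspring, replace=False)]

    # --- mating ---------------------------------------------------------
    d_site_par = np.sqrt(((sites[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    d_par_par = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    seed_k = np.exp(-d_site_par / cfg.seed_kernel_scale)
    pollen_k = np.exp(-d_par_par / cfg.pollen_kernel_scale)

    # species of each sapling follows the local seed-rain mixture
    mothers = np.empty(cfg.n_offspring, dtype=int)
    fathers = np.empty(cfg.n_offspring, dtype=int)
    w_mother = fec_f[None, :] * seed_k                     # (n_off, n_par)
    for s_i in range(cfg.n_offspring):
        wm = w_mother[s_i]
        mothers[s_i] = r_mating.choice(n_par, p=wm / wm.sum())
        same_sp = sp == sp[mothers[s_i]]
        wf = fec_m * pollen_k[mothers[s_i]] * same_sp
        wf[mothers[s_i]] = 0.0                             # no selfing
        fathers[s_i] = r_mating.choice(n_par, p=wf / wf.sum())

    g2_ids = [f"G2_{i:04d}" for i in range(cfg.n_offspring)]

    def offspring_panel(parent_geno):
        out = np.empty((cfg.n_offspring, parent_geno.shape[1]))
        for i, (m, f) in enumerate(zip(mothers, fathers)):
            out[i] = (_mendelian_gametes(r_geno, parent_geno[m])
                      + _mendelian_gametes(r_geno, parent_geno[f]))
        return out

    g2_small = offspring_panel(g1_small)
    g2_large = offspring_panel(g1_large)

    mend = r_bv.normal(size=(cfg.n_offspring, len(Sigma_A))) @ (L.T / np.sqrt(2.0))
    bv_g2 = 0.5 * (bv_g1[mothers] + bv_g1[fathers]) + mend

    # --- assemble -------------------------------------------------------
    all_ids = g1_ids + g2_ids
    stand = pd.DataFrame({
        "tree_id": all_ids,
        "species": np.concatenate([sp, sp[mothers]]),
        "generation": ["G1"] * n_par + ["G2"] * cfg.n_offspring,
        "x": np.concatenate([xy[:, 0], sites[:, 0]]),
        "y": np.concatenate([xy[:, 1], sites[:, 1]]),
        "dbh": np.concatenate([dbh, np.full(cfg.n_offspring, 8.0)]),
    })

    bv_all = np.vstack([bv_g1, bv_g2])
    bv = pd.DataFrame(bv_all, index=pd.Index(all_ids, name="tree_id"),
                      columns=list(Sigma_A.columns))
    traits = {}
    for j, spec_t in enumerate(cfg.trait_specs, start=1):
        resid = r_resid.normal(0.0, np.sqrt(spec_t.residual_variance),
                               size=len(all_ids))
        traits[spec_t.name] = spec_t.mean + bv_all[:, j] + resid
    trait_tab = pd.DataFrame(traits, index=pd.Index(all_ids, name="tree_id"))

    geno_small = GenotypeMatrix(
        pd.DataFrame(np.vstack([g1_small, g2_small]), index=pd.Index(all_ids),
                     columns=[f"S{j}" for j in range(cfg.n_snps_small)]),
        allele_freqs=pd.Series(p_small, index=[f"S{j}" for j in range(cfg.n_snps_small)]))
    geno_large = GenotypeMatrix(
        pd.DataFrame(np.vstack([g1_large, g2_large]), index=pd.Index(all_ids),
                     columns=[f"L{j}" for j in range(cfg.n_snps_large)]),
        allele_freqs=pd.Series(p_large, index=[f"L{j}" for j in range(cfg.n_snps_large)]))

    env = env_table(np.vstack([xy, sites]), all_ids)
    pedigree = pd.DataFrame({
        "tree_id": g2_ids,
        "mother_id": [g1_ids[m] for m in mothers],
        "father_id": [g1_ids[f] for f in fathers],
    })
    truth = SimTruth(
        breeding_values=bv,
        fecundity_female=pd.Series(fec_f, index=pd.Index(g1_ids, name="tree_id")),
        fecundity_male=pd.Series(fec_m, index=pd.Index(g1_ids, name="tree_id")),
        pedigree=pedigree,
        additive_covariance=Sigma_A,
        config=cfg,
    )
    return stand, geno_small, geno_large, trait_tab, env, truth
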