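"""Per-parent reproductive success and relative fitness.

Two routes to reproductive success are provided:

* **realized** — categorical parentage: each sampled sapling is assigned the
  maximum-likelihood parent pair over all candidate pairs, with a gamete-level
  genotyping-error allowance; assignments are counted per parent.
* **effective** — a simplified spatially explicit mating model: sapling
  genotypes and locations are explained by a mixture over (mother, father)
  pairs weighted by per-parent fecundities and fixed exponential seed and
  pollen dispersal kernels.  The female and male fecundities are estimated by
  a block minorize-maximize (EM-style) algorithm whose observed-data
  log-likelihood is non-decreasing at every iteration.

Adults are monoecious: every adult is a candidate mother and father, and a
tree's reproductive success is the equal-weight average of its female and
male components.  Relative fitness is reproductive success divided by the
within-species mean, so mean(w) = 1 per species; its variance is the
opportunity for selection I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "pair_genotype_loglik",
    "ParentageAssigner",
    "categorical_parentage",
    "MatingModelEM",
    "effective_fecundities_em",
    "relative_fitness",
]


def _transmission_probs(parent_dosage: np.ndarray, freqs: np.ndarray,
                        error_rate: float):
    """P(transmitted allele = 0/1) per parent x locus, with gamete error.

    With probability ``error_rate`` the recorded gamete is a random draw from
    the population allele pool instead of a faithful Mendelian transmission.
    """
    t1 = (1.0 - error_rate) * parent_dosage / 2.0 + error_rate * freqs[None, :]
    return 1.0 - t1, t1


def pair_genotype_loglik(offspring: GenotypeMatrix, parents: GenotypeMatrix,
                         error_rate: float = 0.0):
    """Log-likelihood of each offspring genotype given each ordered parent pair.

    Returns ``(loglik, bg_loglik)`` where ``loglik`` has shape
    ``(n_offspring, n_parents, n_parents)`` and ``bg_loglik`` is the
    "both parents unknown" Hardy-Weinberg background log-likelihood per
    offspring.  Impossible pairs (opposing homozygotes at ``error_rate = 0``)
    get ``-inf``.
    """
    shared = offspring.dosages.columns.intersection(parents.dosages.columns)
    if len(shared) == 0:
        raise ValueError("offspring and parent panels share no locus")
    G_off = offspring.dosages[shared].to_numpy(dtype=float)
    G_par = parents.dosages[shared].to_numpy(dtype=float)
    p = parents.freqs()[shared].to_numpy(dtype=float)

    T0, T1 = _transmission_probs(G_par, p, error_rate)
    with np.errstate(divide="ignore"):
        l0, l1 = np.log(T0), np.log(T1)

    n_off, n_par = G_off.shape[0], G_par.shape[0]
    out = np.empty((n_off, n_par, n_par))
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    with np.errstate(divide="ignore"):
        log_hwe = np.log(hwe)
    bg = np.array([log_hwe[G_off[s].astype(int), np.arange(G_off.shape[1])].sum()
                   for s in range(n_off)])

    for s in range(n_off):
        g = G_off[s]
        hom0, het, hom2 = g == 0, g == 1, g == 2
        sep = l0[:, hom0].sum(axis=1) + l1[:, hom2].sum(axis=1)   # per parent
        L = sep[:, None] + sep[None, :]
        if het.any():
            a0, a1 = T0[:, het], T1[:, het]
            with np.errstate(divide="ignore"):
                L = L + np.log(a0[:, None, :] * a1[None, :, :]
                               + a1[:, None, :] * a0[None, :, :]).sum(axis=2)
        out[s] = L
    return out, bg


def _opposing_homozygote_counts(G_off, G_par, pair):
    m, f = pair
    g, gm, gf = G_off, G_par[m], G_par[f]
    conflict = ((g == 0) & ((gm == 2) & (gf == 2))) | ((g == 2) & ((gm == 0) & (gf == 0)))
    # single-parent conflicts: offspring homozygous, one candidate opposite hom
    single = (((g == 0) & ((gm == 2) | (gf == 2))) | ((g == 2) & ((gm == 0) | (gf == 0))))
    return int(single.sum()), int(conflict.sum())


class ParentageAssigner(BaseEstimator):
    """Likelihood-based categorical parentage over an SNP panel.

    For each offspring every unordered candidate pair (selfing excluded) is
    scored by the Mendelian transmission likelihood with genotyping-error
    allowance; the best pair is assigned when its log-likelihood exceeds the
    Hardy-Weinberg "both parents unknown" background by more than
    ``lod_threshold`` (natural-log units).

    Attributes
    ----------
    assignments_ : pandas.DataFrame
        offspring_id, mother_id, father_id (None when unassigned), LOD score
        and opposing-homozygote mismatch count of the assigned pair.
    """

    def __init__(self, error_rate: float = 0.01, lod_threshold: float = 0.0,
                 max_mismatches: int | None = None):
        self.error_rate = error_rate
        self.lod_threshold = lod_threshold
        self.max_mismatches = max_mismatches

    def fit(self, offspring: GenotypeMatrix, parents: GenotypeMatrix
            ) -> "ParentageAssigner":
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        ll, bg = pair_genotype_loglik(offspring, parents, self.error_rate)
        n_off, n_par = ll.shape[:2]
        shared = offspring.dosages.columns.intersection(parents.dosages.columns)
        G_off = offspring.dosages[shared].to_numpy(dtype=float)
        G_par = parents.dosages[shared].to_numpy(dtype=float)
        idx = np.arange(n_par)
        rows = []
        for s in range(n_off):
            L = ll[s].copy()
            L[idx, idx] = -np.inf                       # no selfing
            best = np.unravel_index(np.argmax(L), L.shape)
            lod = L[best] - bg[s]
            _, mism = _opposing_homozygote_counts(G_off[s], G_par, best)
            ok = np.isfinite(L[best]) and lod > self.lod_threshold
            if ok and self.max_mismatches is not None:
                ok = mism <= self.max_mismatches
            rows.append({
                "offspring_id": offspring.ids[s],
                "mother_id": parents.ids[best[0]] if ok else None,
                "father_id": parents.ids[best[1]] if ok else None,
                "lod": float(lod) if np.isfinite(lod) else -np.inf,
                "n_mismatches": mism,
            })
        self.assignments_ = pd.DataFrame(rows)
        return self

    def reproductive_success(self, parents: GenotypeMatrix) -> pd.DataFrame:
        """Realized RS per parent: assignments credit one female and one male slot."""
        asg = self.assignments_.dropna(subset=["mother_id"])
        female = asg["mother_id"].value_counts()
        male = asg["father_id"].value_counts()
        out = pd.DataFrame({
            "RS_female": female.reindex(parents.ids).fillna(0.0),
            "RS_male": male.reindex(parents.ids).fillna(0.0),
        })
        out.index.name = "tree_id"
        return out


def categorical_parentage(offspring_geno: GenotypeMatrix,
                          parent_geno: GenotypeMatrix,
                          error_rate: float = 0.01, **kwargs) -> pd.DataFrame:
    """Assign maximum-likelihood parent pairs; see :class:`ParentageAssigner`."""
    return ParentageAssigner(error_rate=error_rate, **kwargs).fit(
        offspring_geno, parent_geno).assignments_


class MatingModelEM(BaseEstimator):
    """Effective fecundities under a fixed-kernel spatially explicit mating model.

    The sapling at site ``y`` draws its mother ``j`` with probability
    proportional to ``f_j * exp(-d(j, y)/seed_scale)`` and, given the mother,
    its father ``k != j`` with probability proportional to
    ``m_k * exp(-d(j, k)/pollen_scale)``.  The observed data are the sapling
    genotypes; fecundities ``f`` and ``m`` are estimated by alternating
    minorize-maximize updates (the EM posterior weights combined with a
    linearization of the normalizing constants), which makes the observed
    log-likelihood non-decreasing at every iteration.  Estimates are
    normalized to mean 1 (the model is scale-invariant).

    Attributes
    ----------
    fec_female_, fec_male_ : pandas.Series   unit-mean effective fecundities
    loglik_trace_ : ndarray                  observed log-likelihood per iteration
    converged_ : bool
    """

    def __init__(self, seed_kernel_scale: float = 15.0,
                 pollen_kernel_scale: float = 40.0, error_rate: float = 0.01,
                 tol: float = 1e-6, max_iter: int = 500,
                 fecundity_floor: float = 1e-6):
        self.seed_kernel_scale = seed_kernel_scale
        self.pollen_kernel_scale = pollen_kernel_scale
        self.error_rate = error_rate
        self.tol = tol
        self.max_iter = max_iter
        self.fecundity_floor = fecundity_floor

    def fit(self, offspring: GenotypeMatrix, parents: GenotypeMatrix,
            offspring_coords, parent_coords) -> "MatingModelEM":
        if self.seed_kernel_scale <= 0 or self.pollen_kernel_scale <= 0:
            raise ValueError("kernel scales must be positive")
        ll, _ = pair_genotype_loglik(offspring, parents, self.error_rate)
        n_off, n_par = ll.shape[:2]
        shift = ll.max(axis=(1, 2), keepdims=True)
        Pg = np.exp(ll - shift)                      # scaled genotype likelihoods
        base = shift[:, 0, 0]

        A = np.exp(-cdist(np.asarray(offspring_coords, float),
                          np.asarray(parent_coords, float)) / self.seed_kernel_scale)
        B = np.exp(-cdist(np.asarray(parent_coords, float),
                          np.asarray(parent_coords, float)) / self.pollen_kernel_scale)
        np.fill_diagonal(B, 0.0)                     # no selfing

        f = np.ones(n_par)
        m = np.ones(n_par)
        trace = []
        prev = -np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            mB = m[None, :] * B                      # (j, k)
            E = mB.sum(axis=1)                       # pollen normalizer per mother
            R = np.einsum("jk,sjk->sj", mB / E[:, None], Pg)   # father-marginalized
            fA = f[None, :] * A
            D = fA.sum(axis=1)
            U = fA / D[:, None] * R                  # joint weight over mothers
            Ls = U.sum(axis=1)
            trace.append(float(np.sum(np.log(Ls) + base)))
            if it > 0 and trace[-1] - prev < self.tol:
                self.converged_ = True
                prev = trace[-1]
                break
            prev = trace[-1]

            W = U / Ls[:, None]                      # posterior P(mother = j | s)
            # MM update for f: linearize log sum_j f_j A_sj
            f_new = W.sum(axis=0) / (A / D[:, None]).sum(axis=0)
            # MM update for m with posterior pair weights
            S = np.einsum("sj,sjk->jk", W / np.maximum(R, 1e-300), Pg)  # (j, k)
            num = (S * mB / E[:, None]).sum(axis=0)
            den = (W.sum(axis=0)[:, None] * B / E[:, None]).sum(axis=0)
            m_new = num / np.maximum(den, 1e-300)
            f = f_new / f_new.mean()
            m = m_new / m_new.mean()
        else:
            logger.warning("mating-model EM did not converge in %d iterations",
                           self.max_iter)

        self.n_iter_ = len(trace)
        self.loglik_trace_ = np.asarray(trace)
        # boundary estimates can underflow to 0; a tiny floor keeps the
        # downstream log-fitness defined without affecting the fit
        f = np.maximum(f, self.fecundity_floor)
        m = np.maximum(m, self.fecundity_floor)
        self.fec_female_ = pd.Series(f / f.mean(), index=parents.ids, name="RS_female")
        self.fec_male_ = pd.Series(m / m.mean(), index=parents.ids, name="RS_male")
        return self


def effective_fecundities_em(offspring_geno: GenotypeMatrix,
                             parent_geno: GenotypeMatrix,
                             offspring_coords, parent_coords,
                             seed_kernel_scale: float = 15.0,
                             pollen_kernel_scale: float = 40.0,
                             **kwargs) -> pd.DataFrame:
    """Effective female/male fecundities per parent; see :class:`MatingModelEM`."""
    em = MatingModelEM(seed_kernel_scale=seed_kernel_scale,
                       pollen_kernel_scale=pollen_kernel_scale, **kwargs
                       ).fit(offspring_geno, parent_geno, offspring_coords, parent_coords)
    out = pd.DataFrame({"RS_female": em.fec_female_, "RS_male": em.fec_male_})
    out.index.name = "tree_id"
    return out


def relative_fitness(rs: pd.DataFrame, species: pd.Series | None = None,
                     delta: float = 0.0) -> pd.DataFrame:
    """Relative fitness table from female/male reproductive success.

    ``RS = (RS_female + RS_male) / 2``; ``w = RS / mean(RS)`` within each
    species group (so mean(w) = 1 per group); ``I = var(w)`` with the sample
    (n-1) denominator is the opportunity for selection; ``log_w = ln(w +
    delta)``.  ``delta`` stays 0 for strictly positive effective fecundities;
    for realized counts pass e.g. ``1 / (2 * n_offspring)``.
    """
    if (rs[["RS_female", "RS_male"]] < 0).to_numpy().any():
        raise ValueError("reproductive success must be >= 0")
    out = rs.copy()
    out["RS"] = 0.5 * (out["RS_female"] + out["RS_male"])
    grp = species.reindex(out.index) if species is not None else pd.Series("all", index=out.index)
    out["species"] = grp
    out["w"] = out["RS"] / out.groupby("species")["RS"].transform("mean")
    if ((out["w"] + delta) <= 0).any():
        raise ValueError("w + delta <= 0 for some tree; set a positive delta "
                         "(e.g. 1/(2*n_offspring) for realized counts)")
    out["log_w"] = np.log(out["w"] + delta)
    out["I"] = out.groupby("species")["w"].transform(lambda v: v.var(ddof=1))
    return out
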