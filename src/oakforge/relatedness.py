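"""Additive-relationship matrices: genomic (VanRaden), pedigree, hybrid.

The genomic matrix follows VanRaden's first estimator,

    G = (M - P)(M - P)' / (2 * sum_i p_i (1 - p_i)),

where ``M`` holds genotypes recoded -1/0/1 (homozygote / heterozygote /
alternative homozygote, i.e. dosage - 1) and ``P`` repeats ``2(p_i - 0.5)``
per locus.  The pedigree matrix is the classical tabular (recursive) numerator
relationship matrix.  The hybrid matrix, used for two-generation animal
models, keeps the realized genomic block among the parental generation and
propagates relatedness to the offspring generation through the parentage
pedigree, treating the genomic block as founder relatedness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix, RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VanRadenGRM",
    "vanraden_grm",
    "pedigree_nrm",
    "hybrid_relatedness",
    "condition_matrix",
]


class VanRadenGRM(BaseEstimator, TransformerMixin):
    """Genomic relatedness estimator (VanRaden method 1).

    Parameters
    ----------
    freq_source : {"observed", "supplied"}
        Whether allele frequencies come from the sample itself or from the
        :class:`GenotypeMatrix`'s ``allele_freqs`` (useful in parameter-
        recovery settings where the generating frequencies are known).
    max_missing_locus, max_missing_individual : float
        Missingness ceilings; loci above the ceiling are dropped, individuals
        above it are flagged in ``flagged_individuals_`` (never silently
        removed).

    Attributes
    ----------
    grm_ : RelatednessMatrix
        The fitted genomic relationship matrix.
    n_loci_used_ : int
        Polymorphic loci retained after filtering.
    dropped_loci_ : list
        Monomorphic or high-missingness loci removed before computation.
    """

    def __init__(self, freq_source: str = "observed",
                 max_missing_locus: float = 0.2,
                 max_missing_individual: float = 0.2):
        self.freq_source = freq_source
        self.max_missing_locus = max_missing_locus
        self.max_missing_individual = max_missing_individual

    def fit(self, X: GenotypeMatrix, y=None) -> "VanRadenGRM":
        if X.n_individuals < 2:
            raise ValueError("need at least two individuals for a GRM")
        dos = X.dosages
        miss_ind = dos.isna().mean(axis=1)
        self.flagged_individuals_ = list(miss_ind.index[miss_ind > self.max_missing_individual])
        if self.flagged_individuals_:
            logger.warning("individuals above missingness ceiling: %s",
                           self.flagged_individuals_)

        miss_loc = dos.isna().mean(axis=0)
        keep = miss_loc <= self.max_missing_locus
        if self.freq_source == "supplied":
            if X.allele_freqs is None:
                raise ValueError("freq_source='supplied' but no allele_freqs given")
            p = X.allele_freqs.copy()
        elif self.freq_source == "observed":
            p = X.observed_freqs()
        else:
            raise ValueError(f"unknown freq_source {self.freq_source!r}")
        poly = (p > 0) & (p < 1)
        keep &= poly
        self.dropped_loci_ = list(dos.columns[~keep])
        if self.dropped_loci_:
            logger.info("dropping %d monomorphic/high-missing loci", len(self.dropped_loci_))
        if not keep.any():
            raise ValueError("all loci monomorphic or filtered; cannot build GRM")

        dos = dos.loc[:, keep]
        p = p[keep].to_numpy(dtype=float)
        arr = dos.to_numpy(dtype=float)
        # mean imputation on the dosage scale (2p per locus), then recode
        nanmask = np.isnan(arr)
        if nanmask.any():
            arr = np.where(nanmask, 2.0 * p, arr)
        M = arr - 1.0
        P = 2.0 * (p - 0.5)
        Z = M - P
        denom = 2.0 * np.sum(p * (1.0 - p))
        G = Z @ Z.T / denom

        off = G[np.triu_indices_from(G, k=1)]
        self.n_loci_used_ = int(keep.sum())
        self.grm_ = RelatednessMatrix(
            G, X.ids, provenance="genomic",
            offdiag_variance=float(np.var(off, ddof=1)) if off.size > 1 else 0.0,
            meta={"n_loci": self.n_loci_used_, "denominator": denom},
        )
        return self

    def transform(self, X: GenotypeMatrix) -> RelatednessMatrix:
        return self.fit(X).grm_


def vanraden_grm(geno: GenotypeMatrix, freq_source: str = "observed",
                 **kwargs) -> RelatednessMatrix:
    """Compute the VanRaden genomic relationship matrix.  See :class:`VanRadenGRM`."""
    return VanRadenGRM(freq_source=freq_source, **kwargs).fit(geno).grm_


def _check_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    ped = pedigree.copy()
    for col in ("tree_id", "mother_id", "father_id"):
        if col not in ped.columns:
            raise ValueError(f"pedigree must have column {col!r}")
    if ped["tree_id"].duplicated().any():
        dup = ped.loc[ped["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise ValueError(f"duplicated pedigree record for {dup!r}")
    return ped


def pedigree_nrm(pedigree: pd.DataFrame) -> RelatednessMatrix:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` has columns tree_id, mother_id, father_id; unknown parents
    are NaN/None.  Records must be ordered (or orderable) parents-first;
    founders are assumed unrelated and non-inbred.  Additive relationship of
    an individual with itself is ``1 + F`` (F = inbreeding coefficient).
    """
    ped = _check_pedigree(pedigree)
    ids = list(ped["tree_id"])
    idx = {t: i for i, t in enumerate(ids)}

    def parent_pos(v, child):
        if pd.isna(v) or v is None or v == "":
            return -1
        if v not in idx:
            raise ValueError(f"unknown parent id {v!r} for {child!r}")
        return idx[v]

    mothers = np.empty(len(ids), dtype=int)
    fathers = np.empty(len(ids), dtype=int)
    for i, (t, m, f) in enumerate(zip(ped["tree_id"], ped["mother_id"], ped["father_id"])):
        mothers[i], fathers[i] = parent_pos(m, t), parent_pos(f, t)
        if mothers[i] >= i or fathers[i] >= i:
            raise ValueError(f"pedigree not parents-first at record {t!r} "
                             "(parent appears at or after offspring; cycles included)")

    A = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        m, f = mothers[i], fathers[i]
        amf = A[m, f] if (m >= 0 and f >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * amf
        for j in range(i):
            a = 0.0
            if m >= 0:
                a += 0.5 * A[j, m]
            if f >= 0:
                a += 0.5 * A[j, f]
            A[i, j] = A[j, i] = a
    return RelatednessMatrix(A, pd.Index(ids), provenance="pedigree")


def hybrid_relatedness(grm_g1: RelatednessMatrix,
                       pedigree: pd.DataFrame) -> RelatednessMatrix:
    """Two-generation relatedness: genomic among parents, pedigree-propagated beyond.

    The parental (G1) block is the realized genomic GRM.  Offspring rows are
    added by the standard recursions with the genomic block as founder
    relatedness::

        a(o, z) = 0.5 * [a(mother, z) + a(father, z)]
        a(o, o) = 1 + 0.5 * a(mother, father)

    Unknown parents contribute 0.  ``pedigree`` lists only offspring records
    (tree_id, mother_id, father_id); parents must be in ``grm_g1`` or NaN.
    """
    ped = _check_pedigree(pedigree)
    g1_ids = list(grm_g1.ids)
    g1_set = set(g1_ids)
    off_ids = list(ped["tree_id"])
    if set(off_ids) & g1_set:
        clash = (set(off_ids) & g1_set).pop()
        raise ValueError(f"offspring id {clash!r} already present in the G1 matrix")
    ids = g1_ids + off_ids
    idx = {t: i for i, t in enumerate(ids)}
    n1, n = len(g1_ids), len(ids)

    A = np.zeros((n, n))
    A[:n1, :n1] = grm_g1.values
    for row in ped.itertuples(index=False):
        i = idx[row.tree_id]
        par = []
        for v in (row.mother_id, row.father_id):
            if pd.isna(v) or v is None or v == "":
                par.append(-1)
            elif v in idx:
                p = idx[v]
                if p >= i:
                    raise ValueError(f"pedigree not parents-first at {row.tree_id!r}")
                par.append(p)
            else:
                raise ValueError(f"parent {v!r} of {row.tree_id!r} not in G1 matrix "
                                 "or earlier offspring")
        m, f = par
        prev = A[:i, :]
        a_row = np.zeros(i)
        if m >= 0:
            a_row += 0.5 * prev[:, m][:i]
        if f >= 0:
            a_row += 0.5 * prev[:, f][:i]
        A[i, :i] = a_row
        A[:i, i] = a_row
        amf = A[m, f] if (m >= 0 and f >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * amf
    return RelatednessMatrix(A, pd.Index(ids), provenance="hybrid")


def condition_matrix(G: RelatednessMatrix, eps: float = 1e-8) -> RelatednessMatrix:
    """Bend ``G`` to be positive definite: add ``eps - lambda_min`` to the diagonal.

    Off-diagonal entries are untouched (bending rather than eigenvalue
    truncation).  Returns the input unchanged when already PD above ``eps``.
    """
    lam = G.min_eigenvalue()
    if lam >= eps:
        return G
    shift = eps - lam
    V = G.values.copy()
    V[np.diag_indices_from(V)] += shift
    logger.info("bending relatedness matrix: min eigenvalue %.3g -> %.3g", lam, eps)
    return RelatednessMatrix(V, G.ids, G.provenance, bending_applied=True,
                             offdiag_variance=G.offdiag_variance, meta=dict(G.meta))
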