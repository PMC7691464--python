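"""Fixed-effect covariates for the fitness and animal models.

Three per-tree covariates enter every model in the pipeline:

* ``C`` — Hegyi competition index: distance-weighted sum of neighbour-to-focal
  diameter ratios within a 10 m radius.
* ``E`` — environment index: score on the first principal component of the
  standardized ecological variables (altitude, pH, soil moisture, C/N ratio,
  organic matter).
* ``P`` — spatial index: the single PCNM (principal coordinates of neighbour
  matrices) eigenvector whose fitness regression minimizes AIC, used to soak
  up spatial autocorrelation of fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "hegyi_index",
    "EnvironmentPCA",
    "environment_index",
    "PCNM",
    "pcnm_eigenvectors",
    "select_spatial_covariate",
    "morans_i",
    "CovariateTable",
    "build_covariates",
]


def hegyi_index(stand: pd.DataFrame, radius: float = 10.0) -> pd.Series:
    """Hegyi competition index per tree.

    ``C_j = sum_{i in neighbourhood} D_i / (D_j * Dist_ij)`` over the closed
    ball of ``radius`` metres around tree ``j`` (boundary trees included).
    Trees with no neighbour get 0.  Coincident coordinates are an error: the
    index is undefined at distance 0.
    """
    if (stand["dbh"] <= 0).any():
        bad = stand.loc[stand["dbh"] <= 0, "tree_id"].iloc[0]
        raise ValueError(f"non-positive dbh for tree {bad!r}")
    xy = stand[["x", "y"]].to_numpy(dtype=float)
    D = stand["dbh"].to_numpy(dtype=float)
    dist = cdist(xy, xy)
    np.fill_diagonal(dist, np.inf)
    if (dist == 0).any():
        j, i = np.argwhere(dist == 0)[0]
        raise ValueError("coincident coordinates for trees "
                         f"{stand['tree_id'].iloc[j]!r} and {stand['tree_id'].iloc[i]!r}")
    within = dist <= radius
    with np.errstate(divide="ignore"):
        contrib = np.where(within, D[None, :] / dist, 0.0)
    C = contrib.sum(axis=1) / D
    return pd.Series(C, index=pd.Index(stand["tree_id"]), name="C")


class EnvironmentPCA(BaseEstimator, TransformerMixin):
    """First-principal-component environment index on standardized variables.

    Correlation-matrix PCA: each ecological variable is z-scored before the
    decomposition, so the index is unit-free.  Constant variables are dropped
    with a warning.  The component sign is fixed so that the index correlates
    positively with the first retained variable.

    Attributes
    ----------
    scores_ : pandas.Series    first-PC score per tree (mean 0)
    explained_ratio_ : float   share of variance carried by the first PC
    loadings_ : pandas.Series  variable loadings of the first PC
    """

    def fit(self, X: pd.DataFrame, y=None) -> "EnvironmentPCA":
        if X.shape[0] < 3:
            raise ValueError("need at least 3 trees for a PCA")
        sd = X.std(ddof=1)
        constant = sd[sd == 0].index
        if len(constant):
            logger.warning("dropping constant environmental variables: %s", list(constant))
        X = X.drop(columns=constant)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 non-constant environmental variables")
        Z = (X - X.mean()) / X.std(ddof=1)
        pca = PCA(n_components=min(Z.shape)).fit(Z.to_numpy())
        scores = Z.to_numpy() @ pca.components_[0]
        # orient: positive correlation with the first listed variable
        r = np.corrcoef(scores, Z.iloc[:, 0])[0, 1]
        sign = -1.0 if r < 0 else 1.0
        self.columns_ = list(X.columns)
        self.loadings_ = pd.Series(sign * pca.components_[0], index=X.columns)
        self.scores_ = pd.Series(sign * scores, index=X.index, name="E")
        self.explained_ratio_ = float(pca.explained_variance_ratio_[0])
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        Z = (X[self.columns_] - X[self.columns_].mean()) / X[self.columns_].std(ddof=1)
        return pd.Series(Z.to_numpy() @ self.loadings_.to_numpy(), index=X.index, name="E")


def environment_index(env_vars: pd.DataFrame) -> pd.Series:
    """First-PC environment index ``E``; see :class:`EnvironmentPCA`."""
    return EnvironmentPCA().fit(env_vars).scores_


class PCNM(BaseEstimator, TransformerMixin):
    """Principal coordinates of neighbour matrices (spatial eigenvectors).

    Pairwise distances above the truncation threshold ``t`` are replaced by
    ``4 t`` before Gower double-centering of ``-D**2 / 2`` and
    eigendecomposition.  With ``t`` equal to the maximum pairwise distance
    (the default) the truncation is a no-op and the analysis reduces to a
    principal-coordinates analysis of the stand geometry.  Only eigenvectors
    with eigenvalue above ``tol * max(eigenvalue)`` are kept, sorted by
    decreasing eigenvalue; they are centered and mutually orthogonal by
    construction.

    Attributes
    ----------
    eigenvectors_ : ndarray (n, k)
    eigenvalues_ : ndarray (k,)
    """

    def __init__(self, t: float | None = None, tol: float = 1e-9):
        self.t = t
        self.tol = tol

    def fit(self, X, y=None) -> "PCNM":
        coords = np.asarray(X, dtype=float)
        n = coords.shape[0]
        if n < 3:
            raise ValueError("need at least 3 points")
        D = squareform(pdist(coords))
        t = self.t if self.t is not None else float(D.max())
        self.t_ = t
        D = np.where(D > t, 4.0 * t, D)
        A = -0.5 * D ** 2
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        G = J @ A @ J
        G = 0.5 * (G + G.T)
        lam, vec = np.linalg.eigh(G)
        lam, vec = lam[::-1], vec[:, ::-1]
        keep = lam > self.tol * max(lam.max(), 1.0)
        if not keep.any():
            raise ValueError("no positive PCNM eigenvalue")
        self.eigenvalues_ = lam[keep]
        self.eigenvectors_ = vec[:, keep]
        return self

    def transform(self, X=None) -> np.ndarray:
        return self.eigenvectors_


def pcnm_eigenvectors(coords, t: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Spatial eigenvectors and eigenvalues; see :class:`PCNM`."""
    m = PCNM(t=t).fit(coords)
    return m.eigenvectors_, m.eigenvalues_


def _gaussian_aic(y: np.ndarray, X: np.ndarray, k: int) -> float:
    # profile-likelihood Gaussian AIC: n ln(RSS/n) + 2k
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return n * np.log(rss / n) + 2 * k


def select_spatial_covariate(w, eigvecs: np.ndarray):
    """Pick the single PCNM eigenvector minimizing the AIC of ``w ~ 1 + v``.

    Fits one simple linear regression of relative fitness per eigenvector;
    AIC uses the Gaussian profile form ``n ln(RSS/n) + 2k`` with ``k = 3``
    (intercept, slope, residual variance).  Ties go to the lowest-rank
    eigenvector.  Returns ``(P, rank, aic_trace)``.
    """
    w = np.asarray(w, dtype=float)
    n, m = eigvecs.shape
    if len(w) != n:
        raise ValueError("fitness vector and eigenvectors are not aligned")
    trace = np.array([
        _gaussian_aic(w, np.column_stack([np.ones(n), eigvecs[:, j]]), k=3)
        for j in range(m)
    ])
    rank = int(np.argmin(trace))          # argmin takes the first on ties
    if (trace == trace[rank]).sum() > 1:
        logger.info("AIC tie among eigenvectors; keeping lowest rank %d", rank)
    return eigvecs[:, rank].copy(), rank, trace


def morans_i(values, coords, max_dist: float = 10.0) -> float:
    """Moran's I with inverse-distance weights capped at ``max_dist`` metres.

    Diagnostic only (used to verify that regressing out the selected spatial
    eigenvector removes the spatial autocorrelation of fitness).
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    D = squareform(pdist(np.asarray(coords, dtype=float)))
    with np.errstate(divide="ignore"):
        W = np.where((D > 0) & (D <= max_dist), 1.0 / D, 0.0)
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("no pair within max_dist; cannot compute Moran's I")
    n = len(z)
    return float(n / s0 * (z @ W @ z) / (z @ z))


@dataclass
class CovariateTable:
    """Per-tree fixed-effect covariates C, E, P plus selection metadata."""

    table: pd.DataFrame                 # index tree_id; columns C, E, P
    pcnm_rank: int
    aic_trace: np.ndarray = field(repr=False, default=None)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("tree_id").to_csv(path, sep="\t")


def build_covariates(stand: pd.DataFrame, env_vars: pd.DataFrame,
                     fitness: pd.Series, radius: float = 10.0) -> CovariateTable:
    """Assemble the C/E/P covariate table for one species' trees.

    ``stand`` rows, ``env_vars`` rows and ``fitness`` must share tree_id
    (env_vars indexed by tree_id, fitness a Series indexed by tree_id).
    """
    ids = pd.Index(stand["tree_id"])
    C = hegyi_index(stand, radius=radius)
    E = environment_index(env_vars.loc[ids])
    vecs, _ = pcnm_eigenvectors(stand[["x", "y"]].to_numpy())
    P, rank, trace = select_spatial_covariate(fitness.loc[ids].to_numpy(), vecs)
    tab = pd.DataFrame({"C": C.to_numpy(), "E": E.to_numpy(), "P": P}, index=ids)
    return CovariateTable(tab, rank, trace)
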