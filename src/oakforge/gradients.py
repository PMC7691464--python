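"""Univariate phenotypic selection gradients (Lande-Arnold regressions).

Relative fitness is regressed on one SD-standardized trait at a time,
alongside the stand covariates::

    w = mu + C + E + P + beta * x_std (+ gamma * x_std**2) + eps

``beta`` is the linear selection gradient in phenotypic-SD units; because the
trait is standardized, with no covariates it equals the selection
differential (the within-generation shift of the standardized trait mean).
For quadratic fits both the raw ``x**2`` coefficient and its doubled
(Stinchcombe-corrected) value are reported, since either convention appears
in the literature.

Fitness enters untransformed by default; a ``log_fitness`` flag fits the
same model on ln(w) for comparability with analyses that log-transform
skewed fitness data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GradientFit", "SelectionGradientModel", "fit_selection_gradient",
           "gradient_screen"]

_COND_CEILING = 1e8


@dataclass
class GradientFit:
    """Result of one trait-by-species selection-gradient regression."""

    trait: str
    beta: float
    se_beta: float
    p_beta: float
    gamma: float | None
    gamma_doubled: float | None
    p_gamma: float | None
    n: int
    trait_mean: float
    trait_sd: float
    species: str | None = None
    coefficients: pd.DataFrame = field(default=None, repr=False)


class SelectionGradientModel(BaseEstimator):
    """OLS estimator of univariate linear/quadratic selection gradients.

    Parameters
    ----------
    quadratic : bool
        Also fit the squared standardized trait and report the quadratic
        gradient.
    log_fitness : bool
        Regress ln(w) instead of w (requires w > 0).
    """

    def __init__(self, quadratic: bool = False, log_fitness: bool = False):
        self.quadratic = quadratic
        self.log_fitness = log_fitness

    def fit(self, trait, w, covariates: pd.DataFrame | None = None,
            trait_name: str = "trait", species: str | None = None
            ) -> "SelectionGradientModel":
        x = np.asarray(trait, dtype=float)
        y = np.asarray(w, dtype=float)
        cov = (covariates.to_numpy(dtype=float)
               if covariates is not None else np.empty((len(y), 0)))
        cov_names = list(covariates.columns) if covariates is not None else []
        ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
        x, y, cov = x[ok], y[ok], cov[ok]
        if len(y) < 10:
            raise ValueError("need at least 10 complete cases")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("trait has zero variance")
        xs = (x - x.mean()) / sd
        if self.log_fitness:
            if (y <= 0).any():
                raise ValueError("log_fitness requires strictly positive w")
            y = np.log(y)

        cols = [np.ones(len(y))] + [cov[:, j] for j in range(cov.shape[1])] + [xs]
        names = ["mu"] + cov_names + ["x"]
        if self.quadratic:
            cols.append(xs ** 2)
            names.append("x2")
        X = np.column_stack(cols)
        cond = np.linalg.cond(X)
        if cond > _COND_CEILING:
            corr = np.corrcoef(X[:, 1:], rowvar=False)
            raise ValueError(
                f"collinear design (condition number {cond:.3g}); "
                f"columns {names[1:]}, correlations:\n{np.round(corr, 3)}")

        res = sm.OLS(y, X).fit()
        tab = pd.DataFrame({"estimate": res.params, "se": res.bse,
                            "p": res.pvalues}, index=names)
        g = tab.loc["x2"] if self.quadratic else None
        self.result_ = res
        self.fit_ = GradientFit(
            trait=trait_name,
            beta=float(tab.loc["x", "estimate"]),
            se_beta=float(tab.loc["x", "se"]),
            p_beta=float(tab.loc["x", "p"]),
            gamma=float(g["estimate"]) if g is not None else None,
            gamma_doubled=2.0 * float(g["estimate"]) if g is not None else None,
            p_gamma=float(g["p"]) if g is not None else None,
            n=int(len(y)),
            trait_mean=float(x.mean()),
            trait_sd=float(sd),
            species=species,
            coefficients=tab,
        )
        return self


def fit_selection_gradient(w, x, covs: pd.DataFrame | None = None,
                           quadratic: bool = False, log_fitness: bool = False,
                           trait_name: str = "trait",
                           species: str | None = None) -> GradientFit:
    """Fit one univariate selection gradient; see :class:`SelectionGradientModel`."""
    return SelectionGradientModel(quadratic=quadratic, log_fitness=log_fitness
                                  ).fit(x, w, covs, trait_name, species).fit_


def gradient_screen(traits: pd.DataFrame, w: pd.Series,
                    covs: pd.DataFrame | None = None,
                    species: pd.Series | None = None,
                    quadratic: bool = False, log_fitness: bool = False,
                    max_missing: float = 0.5) -> pd.DataFrame:
    """Per-trait (and per-species) selection-gradient screen.

    Returns a tidy table with one row per trait x species: beta, SE, p, the
    quadratic terms when requested, and a Benjamini-Hochberg adjusted p
    column (``p_beta_bh``) alongside the unadjusted values.
    Traits with more than ``max_missing`` missingness in a group are skipped.
    """
    grp = (species.reindex(traits.index) if species is not None
           else pd.Series("all", index=traits.index))
    rows = []
    for sp_name, sub in traits.groupby(grp):
        w_sub = w.reindex(sub.index)
        c_sub = covs.reindex(sub.index) if covs is not None else None
        for trait in sub.columns:
            col = sub[trait]
            if col.isna().mean() > max_missing:
                logger.info("skipping %s/%s: >%d%% missing", sp_name, trait,
                            int(100 * max_missing))
                continue
            try:
                f = fit_selection_gradient(w_sub, col, c_sub, quadratic=quadratic,
                                           log_fitness=log_fitness,
                                           trait_name=trait, species=sp_name)
            except ValueError as e:
                logger.info("skipping %s/%s: %s", sp_name, trait, e)
                continue
            rows.append({"species": sp_name, "trait": trait, "beta": f.beta,
                         "se_beta": f.se_beta, "p_beta": f.p_beta,
                         "gamma": f.gamma, "gamma_doubled": f.gamma_doubled,
                         "p_gamma": f.p_gamma, "n": f.n})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_beta_bh"] = np.nan
        for sp_name, idx in out.groupby("species").groups.items():
            out.loc[idx, "p_beta_bh"] = multipletests(
                out.loc[idx, "p_beta"], method="fdr_bh")[1]
    return out
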