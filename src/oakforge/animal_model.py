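"""REML animal models with a relatedness-structured additive effect.

The model for one or two response columns (e.g. relative fitness ``w`` and a
trait ``x``) on ``n`` trees is::

    y = X b + Z a + e,   a ~ N(0, G0 (x) G),   e ~ N(0, R0 (x) I)

with one record per tree (``Z = I``), fixed effects ``X`` (intercept plus the
stand covariates, plus generation for two-generation fits), ``G`` a
relatedness matrix (genomic, pedigree or hybrid) and ``G0``/``R0`` the 2x2 (or
scalar) additive and residual covariance blocks.  The additive covariance
between relative fitness and a trait, ``Cov(w_a, x_a)``, is the
Robertson-Price (second theorem of selection) prediction of the
per-generation genetic change of the trait.

Estimation maximizes the restricted log-likelihood over Cholesky-parameterized
``(G0, R0)``.  A single eigendecomposition ``G = U D U'`` rotates the data so
the restricted likelihood factorizes over trees (2x2 blocks ``d_i G0 + R0``),
making each evaluation O(n); the optimizer is a multi-start Nelder-Mead
simplex.  Standard errors come from the curvature (observed information) of
the restricted log-likelihood at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .containers import RelatednessMatrix
from .relatedness import condition_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarCompEstimate", "RemlAnimalModel", "reml_fit",
    "ResponsePrediction", "sts_response",
    "lognormal_mean", "lognormal_cov", "lognormal_gaussian_cov",
    "lognormal_backtransform",
    "BlupResult", "breeding_values", "covariance_decomposition",
]


# --------------------------------------------------------------------------
# restricted likelihood machinery
# --------------------------------------------------------------------------

def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower Cholesky factor from log-diag parameterization (q = 1 or 2)."""
    if q == 1:
        return np.array([[np.exp(theta[0])]])
    L = np.zeros((2, 2))
    L[0, 0] = np.exp(theta[0])
    L[1, 0] = theta[1]
    L[1, 1] = np.exp(theta[2])
    return L


def _theta_from_cov(C: np.ndarray) -> np.ndarray:
    q = C.shape[0]
    L = np.linalg.cholesky(C + 1e-10 * np.eye(q))
    if q == 1:
        return np.array([np.log(L[0, 0])])
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _neg2_restricted_loglik(G0, R0, d, Yt, Xt):
    """-2 * restricted log-likelihood (constant dropped), O(n) per call.

    ``d`` are the eigenvalues of G; ``Yt`` (n x q) and ``Xt`` (n x p) the
    eigen-rotated responses and fixed-effect design.
    """
    n, q = Yt.shape
    p = Xt.shape[1]
    if q == 1:
        v = d * G0[0, 0] + R0[0, 0]
        if np.any(v <= 0):
            return np.inf
        iv = 1.0 / v
        C = (Xt * iv[:, None]).T @ Xt
        rhs = (Xt * iv[:, None]).T @ Yt[:, 0]
        try:
            cho = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return np.inf
        b = np.linalg.solve(C, rhs)
        r = Yt[:, 0] - Xt @ b
        logdetC = 2.0 * np.log(np.diag(cho)).sum()
        return float(np.log(v).sum() + logdetC + (r * r * iv).sum())

    # bivariate: per-tree 2x2 covariance V_i = d_i G0 + R0
    a = d * G0[0, 0] + R0[0, 0]
    b2 = d * G0[0, 1] + R0[0, 1]
    c = d * G0[1, 1] + R0[1, 1]
    det = a * c - b2 * b2
    if np.any(det <= 0) or np.any(a <= 0):
        return np.inf
    ia, ib, ic = c / det, -b2 / det, a / det
    # C = [[sum ia x x', sum ib x x'], [sum ib x x', sum ic x x']]
    C11 = (Xt * ia[:, None]).T @ Xt
    C12 = (Xt * ib[:, None]).T @ Xt
    C22 = (Xt * ic[:, None]).T @ Xt
    C = np.block([[C11, C12], [C12, C22]])
    y1, y2 = Yt[:, 0], Yt[:, 1]
    rhs = np.concatenate([
        Xt.T @ (ia * y1 + ib * y2),
        Xt.T @ (ib * y1 + ic * y2),
    ])
    try:
        cho = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(C, rhs)
    r1 = y1 - Xt @ beta[:p]
    r2 = y2 - Xt @ beta[p:]
    quad = (ia * r1 * r1 + 2 * ib * r1 * r2 + ic * r2 * r2).sum()
    logdetC = 2.0 * np.log(np.diag(cho)).sum()
    return float(np.log(det).sum() + logdetC + quad)


def _pack_cov(G0, R0, q):
    if q == 1:
        return np.array([G0[0, 0], R0[0, 0]])
    return np.array([G0[0, 0], G0[0, 1], G0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])


def _unpack_cov(v, q):
    if q == 1:
        return np.array([[v[0]]]), np.array([[v[1]]])
    G0 = np.array([[v[0], v[1]], [v[1], v[2]]])
    R0 = np.array([[v[3], v[4]], [v[4], v[5]]])
    return G0, R0


@dataclass
class VarCompEstimate:
    """REML variance components of a (bi)variate animal model."""

    G0: pd.DataFrame                  # additive covariance block
    R0: pd.DataFrame                  # residual covariance block
    se_G0: pd.DataFrame
    se_R0: pd.DataFrame
    loglik: float                     # restricted log-likelihood (-0.5 * crit)
    converged: bool
    boundary: bool
    n: int
    n_iter: int
    responses: list[str]
    fixed_effects: pd.DataFrame | None = field(default=None, repr=False)
    method: str = "reml-cholesky-simplex"

    @property
    def heritability(self) -> pd.Series:
        g = np.diag(self.G0.to_numpy())
        r = np.diag(self.R0.to_numpy())
        return pd.Series(g / (g + r), index=self.responses, name="h2")


class RemlAnimalModel(BaseEstimator):
    """REML estimator for the additive-effect mixed model described above.

    Parameters
    ----------
    n_starts : int
        Multi-start count for the simplex search (starting additive fractions
        spread over (0, 1) to dodge local optima).
    tol : float
        Relative convergence tolerance on -2*restricted-log-likelihood.
    eig_floor : float
        Eigenvalue floor used to condition ``G`` before rotation.

    Attributes (fitted)
    -------------------
    varcomp_ : VarCompEstimate
    """

    def __init__(self, n_starts: int = 3, tol: float = 1e-8,
                 max_iter: int = 20000, eig_floor: float = 1e-8):
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.eig_floor = eig_floor

    def fit(self, responses: pd.DataFrame, G: RelatednessMatrix,
            fixed: pd.DataFrame | None = None) -> "RemlAnimalModel":
        Y = responses.dropna()
        ids = Y.index
        n, q = Y.shape
        if q not in (1, 2):
            raise ValueError("1 or 2 response columns required")
        if n < 30:
            raise ValueError("need at least 30 complete records")
        Gs = condition_matrix(G.reindex(ids), self.eig_floor)
        d, U = np.linalg.eigh(Gs.values)
        d = np.maximum(d, self.eig_floor)

        if fixed is not None:
            Xf = fixed.reindex(ids).to_numpy(dtype=float)
            X = np.column_stack([np.ones(n), Xf])
        else:
            X = np.ones((n, 1))
        Yt = U.T @ Y.to_numpy(dtype=float)
        Xt = U.T @ X

        # moment starting values from the OLS residual covariance
        bols, *_ = np.linalg.lstsq(X, Y.to_numpy(dtype=float), rcond=None)
        Sp = np.atleast_2d(np.cov((Y.to_numpy(dtype=float) - X @ bols).T, ddof=1))
        fracs = np.linspace(0.25, 0.75, self.n_starts)

        def objective(theta):
            G0 = _chol_from_theta(theta[: len(theta) // 2], q)
            R0 = _chol_from_theta(theta[len(theta) // 2:], q)
            return _neg2_restricted_loglik(G0 @ G0.T, R0 @ R0.T, d, Yt, Xt)

        best = None
        n_iter = 0
        for h in fracs:
            t0 = np.concatenate([_theta_from_cov(h * Sp), _theta_from_cov((1 - h) * Sp)])
            res = optimize.minimize(
                objective, t0, method="Nelder-Mead",
                options={"fatol": self.tol, "xatol": 1e-10,
                         "maxiter": self.max_iter, "maxfev": self.max_iter})
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        Lg = _chol_from_theta(theta[: len(theta) // 2], q)
        Lr = _chol_from_theta(theta[len(theta) // 2:], q)
        G0, R0 = Lg @ Lg.T, Lr @ Lr.T
        crit = best.fun
        converged = bool(best.success and np.isfinite(crit))

        tot = np.trace(G0) + np.trace(R0)
        boundary = bool(min(np.diag(G0).min(), np.diag(R0).min()) < 1e-6 * tot)
        if not converged:
            logger.warning("REML did not converge (criterion %.6g)", crit)

        se = self._information_se(G0, R0, d, Yt, Xt, q)
        names = list(Y.columns)
        mk = lambda M: pd.DataFrame(M, index=names, columns=names)
        b_hat = self._gls_fixed(G0, R0, d, Yt, Xt, q, U, X, Y)
        self.varcomp_ = VarCompEstimate(
            G0=mk(G0), R0=mk(R0), se_G0=mk(se[0]), se_R0=mk(se[1]),
            loglik=-0.5 * crit, converged=converged, boundary=boundary,
            n=n, n_iter=n_iter, responses=names, fixed_effects=b_hat)
        self._rotation_ = (d, U, ids, X)
        return self

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _gls_fixed(G0, R0, d, Yt, Xt, q, U, X, Y):
        if q == 1:
            iv = 1.0 / (d * G0[0, 0] + R0[0, 0])
            C = (Xt * iv[:, None]).T @ Xt
            b = np.linalg.solve(C, (Xt * iv[:, None]).T @ Yt[:, 0])
            se = np.sqrt(np.diag(np.linalg.inv(C)))
            return pd.DataFrame({"estimate": b, "se": se})
        a = d * G0[0, 0] + R0[0, 0]
        b2 = d * G0[0, 1] + R0[0, 1]
        c = d * G0[1, 1] + R0[1, 1]
        det = a * c - b2 * b2
        ia, ib, ic = c / det, -b2 / det, a / det
        C = np.block([
            [(Xt * ia[:, None]).T @ Xt, (Xt * ib[:, None]).T @ Xt],
            [(Xt * ib[:, None]).T @ Xt, (Xt * ic[:, None]).T @ Xt]])
        y1, y2 = Yt[:, 0], Yt[:, 1]
        rhs = np.concatenate([Xt.T @ (ia * y1 + ib * y2), Xt.T @ (ib * y1 + ic * y2)])
        bb = np.linalg.solve(C, rhs)
        se = np.sqrt(np.diag(np.linalg.inv(C)))
        return pd.DataFrame({"estimate": bb, "se": se})

    @staticmethod
    def _information_se(G0, R0, d, Yt, Xt, q):
        """SEs from the numerical curvature of -2lR w.r.t. the components."""
        v0 = _pack_cov(G0, R0, q)
        scale = np.maximum(np.abs(v0), 1e-3 * max(np.trace(G0) + np.trace(R0), 1e-8))
        h = 1e-4 * scale

        def f(v):
            g, r = _unpack_cov(v, q)
            return _neg2_restricted_loglik(g, r, d, Yt, Xt)

        k = len(v0)
        H = np.full((k, k), np.nan)
        f0 = f(v0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    val = (f(v0 + ei) - 2 * f0 + f(v0 - ei)) / h[i] ** 2
                else:
                    val = (f(v0 + ei + ej) - f(v0 + ei - ej)
                           - f(v0 - ei + ej) + f(v0 - ei - ej)) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        H *= 0.5  # information of lR, not -2lR
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        if q == 1:
            return np.array([[se[0]]]), np.array([[se[1]]])
        seG = np.array([[se[0], se[1]], [se[1], se[2]]])
        seR = np.array([[se[3], se[4]], [se[4], se[5]]])
        return seG, seR


def reml_fit(responses: pd.DataFrame, G: RelatednessMatrix,
             fixed: pd.DataFrame | None = None, **kwargs) -> VarCompEstimate:
    """REML variance components; see :class:`RemlAnimalModel`."""
    return RemlAnimalModel(**kwargs).fit(responses, G, fixed).varcomp_


# --------------------------------------------------------------------------
# second-theorem response prediction and scale back-transformation
# --------------------------------------------------------------------------

@dataclass
class ResponsePrediction:
    """Predicted per-generation genetic change of one trait (Robertson-Price)."""

    trait: str
    Re: float                  # Cov(w_a, x_a) on the analysis scale
    se_Re: float
    st_cov_a: float            # Re / phenotypic SD of the trait
    significant: bool
    converged: bool
    Re_data_scale: float | None = None


def sts_response(fit: VarCompEstimate, trait_sd: float,
                 fitness_col: str | None = None,
                 Re_data_scale: float | None = None) -> ResponsePrediction:
    """Second-theorem-of-selection prediction from a bivariate REML fit.

    ``Re`` is the estimated additive covariance between relative fitness and
    the trait; ``st_cov_a`` standardizes it by the phenotypic SD.  The
    significance flag is the Wald criterion |Re| > 1.96 SE.  A non-converged
    fit propagates its flag (predictions from it should be treated as NA).
    """
    if len(fit.responses) != 2:
        raise ValueError("sts_response needs a bivariate fit")
    wname = fitness_col or fit.responses[0]
    xname = [r for r in fit.responses if r != wname][0]
    cov = float(fit.G0.loc[wname, xname])
    se = float(fit.se_G0.loc[wname, xname])
    return ResponsePrediction(
        trait=xname, Re=cov, se_Re=se, st_cov_a=cov / trait_sd,
        significant=bool(np.isfinite(se) and abs(cov) > 1.96 * se),
        converged=fit.converged, Re_data_scale=Re_data_scale)


def lognormal_mean(mu: float, var_total: float) -> float:
    """Data-scale mean of exp(N(mu, var_total))."""
    return float(np.exp(mu + var_total / 2.0))


def lognormal_cov(mu_x: float, mu_y: float, var_x: float, var_y: float,
                  cov_xy: float) -> float:
    """Data-scale covariance of two jointly lognormal variables.

    ``Cov(e^X, e^Y) = exp(mu_x + mu_y + (var_x + var_y)/2) (exp(cov_xy) - 1)``
    with the variances being the *total* log-scale variances.
    """
    return float(np.exp(mu_x + mu_y + (var_x + var_y) / 2.0) * np.expm1(cov_xy))


def lognormal_gaussian_cov(mu_l: float, var_l: float, cov_lx: float) -> float:
    """Covariance between exp(L) and a Gaussian X: exp(mu + var/2) * Cov(L, X).

    Used when fitness is analysed on the log scale but the trait stays
    Gaussian (Stein-type identity for the bivariate normal).
    """
    return float(np.exp(mu_l + var_l / 2.0) * cov_lx)


def lognormal_backtransform(mu_log, var_components_log) -> dict:
    """Data-scale mean/variance/covariance of log-Gaussian model components.

    Parameters
    ----------
    mu_log : float or (float, float)
        Log-scale mean(s).
    var_components_log : dict
        For one variable: ``{"var_total": s2}``.  For two:
        ``{"var_total_x": ..., "var_total_y": ..., "cov_xy": ...}``.

    Returns a dict with ``mean`` (per variable), ``variance`` and, in the
    bivariate case, ``covariance`` on the untransformed data scale.
    """
    if np.isscalar(mu_log):
        s2 = var_components_log["var_total"]
        m = lognormal_mean(mu_log, s2)
        return {"mean": m, "variance": float(m ** 2 * np.expm1(s2))}
    mx, my = mu_log
    s2x = var_components_log["var_total_x"]
    s2y = var_components_log["var_total_y"]
    sxy = var_components_log["cov_xy"]
    return {
        "mean": (lognormal_mean(mx, s2x), lognormal_mean(my, s2y)),
        "variance": (float(lognormal_mean(mx, s2x) ** 2 * np.expm1(s2x)),
                     float(lognormal_mean(my, s2y) ** 2 * np.expm1(s2y))),
        "covariance": lognormal_cov(mx, my, s2x, s2y, sxy),
    }


# --------------------------------------------------------------------------
# breeding values (BLUP) and the phenotypic-covariance decomposition
# --------------------------------------------------------------------------

@dataclass
class BlupResult:
    table: pd.DataFrame            # tree_id, generation, blup, blup_std
    generation_means: pd.Series    # standardized-scale mean per generation
    shift: float                   # mean(G2) - mean(G1), standardized scale
    t_stat: float
    p_value: float
    varcomp: VarCompEstimate


def breeding_values(responses: pd.DataFrame, G: RelatednessMatrix,
                    generation: pd.Series, fixed: pd.DataFrame | None = None,
                    fit: VarCompEstimate | None = None, **kwargs) -> BlupResult:
    """Univariate two-generation BLUPs with a generation fixed effect.

    Fits (or reuses) the univariate REML model with generation added to the
    fixed effects, solves for the additive-effect BLUPs at the estimates,
    standardizes them across the two generations and compares the
    per-generation means with Welch's t test.  With zero additive variance
    every BLUP shrinks to exactly 0.
    """
    if responses.shape[1] != 1:
        raise ValueError("breeding_values expects a single response column")
    Y = responses.dropna()
    ids = Y.index
    gen = generation.reindex(ids)
    if gen.isna().any():
        raise ValueError("generation labels missing for some trees")
    gen_dummy = pd.get_dummies(gen, drop_first=True).astype(float)
    Xf = (pd.concat([fixed.reindex(ids), gen_dummy], axis=1)
          if fixed is not None else gen_dummy)

    model = RemlAnimalModel(**kwargs)
    if fit is None:
        fit = model.fit(Y, G, Xf).varcomp_
        d, U, _, X = model._rotation_
    else:
        Gs = condition_matrix(G.reindex(ids), model.eig_floor)
        d, U = np.linalg.eigh(Gs.values)
        d = np.maximum(d, model.eig_floor)
        X = np.column_stack([np.ones(len(ids)), Xf.to_numpy(dtype=float)])
    if not fit.converged:
        logger.warning("BLUPs computed at a non-converged REML optimum")

    s2a = float(fit.G0.iloc[0, 0])
    s2e = float(fit.R0.iloc[0, 0])
    y = Y.to_numpy(dtype=float)[:, 0]
    Xt, yt = U.T @ X, U.T @ y
    v = d * s2a + s2e
    iv = 1.0 / v
    C = (Xt * iv[:, None]).T @ Xt
    b = np.linalg.solve(C, (Xt * iv[:, None]).T @ yt)
    et = yt - Xt @ b
    # a_hat = s2a * G V^{-1} e  =  U diag(s2a d / v) U' e
    a_hat = U @ (s2a * d * iv * et)

    sd = a_hat.std(ddof=1)
    a_std = a_hat / sd if sd > 0 else np.zeros_like(a_hat)
    tab = pd.DataFrame({"generation": gen.to_numpy(), "blup": a_hat,
                        "blup_std": a_std}, index=ids)
    means = tab.groupby("generation")["blup_std"].mean()
    gens = sorted(means.index)
    if len(gens) == 2 and sd > 0:
        g1, g2 = (tab.loc[tab.generation == g, "blup_std"] for g in gens)
        t, p = stats.ttest_ind(g2, g1, equal_var=False)
        shift = float(means[gens[1]] - means[gens[0]])
    else:
        t, p, shift = np.nan, np.nan, 0.0
    return BlupResult(tab, means, shift, float(t), float(p), fit)


def covariance_decomposition(w_additive, w_environmental,
                             x_additive, x_environmental) -> pd.DataFrame:
    """Decompose the phenotypic fitness-trait covariance into four components.

    Given the realized additive and environmental values of relative fitness
    and a trait (available in simulation, where the truth is known),
    ``Cov(w, x)`` splits exactly into ``Cov(w_a, x_a) + Cov(w_e, x_a) +
    Cov(w_a, x_e) + Cov(w_e, x_e)``.  Opposite signs of the first and last
    terms explain phenotypic selection gradients that contradict the genetic
    covariance.
    """
    wa = np.asarray(w_additive, float)
    we = np.asarray(w_environmental, float)
    xa = np.asarray(x_additive, float)
    xe = np.asarray(x_environmental, float)
    if not (len(wa) == len(we) == len(xa) == len(xe)):
        raise ValueError("component vectors must share length "
                         "(decomposition requires the simulated truth)")
    c = lambda u, v: float(np.cov(u, v, ddof=1)[0, 1])
    rows = {
        "cov_wa_xa": c(wa, xa), "cov_we_xa": c(we, xa),
        "cov_wa_xe": c(wa, xe), "cov_we_xe": c(we, xe),
    }
    rows["sum_components"] = sum(rows.values())
    rows["cov_phenotypic"] = c(wa + we, xa + xe)
    return pd.DataFrame([rows])
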