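"""REML animal model, BLUPs, response prediction, scale back-transform."""

import numpy as np
import pandas as pd
import pytest

import oakforge as of
from oakforge.animal_model import _neg2_restricted_loglik
from oakforge.containers import RelatednessMatrix
from tests.conftest import full_pedigree


def _halfsib(rng, n_sires, n_off, h2=0.4):
    sires = np.repeat(np.arange(n_sires), n_off)
    ids = pd.Index([f"t{i}" for i in range(n_sires * n_off)])
    A = np.where(sires[:, None] == sires[None, :], 0.25, 0.0)
    np.fill_diagonal(A, 1.0)
    s = rng.normal(0, np.sqrt(h2 / 4), n_sires)
    y = 10.0 + s[sires] + rng.normal(0, np.sqrt(1 - h2 / 4), len(ids))
    return pd.DataFrame({"y": y}, index=ids), RelatednessMatrix(A, ids), sires


def _anova_h2(y, sires, n_off):
    df = pd.DataFrame({"y": y, "s": sires})
    g = df.groupby("s")["y"]
    msb = n_off * g.mean().var(ddof=1)
    msw = g.apply(lambda v: v.var(ddof=1)).mean()
    s2s = (msb - msw) / n_off
    return 4 * s2s / (s2s + msw)


def test_balanced_halfsib_reml_equals_anova(rng):
    """On a balanced paternal half-sib design REML = closed-form ANOVA."""
    Y, G, sires = _halfsib(rng, 30, 12)
    vc = of.reml_fit(Y, G)
    assert vc.converged
    h2_reml = vc.heritability["y"]
    h2_anova = _anova_h2(Y["y"].to_numpy(), sires, 12)
    assert h2_reml == pytest.approx(h2_anova, abs=1e-6)


def _dense_neg2_reml(G0, R0, K, Y, X):
    """Brute-force restricted criterion: log|V| + log|X'V^-1 X| + r'V^-1 r."""
    n, q = Y.shape
    V = np.kron(G0, K) + np.kron(R0, np.eye(n))
    Xf = np.kron(np.eye(q), X)
    y = Y.T.to_numpy().ravel()
    Vi = np.linalg.inv(V)
    C = Xf.T @ Vi @ Xf
    b = np.linalg.solve(C, Xf.T @ Vi @ y)
    r = y - Xf @ b
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(C)[1] + r @ Vi @ r)


@pytest.mark.parametrize("q", [1, 2])
def test_rotated_criterion_matches_dense_oracle(rng, q):
    """The O(n) eigen-rotated restricted likelihood equals the dense formula."""
    n = 40
    ids = pd.Index([f"t{i}" for i in range(n)])
    B = rng.normal(size=(n, 5))
    K = B @ B.T / 5 + np.eye(n)              # arbitrary PD relatedness
    Y = pd.DataFrame(rng.normal(size=(n, q)), index=ids,
                     columns=[f"y{j}" for j in range(q)])
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    if q == 1:
        G0, R0 = np.array([[0.7]]), np.array([[0.4]])
    else:
        G0 = np.array([[0.7, 0.2], [0.2, 0.5]])
        R0 = np.array([[0.6, -0.1], [-0.1, 0.8]])
    d, U = np.linalg.eigh(K)
    fast = _neg2_restricted_loglik(G0, R0, d, U.T @ Y.to_numpy(), U.T @ X)
    dense = _dense_neg2_reml(G0, R0, K, Y, X)
    assert fast == pytest.approx(dense, rel=1e-9)


def test_identity_relatedness_reduces_to_independent_effects(rng):
    """With G = I the criterion matches a direct two-variance oracle at any split."""
    n = 50
    ids = pd.Index([f"t{i}" for i in range(n)])
    y = rng.normal(2.0, 1.0, n)
    Y = pd.DataFrame({"y": y}, index=ids)
    X = np.ones((n, 1))
    d = np.ones(n)
    for s2a, s2e in [(0.3, 0.7), (0.9, 0.1)]:
        fast = _neg2_restricted_loglik(np.array([[s2a]]), np.array([[s2e]]),
                                       d, Y.to_numpy(), X)
        dense = _dense_neg2_reml(np.array([[s2a]]), np.array([[s2e]]),
                                 np.eye(n), Y, X)
        assert fast == pytest.approx(dense, rel=1e-9)


def test_loglik_invariant_to_fixed_effect_reparameterization(rng):
    Y, G, _ = _halfsib(rng, 20, 8)
    n = len(Y)
    cov = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)},
                       index=Y.index)
    vc1 = of.reml_fit(Y, G, cov)
    T = np.array([[2.0, 1.0], [0.5, -1.0]])          # invertible recombination
    cov2 = pd.DataFrame(cov.to_numpy() @ T, index=Y.index, columns=["a", "b"])
    vc2 = of.reml_fit(Y, G, cov2)
    # restricted likelihood depends on the column span only; the |X'V^-1X|
    # term shifts by a data-free constant log|T'T|
    shift = np.linalg.slogdet(T.T @ T)[1]
    assert vc2.loglik == pytest.approx(vc1.loglik - 0.5 * shift, abs=1e-5)
    assert np.allclose(vc1.G0, vc2.G0, atol=1e-4)


def test_bivariate_criterion_separates_when_cross_covariances_zero(rng):
    n = 35
    d = rng.uniform(0.5, 2.0, n)
    Y = rng.normal(size=(n, 2))
    X = np.ones((n, 1))
    G0 = np.diag([0.5, 0.8])
    R0 = np.diag([0.7, 0.3])
    biv = _neg2_restricted_loglik(G0, R0, d, Y, X)
    uni = sum(_neg2_restricted_loglik(G0[k:k+1, k:k+1], R0[k:k+1, k:k+1],
                                      d, Y[:, k:k+1], X) for k in range(2))
    assert biv == pytest.approx(uni, rel=1e-10)


def test_bivariate_covariance_recovery():
    """Planted additive covariance 0.3 between two traits is recovered on average."""
    r = np.sqrt(0.6)
    ests = []
    for seed in range(6):
        cfg = of.SimConfig(n_parents_per_species=25, n_snps_small=5, n_snps_large=5,
                           n_offspring=400, plot_width=160, plot_height=160,
                           trait_specs=[of.TraitSpec("x1", 0, 0.5, 0.5, r),
                                        of.TraitSpec("x2", 0, 0.5, 0.5, r)],
                           rng_seed=300 + seed)
        stand, _, _, traits, _, truth = of.simulate_stand(cfg)
        assert truth.additive_covariance.loc["x1", "x2"] == pytest.approx(0.3)
        g2 = stand.loc[stand.generation == "G2", "tree_id"]
        A = of.pedigree_nrm(full_pedigree(stand, truth)).reindex(g2)
        vc = of.reml_fit(traits.loc[g2, ["x1", "x2"]], A)
        assert vc.converged
        ests.append(vc.G0.loc["x1", "x2"])
    assert np.mean(ests) == pytest.approx(0.3, abs=0.1)


def test_se_shrinks_with_sample_size(rng):
    ses = []
    for n_sires in (10, 20, 40):
        Y, G, _ = _halfsib(np.random.default_rng(17), n_sires, 10)
        vc = of.reml_fit(Y, G)
        ses.append(vc.se_G0.iloc[0, 0])
    assert ses[0] > ses[1] > ses[2]


# ----------------------------------------------------------- STS response
def test_sts_response_properties():
    names = ["w", "x"]
    mk = lambda M: pd.DataFrame(M, index=names, columns=names)
    vc = of.VarCompEstimate(
        G0=mk([[0.4, 0.12], [0.12, 0.8]]), R0=mk(np.eye(2)),
        se_G0=mk([[0.1, 0.05], [0.05, 0.2]]), se_R0=mk(np.eye(2)),
        loglik=-10.0, converged=True, boundary=False, n=100, n_iter=5,
        responses=names)
    r1 = of.sts_response(vc, trait_sd=2.0)
    assert r1.Re == pytest.approx(0.12)
    assert r1.st_cov_a == pytest.approx(0.06)
    assert r1.significant                      # |0.12| > 1.96 * 0.05
    # st_cov halves when sd doubles, Re unchanged
    r2 = of.sts_response(vc, trait_sd=4.0)
    assert r2.Re == r1.Re
    assert r2.st_cov_a == pytest.approx(r1.st_cov_a / 2)


def test_sts_zero_covariance_and_convergence_propagation():
    names = ["w", "x"]
    mk = lambda M: pd.DataFrame(M, index=names, columns=names)
    vc = of.VarCompEstimate(
        G0=mk([[0.4, 0.0], [0.0, 0.8]]), R0=mk(np.eye(2)),
        se_G0=mk([[0.1, 0.05], [0.05, 0.2]]), se_R0=mk(np.eye(2)),
        loglik=-10.0, converged=False, boundary=False, n=100, n_iter=5,
        responses=names)
    r = of.sts_response(vc, trait_sd=1.0)
    assert r.Re == 0.0 and not r.significant and not r.converged


# ----------------------------------------------------- back-transformation
def test_lognormal_closed_forms():
    assert of.lognormal_mean(0.0, np.log(2.0)) == pytest.approx(np.sqrt(2.0))
    assert of.lognormal_cov(0.0, 0.0, 0.5, 0.5, 0.0) == 0.0
    out = of.lognormal_backtransform(0.0, {"var_total": np.log(2.0)})
    assert out["mean"] == pytest.approx(np.sqrt(2.0))


def test_lognormal_backtransform_monte_carlo(rng):
    mu = np.array([0.2, -0.1])
    S = np.array([[0.3, 0.12], [0.12, 0.2]])
    draws = np.exp(rng.multivariate_normal(mu, S, size=1_000_000))
    out = of.lognormal_backtransform(
        (mu[0], mu[1]), {"var_total_x": S[0, 0], "var_total_y": S[1, 1],
                         "cov_xy": S[0, 1]})
    assert out["mean"][0] == pytest.approx(draws[:, 0].mean(), rel=5e-3)
    assert out["covariance"] == pytest.approx(
        np.cov(draws.T, ddof=1)[0, 1], rel=2e-2)
    # mixed lognormal-Gaussian covariance (Stein identity)
    logs = np.log(draws[:, 0])
    assert of.lognormal_gaussian_cov(mu[0], S[0, 0], S[0, 1]) == pytest.approx(
        np.cov(draws[:, 0], np.log(draws[:, 1]), ddof=1)[0, 1], rel=2e-2)


# ------------------------------------------------------------------ BLUPs
def _fixed_vc(s2a, s2e):
    mk = lambda v: pd.DataFrame([[v]], index=["y"], columns=["y"])
    return of.VarCompEstimate(G0=mk(s2a), R0=mk(s2e), se_G0=mk(0.1),
                              se_R0=mk(0.1), loglik=0.0, converged=True,
                              boundary=False, n=0, n_iter=0, responses=["y"])


def test_blups_zero_additive_variance_shrink_to_zero(rng):
    n = 40
    ids = pd.Index([f"t{i}" for i in range(n)])
    Y = pd.DataFrame({"y": rng.normal(size=n)}, index=ids)
    G = RelatednessMatrix(np.eye(n), ids)
    gen = pd.Series(["G1"] * 20 + ["G2"] * 20, index=ids)
    res = of.breeding_values(Y, G, gen, fit=_fixed_vc(0.0, 1.0))
    assert np.allclose(res.table["blup"], 0.0)
    assert res.shift == 0.0


def test_blups_match_dense_mixed_model_solve(rng):
    n = 60
    ids = pd.Index([f"t{i}" for i in range(n)])
    B = rng.normal(size=(n, 4))
    K = B @ B.T / 4 + np.eye(n)
    y = rng.normal(size=n) + 3.0
    Y = pd.DataFrame({"y": y}, index=ids)
    G = RelatednessMatrix(K, ids)
    gen = pd.Series(["G1"] * 30 + ["G2"] * 30, index=ids)
    s2a, s2e = 0.6, 0.8
    res = of.breeding_values(Y, G, gen, fit=_fixed_vc(s2a, s2e))
    # dense oracle: a = s2a K V^-1 (y - X b_gls)
    X = np.column_stack([np.ones(n), (gen == "G2").astype(float)])
    V = s2a * K + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = s2a * K @ Vi @ (y - X @ b)
    assert np.allclose(res.table["blup"].to_numpy(), a, atol=1e-8)


def test_blup_generation_shift_detects_planted_selection():
    """Fitness-correlated trait: offspring of high-fecundity parents shift upward."""
    shifts = []
    for seed in range(3):
        cfg = of.SimConfig(n_parents_per_species=15, n_snps_small=5,
                           n_snps_large=400, n_offspring=150, fecundity_cv=1.5,
                           trait_specs=[of.TraitSpec("x", 0, 0.5, 0.5, 0.9)],
                           rng_seed=700 + seed)
        stand, _, gl, traits, _, truth = of.simulate_stand(cfg)
        g1 = stand.loc[stand.generation == "G1", "tree_id"]
        grm = of.vanraden_grm(gl.subset(g1))
        H = of.hybrid_relatedness(grm, truth.pedigree)
        gen = stand.set_index("tree_id")["generation"]
        res = of.breeding_values(traits[["x"]], H, gen)
        shifts.append(res.shift)
    assert sum(s > 0 for s in shifts) >= 2
    assert np.mean(shifts) > 0


# ------------------------------------------------- covariance decomposition
def test_covariance_decomposition_identity(rng):
    n = 500
    wa, we, xa, xe = (rng.normal(size=n) for _ in range(4))
    out = of.covariance_decomposition(wa, we, xa, xe)
    assert out["sum_components"].iloc[0] == pytest.approx(
        out["cov_phenotypic"].iloc[0], abs=1e-12)


def test_opposite_sign_construction_flips_phenotypic_gradient(rng):
    """Positive genetic but larger negative environmental covariance:
    the phenotypic covariance opposes the genetic one."""
    n = 2000
    wa = rng.normal(size=n)
    xa = 0.5 * wa + rng.normal(0, 0.5, n)          # Cov(wa, xa) > 0
    we = rng.normal(size=n)
    xe = -1.5 * we + rng.normal(0, 0.5, n)         # Cov(we, xe) << 0
    out = of.covariance_decomposition(wa, we, xa, xe)
    assert out["cov_wa_xa"].iloc[0] > 0
    assert out["cov_we_xe"].iloc[0] < 0
    assert np.sign(out["cov_phenotypic"].iloc[0]) != np.sign(out["cov_wa_xa"].iloc[0])


def test_decomposition_requires_aligned_truth(rng):
    with pytest.raises(ValueError, match="truth"):
        of.covariance_decomposition(np.ones(3), np.ones(3), np.ones(3), np.ones(4))
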