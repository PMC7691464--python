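"""Genomic, pedigree and hybrid relatedness matrices."""

import numpy as np
import pandas as pd
import pytest

import oakforge as of
from oakforge.containers import GenotypeMatrix, RelatednessMatrix


def _gm(rows, p, ids=None):
    ids = ids or [f"i{k}" for k in range(len(rows))]
    cols = [f"L{j}" for j in range(len(p))]
    return GenotypeMatrix(pd.DataFrame(rows, index=ids, columns=cols, dtype=float),
                          pd.Series(p, index=cols, dtype=float))


# ---------------------------------------------------------------- VanRaden
def test_grm_hand_cases():
    # one locus, p=0.5, both heterozygous -> recoded 0,0 -> G = 0
    g = of.vanraden_grm(_gm([[1], [1]], [0.5]), freq_source="supplied")
    assert np.allclose(g.values, 0.0)
    # homozygote alternate, recoded +1: G_ii = 1 / (2 * 0.25) * 1 = 2
    g = of.vanraden_grm(_gm([[2], [0]], [0.5]), freq_source="supplied")
    assert g.values[0, 0] == pytest.approx(2.0)
    assert g.values[0, 1] == pytest.approx(-2.0)


def test_grm_hwe_panel_diagonal_and_offdiagonal(rng):
    n, m = 150, 3000
    p = rng.uniform(0.1, 0.9, m)
    dos = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    g = of.vanraden_grm(_gm(dos, p), freq_source="supplied")
    assert np.mean(np.diag(g.values)) == pytest.approx(1.0, abs=0.05)
    off = g.values[np.triu_indices(n, k=1)]
    assert abs(off.mean()) < 0.02


def test_grm_monomorphic_handling(rng):
    dos = rng.binomial(2, 0.5, size=(10, 4)).astype(float)
    dos[:, 0] = 2.0  # monomorphic
    est = of.VanRadenGRM().fit(_gm(dos, [1.0, 0.5, 0.5, 0.5]))
    assert "L0" in est.dropped_loci_
    assert est.n_loci_used_ <= 3
    with pytest.raises(ValueError, match="monomorphic"):
        of.vanraden_grm(_gm([[2, 2], [2, 2]], [1.0, 1.0]), freq_source="supplied")


def test_grm_missing_genotypes_imputed_and_flagged(rng):
    dos = rng.binomial(2, 0.5, size=(8, 20)).astype(float)
    dos[0, :15] = np.nan         # 75% missing -> flagged
    dos[1, 0] = np.nan           # sporadic missing -> imputed
    est = of.VanRadenGRM(max_missing_locus=0.5).fit(
        _gm(dos, [0.5] * 20))
    assert "i0" in est.flagged_individuals_
    assert np.isfinite(est.grm_.values).all()


def test_grm_permutation_equivariance(rng):
    dos = rng.binomial(2, 0.5, size=(12, 60)).astype(float)
    g = of.vanraden_grm(_gm(dos, [0.5] * 60))
    perm = rng.permutation(12)
    gp = of.vanraden_grm(_gm(dos[perm], [0.5] * 60,
                             ids=[f"i{k}" for k in perm]))
    assert np.allclose(gp.values, g.values[np.ix_(perm, perm)])


def test_offdiag_variance_orders_family_structure(rng):
    """A family-structured sample shows larger relatedness variance than unrelated HWE."""
    m = 1500
    p = rng.uniform(0.2, 0.8, m)
    unrel = rng.binomial(2, p[None, :], size=(60, m)).astype(float)
    g_unrel = of.vanraden_grm(_gm(unrel, p), freq_source="supplied")
    founders = rng.binomial(2, p[None, :], size=(20, m))

    def gamete(par):
        out = (par / 2).astype(float)
        het = par == 1
        out[het] = rng.integers(0, 2, het.sum())
        return out

    fam = [gamete(founders[2 * (k % 10)]) + gamete(founders[2 * (k % 10) + 1])
           for k in range(60)]
    g_fam = of.vanraden_grm(_gm(np.array(fam, dtype=float), p), freq_source="supplied")
    assert g_fam.offdiag_variance > g_unrel.offdiag_variance


# ---------------------------------------------------------------- pedigree
def _ped(records):
    return pd.DataFrame(records, columns=["tree_id", "mother_id", "father_id"])


def test_pedigree_textbook_values():
    ped = _ped([("m", None, None), ("f", None, None), ("f2", None, None),
                ("o1", "m", "f"), ("o2", "m", "f"), ("h", "m", "f2")])
    A = of.pedigree_nrm(ped).to_frame()
    assert A.loc["m", "o1"] == pytest.approx(0.5)     # parent-offspring
    assert A.loc["o1", "o2"] == pytest.approx(0.5)    # full sibs
    assert A.loc["o1", "h"] == pytest.approx(0.25)    # half sibs
    assert A.loc["o1", "o1"] == pytest.approx(1.0)    # non-inbred


def test_pedigree_inbred_offspring_of_full_sibs():
    ped = _ped([("m", None, None), ("f", None, None),
                ("s1", "m", "f"), ("s2", "m", "f"), ("o", "s1", "s2")])
    A = of.pedigree_nrm(ped).to_frame()
    assert A.loc["o", "o"] == pytest.approx(1.25)     # F = 0.25


def _path_counting_oracle(ped: pd.DataFrame) -> pd.DataFrame:
    """Wright's path-counting additive relationship, independent of the tabular code.

    a(i,j) = sum over common ancestors A and node-disjoint ancestral paths
    (1/2)^(n_links) * (1 + F_A), with F_A = 0.5 * a(mother_A, father_A).
    """
    parents = {r.tree_id: tuple(p for p in (r.mother_id, r.father_id)
                                if isinstance(p, str))
               for r in ped.itertuples(index=False)}

    def paths_up(x):
        # all ancestor chains from x (inclusive): list of tuples
        out = [(x,)]
        for p in parents[x]:
            out += [(x,) + q for q in paths_up(p)]
        return out

    def inbreeding(x):
        pp = parents[x]
        return 0.5 * relat(pp[0], pp[1]) if len(pp) == 2 else 0.0

    def relat(i, j):
        if i == j:
            return 1.0 + inbreeding(i)
        total = 0.0
        for p1 in paths_up(i):
            for p2 in paths_up(j):
                if p1[-1] != p2[-1]:
                    continue                      # must meet at a common ancestor
                if set(p1[:-1]) & set(p2):
                    continue                      # node-disjoint except ancestor
                total += 0.5 ** (len(p1) + len(p2) - 2) * (1 + inbreeding(p1[-1]))
        return total

    ids = list(ped["tree_id"])
    return pd.DataFrame([[relat(i, j) for j in ids] for i in ids],
                        index=ids, columns=ids)


def test_pedigree_matches_path_counting_oracle():
    """3-generation, 8-individual pedigree equals exhaustive path enumeration."""
    ped = _ped([
        ("a", None, None), ("b", None, None), ("c", None, None), ("d", None, None),
        ("e", "a", "b"), ("f", "a", "c"), ("g", "e", "d"), ("h", "e", "f"),
    ])
    A = of.pedigree_nrm(ped).to_frame()
    O = _path_counting_oracle(ped)
    assert np.allclose(A.to_numpy(), O.to_numpy(), atol=1e-12)


def test_pedigree_error_cases():
    with pytest.raises(ValueError, match="unknown parent"):
        of.pedigree_nrm(_ped([("o", "ghost", None)]))
    with pytest.raises(ValueError, match="parents-first"):
        of.pedigree_nrm(_ped([("o", "m", None), ("m", None, None)]))
    with pytest.raises(ValueError, match="duplicated"):
        of.pedigree_nrm(_ped([("m", None, None), ("m", None, None)]))


# ---------------------------------------------------------------- hybrid
def test_hybrid_hand_cases():
    grm = RelatednessMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]),
                            pd.Index(["p1", "p2"]))
    hyb = of.hybrid_relatedness(grm, _ped([("o", "p1", "p2")])).to_frame()
    assert hyb.loc["p1", "o"] == pytest.approx(0.5)
    assert hyb.loc["o", "o"] == pytest.approx(1.0)

    grm2 = RelatednessMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]),
                             pd.Index(["p1", "p2"]))
    hyb2 = of.hybrid_relatedness(grm2, _ped([("o", "p1", "p2")])).to_frame()
    assert hyb2.loc["o", "o"] == pytest.approx(1.25)


def test_hybrid_equals_pedigree_nrm_on_equivalent_pedigree():
    """Full-sib G1 parents per the genomic block reproduce the 2-generation NRM."""
    ped_full = _ped([("gm", None, None), ("gf", None, None),
                     ("s1", "gm", "gf"), ("s2", "gm", "gf"), ("o", "s1", "s2")])
    A = of.pedigree_nrm(ped_full).to_frame().loc[["s1", "s2", "o"], ["s1", "s2", "o"]]
    grm = RelatednessMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]),
                            pd.Index(["s1", "s2"]))
    H = of.hybrid_relatedness(grm, _ped([("o", "s1", "s2")])).to_frame()
    assert np.allclose(H.to_numpy(), A.to_numpy(), atol=1e-12)


def test_hybrid_unknown_parent_contributes_zero():
    grm = RelatednessMatrix(np.eye(2), pd.Index(["p1", "p2"]))
    hyb = of.hybrid_relatedness(grm, _ped([("o", "p1", None)])).to_frame()
    assert hyb.loc["p2", "o"] == 0.0
    assert hyb.loc["o", "o"] == 1.0
    with pytest.raises(ValueError, match="not in G1"):
        of.hybrid_relatedness(grm, _ped([("o", "nope", "p1")]))


# ---------------------------------------------------------------- bending
def test_condition_matrix():
    pd_ok = RelatednessMatrix(np.eye(3), pd.Index(list("abc")))
    assert of.condition_matrix(pd_ok, 1e-6) is pd_ok
    sing = RelatednessMatrix(np.ones((2, 2)), pd.Index(["a", "b"]))
    bent = of.condition_matrix(sing, 1e-6)
    assert bent.bending_applied
    assert bent.min_eigenvalue() >= 1e-6 - 1e-12
    assert bent.values[0, 1] == 1.0   # off-diagonals untouched
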