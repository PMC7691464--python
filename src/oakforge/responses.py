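"""Predicted vs observed selection responses across the two generations.

Three complementary response measures are assembled per trait:

* **predicted** — the Robertson-Price genetic response on the data scale,
  expressed as a percentage of the parental mean:
  ``Re% = (G2_pred - G1) * 100 / G1`` with ``G2_pred = G1 + Re``;
* **observed (phenotypic)** — the parental-fitness-split contrast: parents
  are split at the within-species median of observed fitness, offspring are
  classed by their parents' class, and
  ``Delta% = (mean(G2+) - mean(G2-)) * 100 / mean(mean(G2+), mean(G2-))``
  (the signed mean in the denominator; for traits with negative means, e.g.
  isotope compositions, the sign of the percentage then depends on the
  denominator's sign — a warning is emitted);
* **observed (genetic)** — the shift of mean standardized breeding values
  between generations from the two-generation animal model.

Because the predicted and observed routes rest on different machinery, only
the *signs* of the shifts are compared (concordance report).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .reference_tables import published_response_table

logger = logging.getLogger(__name__)

__all__ = [
    "predicted_response_pct",
    "parental_split_response",
    "concordance_report",
    "recompute_published_cells",
]


def predicted_response_pct(G1_mean: float, Re_data_scale: float
                           ) -> tuple[float, float]:
    """Predicted G2 mean and response percentage from a data-scale Re.

    ``G2_pred = G1_mean + Re``; ``Re% = (G2_pred - G1) * 100 / G1``.
    """
    if G1_mean == 0:
        raise ValueError("G1 mean is zero; response percentage undefined")
    g2 = G1_mean + Re_data_scale
    return g2, (g2 - G1_mean) * 100.0 / G1_mean


def delta_pct(mean_minus: float, mean_plus: float) -> float:
    """Observed response percentage between the two parental-fitness classes."""
    denom = 0.5 * (mean_plus + mean_minus)
    if denom == 0:
        raise ValueError("class means average to zero; percentage undefined")
    if denom < 0:
        warnings.warn("negative trait mean: the sign of Delta% follows the signed "
                      "denominator and may oppose the direction of the raw shift")
    return (mean_plus - mean_minus) * 100.0 / denom


def parental_split_response(traits_g2: pd.Series, fitness_g1: pd.Series,
                            pedigree: pd.DataFrame,
                            species_g1: pd.Series | None = None,
                            disagree: str = "mean") -> tuple[float, float, float]:
    """Split G2 phenotypes by parental observed-fitness class.

    G1 trees are split at the median of observed fitness (per species when
    ``species_g1`` is given; ties at the median go to the bottom class).
    Each offspring is classed by its two parents: both-top -> G2+, both-bottom
    -> G2-; when the parents disagree the ``disagree`` policy applies:
    ``"mean"`` (default) classes by the mean of the two parental fitness
    values relative to the median, ``"mother"`` uses the mother's class,
    ``"exclude"`` drops the offspring.

    Returns ``(G2_minus_mean, G2_plus_mean, Delta_pct)``.
    """
    grp = (species_g1.reindex(fitness_g1.index) if species_g1 is not None
           else pd.Series("all", index=fitness_g1.index))
    med = fitness_g1.groupby(grp).transform("median")
    top = fitness_g1 > med            # tree at the median -> bottom class

    classes = []
    for row in pedigree.itertuples(index=False):
        if row.tree_id not in traits_g2.index:
            continue
        if pd.isna(traits_g2.loc[row.tree_id]):
            continue
        pars = [p for p in (row.mother_id, row.father_id) if p in fitness_g1.index]
        if not pars:
            raise ValueError(f"offspring {row.tree_id!r} has no parent with fitness")
        flags = [bool(top.loc[p]) for p in pars]
        if all(flags):
            cls = True
        elif not any(flags):
            cls = False
        elif disagree == "mother":
            cls = flags[0]
        elif disagree == "exclude":
            continue
        elif disagree == "mean":
            fmean = np.mean([fitness_g1.loc[p] for p in pars])
            cls = fmean > float(np.mean([med.loc[p] for p in pars]))
        else:
            raise ValueError(f"unknown disagree policy {disagree!r}")
        classes.append((row.tree_id, cls))
    if not classes:
        raise ValueError("no classifiable offspring")
    cls = pd.Series(dict(classes))
    vals = traits_g2.loc[cls.index]
    m_plus = float(vals[cls].mean())
    m_minus = float(vals[~cls].mean())
    if np.isnan(m_plus) or np.isnan(m_minus):
        raise ValueError("one parental-fitness class is empty")
    return m_minus, m_plus, delta_pct(m_minus, m_plus)


def concordance_report(response_table: pd.DataFrame,
                       blup_shifts: pd.Series | None = None) -> pd.DataFrame:
    """Sign-concordance summary of predicted vs observed responses.

    ``response_table`` needs columns ``trait``, ``Re_pct``, ``Delta_pct``
    (NaN allowed); ``blup_shifts`` optionally maps trait -> standardized
    breeding-value shift.  Flags per trait whether the predicted genetic and
    observed phenotypic (and genetic, if given) shifts agree in sign —
    conflicts such as a predicted decrease alongside an observed increase
    are the interesting rows.
    """
    out = response_table[["trait"]].copy()
    out["sign_pred"] = np.sign(response_table["Re_pct"])
    out["sign_obs"] = np.sign(response_table["Delta_pct"])
    out["concordant"] = np.where(
        response_table[["Re_pct", "Delta_pct"]].isna().any(axis=1), np.nan,
        (out["sign_pred"] == out["sign_obs"]).astype(float))
    if blup_shifts is not None:
        out["sign_blup"] = np.sign(
            blup_shifts.reindex(response_table["trait"]).to_numpy())
        out["blup_concordant"] = np.where(
            np.isnan(out["sign_blup"]) | out["sign_pred"].isna(), np.nan,
            (out["sign_pred"] == out["sign_blup"]).astype(float))
    n = out["concordant"].notna().sum()
    k = out["concordant"].sum()
    logger.info("sign concordance: %d/%d traits", int(k), int(n))
    return out


def recompute_published_cells(species: str) -> pd.DataFrame:
    """Recompute every Re% / Delta% cell of a published response table.

    For each trait the percentage is recomputed from the printed means with
    the package's formulas.  Because the published means are themselves
    rounded, each cell carries a ``slack`` column: the worst-case shift of
    the recomputed percentage when every input mean moves by half an ulp of
    its printed precision.  ``magnitude_only`` marks traits with a negative
    denominator mean, where the published percentages follow an
    absolute-value denominator convention and only magnitudes are comparable.
    """
    tab = published_response_table(species)
    rows = []
    for r in tab.itertuples(index=False):
        half_g1 = 0.5 * 10.0 ** -r.decimals_G1
        if not pd.isna(r.G2_pred):
            _, re_pct = predicted_response_pct(r.G1, r.G2_pred - r.G1)
            half_g2 = 0.5 * 10.0 ** -r.decimals_G2_pred
            slack = 100.0 * (half_g1 + half_g2) / abs(r.G1) \
                + abs(re_pct) * half_g1 / abs(r.G1)
            rows.append({"trait": r.trait, "column": "Re_pct",
                         "printed": r.Re_pct, "recomputed": re_pct,
                         "slack": slack, "magnitude_only": r.G1 < 0})
        half_m = 0.5 * 10.0 ** -r.decimals_G2_minus
        half_p = 0.5 * 10.0 ** -r.decimals_G2_plus
        mean = 0.5 * (r.G2_minus + r.G2_plus)
        d_pct = delta_pct(r.G2_minus, r.G2_plus) if mean != 0 else np.nan
        slack = 100.0 * (half_m + half_p) / abs(mean) \
            + abs(d_pct) * 0.5 * (half_m + half_p) / abs(mean)
        rows.append({"trait": r.trait, "column": "Delta_pct",
                     "printed": r.Delta_pct, "recomputed": d_pct,
                     "slack": slack, "magnitude_only": mean < 0})
    out = pd.DataFrame(rows)
    out["species"] = species
    a = np.where(out["magnitude_only"], np.abs(out["recomputed"]), out["recomputed"])
    b = np.where(out["magnitude_only"], np.abs(out["printed"]), out["printed"])
    out["abs_error"] = np.abs(a - b)
    out["consistent"] = out["abs_error"] <= 0.02 + out["slack"]
    return out
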