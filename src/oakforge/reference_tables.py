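"""Published response tables for the La Petite Charnie mixed oak stand.

Mean trait values per generation and per parental-fitness class, as printed
in the published comparison of predicted (second-theorem) and observed
(parental-fitness-split) selection responses for the eleven traits assessed
in both generations.  Columns:

* ``G1`` — phenotypic mean of the parental generation;
* ``G2_pred`` — predicted G2 mean (G1 plus the data-scale Robertson-Price
  response); ``Re_pct`` — the printed predicted response percentage;
* ``G2_minus`` / ``G2_plus`` — G2 phenotypic means for offspring of
  bottom-50% / top-50% fitness parents; ``Delta_pct`` — the printed observed
  response percentage;
* ``decimals_*`` — the printed precision of each mean, used to propagate
  print-rounding when the percentages are recomputed.

These serve as worked-example inputs: the pipeline's percentage formulas are
validated by recomputing every cell from the printed means.  NA cells
correspond to traits whose variance-component estimation did not converge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["published_response_table", "PINNED_CELLS"]

_COLS = ["trait", "units", "G1", "G2_pred", "Re_pct", "G2_minus", "G2_plus",
         "Delta_pct"]

_PETRAEA = [
    ("CIRC", "cm",      190.83,  200.94,   5.30,    32.43,    33.52,   3.32),
    ("HGHT", "cm",     2655.22, 2696.84,   1.57,  1089.00,  1106.573,  1.60),
    ("LU",   "days",    106.21,  106.31,   0.095,    3.92,     3.92,   0.13),
    ("C",    "g/kg",    454.74,  443.51,  -2.47,   458.69,   458.178, -0.11),
    ("C/N",  "ratio",    24.53,   24.77,   0.99,    19.29,    19.132, -0.83),
    ("d13C", "permil",  -29.77,  -29.73,   0.14,   -29.46,   -29.59,   0.44),
    ("d15N", "permil",   -3.35,   -3.25,   2.87,    -6.42,    -6.46,   0.65),
    ("MLA",  "cm2",      44.78,   47.13,   5.25,    32.21,    32.51,   0.92),
    ("N",    "g/kg",     18.84,   18.44,  -2.17,    24.03,    24.14,   0.47),
    ("SLA",  "m2/kg",    11.93,   11.48,  -3.76,    13.21,    13.49,   2.12),
    ("WD",   "kg/m3",   576.77,  569.87,  -1.20,   506.97,   509.31,   0.46),
]

_ROBUR = [
    ("CIRC", "cm",      167.19,  168.47,   0.76,    26.695,   27.455,  2.81),
    ("HGHT", "cm",     2516.41, 2474.53,  -1.66,   924.252,  945.46,   2.27),
    ("LU",   "days",    101.80,  101.28,  -0.50,     3.687,    3.685, -0.05),
    ("C",    "g/kg",    461.31,  461.59,   0.06,   465.434,  465.098, -0.07),
    ("C/N",  "ratio",    23.69,   23.88,   0.80,    20.205,   19.991, -1.06),
    ("d13C", "permil",  -30.08,  -30.00,   0.27,   -29.657,  -29.713, -0.19),
    ("d15N", "permil",   -2.32,   -2.22,   4.39,    -3.904,   -4.156, -6.25),
    ("MLA",  "cm2",      35.78,   32.72,  -8.53,    22.773,   23.351,  2.51),
    ("N",    "g/kg",     19.84,  np.nan,  np.nan,   23.362,   23.579,  0.92),
    ("SLA",  "m2/kg",    13.82,  np.nan,  np.nan,   13.49,    13.866,  2.75),
    ("WD",   "kg/m3",   549.69,  543.78,  -1.07,   498.269,  497.628, -0.13),
]


def _decimals(x) -> int:
    if pd.isna(x):
        return 2
    s = np.format_float_positional(float(x), trim="-")
    return len(s.split(".")[1]) if "." in s else 0


def published_response_table(species: str) -> pd.DataFrame:
    """Printed response-comparison table for ``'petraea'`` or ``'robur'``."""
    rows = {"petraea": _PETRAEA, "robur": _ROBUR}[species]
    df = pd.DataFrame(rows, columns=_COLS)
    for col in ("G1", "G2_pred", "G2_minus", "G2_plus"):
        df[f"decimals_{col}"] = [_decimals(v) for v in df[col]]
    return df


# Cells whose recomputation from the printed means reproduces the printed
# percentage exactly at two decimals (signed formulas, positive-mean traits).
PINNED_CELLS = [
    # (species, trait, column, printed value)
    ("petraea", "CIRC", "Re_pct", 5.30),
    ("petraea", "HGHT", "Re_pct", 1.57),
    ("petraea", "HGHT", "Delta_pct", 1.60),
    ("petraea", "C", "Re_pct", -2.47),
    ("petraea", "C", "Delta_pct", -0.11),
    ("petraea", "MLA", "Re_pct", 5.25),
    ("petraea", "WD", "Re_pct", -1.20),
    ("petraea", "WD", "Delta_pct", 0.46),
    ("robur", "CIRC", "Delta_pct", 2.81),
    ("robur", "HGHT", "Re_pct", -1.66),
    ("robur", "HGHT", "Delta_pct", 2.27),
    ("robur", "C/N", "Re_pct", 0.80),
]
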