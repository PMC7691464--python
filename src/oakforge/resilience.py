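"""Lloret-style resilience indices of ring growth around stress years.

For a pointer (stress) year with ring growth ``g_dur``, a pre-stress window
mean ``g_pre`` and a post-stress window mean ``g_post``:

* resistance  RET = g_dur / g_pre   (inverse of the growth reduction)
* recovery    REC = g_post / g_dur
* resilience  REL = g_post / g_pre

so that REL = RET * REC holds exactly.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["resilience_indices"]


def resilience_indices(ring_widths: pd.Series, pointer_years, window: int = 3
                       ) -> pd.DataFrame:
    """Resistance/recovery/resilience per pointer year.

    Parameters
    ----------
    ring_widths : pandas.Series
        Ring growth indexed by calendar year (consecutive years).
    pointer_years : iterable of int
        Stress years.  Years without ``window`` full years on both sides are
        skipped with a warning.
    window : int
        Width (in years) of the pre- and post-stress averaging windows.

    Returns
    -------
    pandas.DataFrame indexed by pointer year with columns RET, REC, REL.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rw = ring_widths.sort_index()
    years = rw.index
    rows = {}
    for y in pointer_years:
        pre = range(y - window, y)
        post = range(y + 1, y + window + 1)
        if y not in years or any(p not in years for p in pre) or any(p not in years for p in post):
            warnings.warn(f"pointer year {y} too close to the series edge; skipped")
            continue
        g_pre = rw.loc[list(pre)].mean()
        g_post = rw.loc[list(post)].mean()
        g_dur = rw.loc[y]
        rows[y] = {"RET": g_dur / g_pre, "REC": g_post / g_dur, "REL": g_post / g_pre}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("pointer_year")
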