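"""Group comparison: Mann-Whitney U with Bonferroni correction.

Subject-level metric aggregates are compared pairwise between groups with
a two-sided Mann-Whitney U test; p values are Bonferroni-adjusted over an
explicitly declared comparison family (the family size must be stated by
the caller, so multiplicity control is reproducible).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["compare_groups", "median_mad"]


def median_mad(x: np.ndarray) -> tuple[float, float]:
    """Median and median absolute deviation."""
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


def compare_groups(
    table: pd.DataFrame,
    value: str,
    group_col: str = "group",
    pairs: list[tuple[str, str]] | None = None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests on subject-level values.

    ``table`` holds one row per subject with a ``value`` column and a group
    label. ``pairs`` declares the comparisons (all unordered group pairs by
    default); ``family_size`` the Bonferroni family (default: number of
    pairs tested). Adjusted p = min(1, raw p * family_size).
    """
    groups = {g: sub[value].dropna().to_numpy() for g, sub in table.groupby(group_col)}
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        med_a, mad_a = median_mad(xa)
        med_b, mad_b = median_mad(xb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": xa.size,
                "n_b": xb.size,
                "median_a": med_a,
                "mad_a": mad_a,
                "median_b": med_b,
                "mad_b": mad_b,
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonferroni": float(min(1.0, res.pvalue * m)),
            }
        )
    return pd.DataFrame(rows)
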