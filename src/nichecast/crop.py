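"""Overlap of pest suitability with crop-suitability categories.

Pairs the continuous beetle-suitability raster with the categorical crop map
cell-by-cell, summarizes suitability per crop category (mean, SE), and tests
category differences with a one-way fixed-effects ANOVA followed by
Bonferroni-adjusted pairwise t-tests.  Cells are treated as independent
observations, as is conventional in this kind of overlay (the resulting F
statistics are huge and the inference is anticonservative under spatial
autocorrelation — a caveat, not a correction, here).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .grid import CROP_CATEGORIES, CropCategoryMap, SuitabilityMap

__all__ = ["OverlapSummary", "overlay_summarize", "anova_bonferroni"]

_ORDER = ("suitable", "conditioned", "unsuitable")


@dataclass
class OverlapSummary:
    """Per-category suitability summary with ANOVA and post-hoc tests."""

    per_category: pd.DataFrame       # index: category; n, mean, se, sd
    anova: dict | None = None        # {"F", "df", "df_resid", "p"}
    pairwise: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return self.per_category


def _paired_values(suitability: SuitabilityMap, crop: CropCategoryMap,
                   ) -> dict[str, np.ndarray]:
    sgrid, cgrid = suitability.grid, crop.grid
    if sgrid.shape == cgrid.shape and np.isclose(sgrid.x0, cgrid.x0) \
            and np.isclose(sgrid.y0, cgrid.y0):
        cats = crop.categories
        vals = suitability.values
    else:
        # nearest-neighbour lookup from the suitability grid onto crop cells
        rows, cols = np.nonzero(crop.mask)
        x, y = cgrid.center(rows, cols)
        srow, scol = sgrid.cell_of(x, y)
        ok = sgrid.contains(srow, scol)
        cats = np.full(cgrid.shape, CROP_CATEGORIES["nodata"], int)
        vals = np.full(cgrid.shape, np.nan)
        cats[rows[ok], cols[ok]] = crop.categories[rows[ok], cols[ok]]
        vals[rows[ok], cols[ok]] = suitability.values[srow[ok], scol[ok]]
    groups = {}
    for name in _ORDER:
        sel = (cats == CROP_CATEGORIES[name]) & np.isfinite(vals)
        groups[name] = vals[sel]
    return groups


def overlay_summarize(suitability: SuitabilityMap, crop: CropCategoryMap,
                      run_anova: bool = True) -> OverlapSummary:
    """Mean and SE of pest suitability within each crop category."""
    groups = _paired_values(suitability, crop)
    if sum(g.size for g in groups.values()) == 0:
        raise ValueError("suitability and crop maps share no valid cells")
    rows = []
    for name in _ORDER:
        g = groups[name]
        n = g.size
        sd = g.std(ddof=1) if n > 1 else np.nan
        rows.append({"category": name, "n": n,
                     "mean": g.mean() if n else np.nan,
                     "sd": sd, "se": sd / np.sqrt(n) if n > 1 else np.nan})
    per_cat = pd.DataFrame(rows).set_index("category")
    summary = OverlapSummary(per_cat)
    if run_anova:
        present = {k: v for k, v in groups.items() if v.size >= 2}
        if len(present) >= 2:
            anova, pairwise = anova_bonferroni(present)
            summary.anova, summary.pairwise = anova, pairwise
    return summary


def anova_bonferroni(groups: dict[str, np.ndarray],
                     ) -> tuple[dict, pd.DataFrame]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Adjusted p = raw two-sample-t p times the number of pairs, capped at 1.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least two groups with at least two values each")
    F, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    anova = {"F": float(F), "df": df_between, "df_resid": df_within,
             "p": float(p)}
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        t, praw = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        rows.append({"pair": f"{a} vs {b}", "t": float(t),
                     "p_raw": float(praw),
                     "p_bonferroni": min(1.0, float(praw) * len(pairs))})
    return anova, pd.DataFrame(rows).set_index("pair")
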