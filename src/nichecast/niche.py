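"""Niche contrasts: presence climates vs randomized no-record climates.

No-record points are drawn from cells that (i) hold no occurrence record and
(ii) fall below the suitability cut-off in *both* the lower and upper bound
maps — i.e. cells the ensemble confidently calls unsuitable.  One hundred
random sets, each as large as the presence sample, are drawn; per variable the
sets are reduced to one comparison sample (element-wise mean across sets by
default, or concatenated with ``mode='pool'``) and contrasted against the
presence values with a two-sample Student's t-test (pooled variance,
df = n1 + n2 - 2).

Note the deliberate circularity, inherited from the procedure this implements:
the no-record sample is defined through the fitted bound maps that the
contrast then characterizes.  The tests describe *where the model places the
species*, not an independent habitat contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleSDMResults
from .grid import ClimateStack, OccurrenceSet, presence_cells

__all__ = ["NicheContrast", "sample_norecord_sets", "niche_ttests"]


@dataclass
class NicheContrast:
    """Per-variable presence vs no-record comparison table."""

    table: pd.DataFrame   # index: variable; columns: means, sds, t, p, ...
    n_presence: int
    n_sets: int
    mode: str

    def summary(self) -> pd.DataFrame:
        return self.table


def sample_norecord_sets(stack: ClimateStack, presences: OccurrenceSet,
                         result: EnsembleSDMResults, n_sets: int = 100,
                         seed: int = 0, cutoff: float | None = None,
                         ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random no-record cell sets outside the lower and upper suitable areas.

    Each of the ``n_sets`` sets samples as many cells as there are (thinned)
    presence cells, uniformly without replacement, from valid cells with no
    record and lower/upper suitability below the cut-off.
    """
    cutoff = cutoff if cutoff is not None else result.cutoff
    p_rows, p_cols = presence_cells(stack, presences)
    occupied = np.zeros(stack.grid.shape, bool)
    occupied[p_rows, p_cols] = True
    with np.errstate(invalid="ignore"):
        eligible = (stack.mask & ~occupied
                    & (result.lower.values < cutoff)
                    & (result.upper.values < cutoff))
    e_rows, e_cols = np.nonzero(eligible)
    n_need = len(p_rows)
    if len(e_rows) < n_need:
        raise ValueError(
            f"eligible no-record pool has {len(e_rows)} cells; "
            f"{n_need} are required per set")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        idx = rng.choice(len(e_rows), size=n_need, replace=False)
        sets.append((e_rows[idx], e_cols[idx]))
    return sets


def niche_ttests(stack: ClimateStack, presences: OccurrenceSet,
                 norecord_sets: list[tuple[np.ndarray, np.ndarray]],
                 variables: list[str] | None = None,
                 mode: str = "average") -> NicheContrast:
    """Student's t contrast of presence vs no-record climate, per variable.

    ``mode='average'`` averages the no-record value vectors element-wise
    across the sets into one sample the size of the presence sample (positions
    within a set are random, so this approximates the pooled mean with reduced
    variance); ``mode='pool'`` concatenates all sets.
    """
    if mode not in ("average", "pool"):
        raise ValueError("mode must be 'average' or 'pool'")
    variables = variables or stack.variable_names
    p_rows, p_cols = presence_cells(stack, presences)
    pres = stack.values_at(p_rows, p_cols, variables)
    if len(p_rows) < 2 or not norecord_sets:
        raise ValueError("need at least two presence cells and one no-record set")
    per_set = [stack.values_at(r, c, variables) for r, c in norecord_sets]
    if mode == "average":
        nor = np.mean(per_set, axis=0)
    else:
        nor = np.vstack(per_set)

    rows = []
    for j, name in enumerate(variables):
        a, b = pres[:, j], nor[:, j]
        q1, q2, q3 = np.percentile(a, [25, 50, 75])
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.nan, np.nan)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "variable": name,
            "presence_mean": a.mean(), "presence_sd": a.std(ddof=1),
            "presence_q1": q1, "presence_median": q2, "presence_q3": q3,
            "norecord_mean": b.mean(), "norecord_sd": b.std(ddof=1),
            "t": float(t), "df": len(a) + len(b) - 2, "p": float(p),
            "direction": "higher" if a.mean() > b.mean() else "lower",
        })
    table = pd.DataFrame(rows).set_index("variable")
    return NicheContrast(table, n_presence=len(p_rows),
                         n_sets=len(norecord_sets), mode=mode)
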