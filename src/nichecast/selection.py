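"""Collinearity-aware predictor selection.

Candidate climate layers are reduced in two stages:

1. Ward agglomeration of the dissimilarity ``d(i, j) = 1 - |r(i, j)|`` (Pearson
   correlation over sampled valid cells), cut at a distance threshold
   (default 0.3, i.e. clusters of variables correlated above ~70%), keeping one
   representative per cluster.  Ward linkage is applied to the 1-|r|
   dissimilarity directly; this is a pragmatic convention — Ward formally
   assumes Euclidean distances — and is the documented default.
2. An iterative variance-inflation-factor filter: while any retained variable
   has VIF = 1/(1 - R_i^2) above ``max_vif`` (default 5), drop the worst one.

The representative of a cluster defaults to the variable with the highest
variance after z-scoring across the sampled cells; a ``force_keep`` list
overrides the rule so a published predictor set can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .grid import ClimateStack

__all__ = ["SelectionReport", "select_variables", "vif_filter", "compute_vif"]

MAX_SAMPLE_CELLS = 50_000


@dataclass
class SelectionReport:
    """Record of the clustering + VIF selection pipeline."""

    candidates: list[str]
    correlation: pd.DataFrame
    merge_heights: np.ndarray          # linkage heights, ascending
    clusters: dict[int, list[str]]     # cluster label -> member variables
    representatives: dict[int, str]
    threshold: float
    vif_steps: list[pd.Series] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, members in sorted(self.clusters.items()):
            rep = self.representatives[label]
            for name in members:
                status = ("selected" if name in self.selected else
                          "dropped_vif" if name in self.dropped else
                          "representative" if name == rep else "clustered_out")
                rows.append({"variable": name, "cluster": label,
                             "representative": rep, "status": status})
        return pd.DataFrame(rows)


def _sample_matrix(stack: ClimateStack, sample_cells: int | None,
                   seed: int | None) -> pd.DataFrame:
    table = stack.table()
    limit = MAX_SAMPLE_CELLS if sample_cells is None else sample_cells
    if len(table) > limit:
        rng = np.random.default_rng(seed)
        table = table.iloc[rng.choice(len(table), size=limit, replace=False)]
    return table


def correlation_distance(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ``1 - |Pearson r|`` dissimilarity; errors on constant layers."""
    sds = values.std(ddof=0)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(f"constant layer(s) {flat}: correlation undefined")
    corr = values.corr(method="pearson")
    return 1.0 - corr.abs()


def select_variables(stack: ClimateStack, sample_cells: int | None = None,
                     threshold: float = 0.3, seed: int | None = 0,
                     force_keep: list[str] | None = None) -> SelectionReport:
    """Cluster candidate layers and keep one representative per cluster.

    Returns a pre-VIF :class:`SelectionReport`; follow with :func:`vif_filter`
    for the final set.  Singleton clusters at distance > threshold survive
    untouched.
    """
    names = stack.variable_names
    if len(names) < 2:
        raise ValueError("need at least two candidate layers")
    values = _sample_matrix(stack, sample_cells, seed)
    dist = correlation_distance(values)
    condensed = squareform(dist.to_numpy(), checks=False)
    lk = linkage(condensed, method="ward")
    labels = fcluster(lk, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for name, lab in zip(names, labels):
        clusters.setdefault(int(lab), []).append(name)
    # representative: forced name if present in the cluster, else the member
    # with the largest z-scored variance over the sample (ties -> first name)
    z_var = ((values - values.mean()) / values.std(ddof=0)).var(ddof=0)
    force = list(force_keep or [])
    reps: dict[int, str] = {}
    for lab, members in clusters.items():
        forced = [m for m in members if m in force]
        if forced:
            reps[lab] = forced[0]
        else:
            reps[lab] = max(members, key=lambda m: (z_var[m], -members.index(m)))
    report = SelectionReport(
        candidates=list(names),
        correlation=1.0 - dist,
        merge_heights=lk[:, 2].copy(),
        clusters=clusters,
        representatives=reps,
        threshold=threshold,
        selected=sorted(reps.values(), key=names.index),
    )
    return report


def compute_vif(values: pd.DataFrame) -> pd.Series:
    """VIF_i = 1/(1 - R_i^2) from OLS of z-scored variable i on the others.

    Perfect collinearity yields ``inf`` rather than an error so the iterative
    filter can drop the offender.
    """
    z = (values - values.mean()) / values.std(ddof=0)
    z = z.to_numpy()
    n, p = z.shape
    out = {}
    for i, name in enumerate(values.columns):
        y = z[:, i]
        X = np.column_stack([np.ones(n), np.delete(z, i, axis=1)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = float(y @ y)
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_filter(stack: ClimateStack, report: SelectionReport, max_vif: float = 5.0,
               sample_cells: int | None = None, seed: int | None = 0,
               ) -> SelectionReport:
    """Iteratively drop the largest-VIF variable while any VIF exceeds max_vif."""
    keep = list(report.selected)
    if len(keep) < 2:
        report.vif_steps = []
        return report
    values = _sample_matrix(stack.subset(keep), sample_cells, seed)
    dropped: list[str] = []
    steps: list[pd.Series] = []
    while len(keep) >= 2:
        vifs = compute_vif(values[keep])
        steps.append(vifs)
        worst = vifs.idxmax()
        if vifs[worst] > max_vif:
            keep.remove(worst)
            dropped.append(str(worst))
        else:
            break
    report.vif_steps = steps
    report.dropped = dropped
    report.selected = keep
    return report
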