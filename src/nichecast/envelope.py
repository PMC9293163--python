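"""Presence-only environmental envelope and background/pseudoabsence pools.

The envelope is the per-variable [min, max] interval spanned by presence
cells (intervals are closed, so every presence cell lies inside its own
envelope).  Each valid landscape cell is then classified by the number of
selected variables whose value falls strictly outside its interval:

* 0 failures  -> **background** (climate fully within the species' observed range)
* 1 failure   -> **excluded** (neither pool; the rule set is silent on these)
* >=2 failures -> **pseudoabsence** (confidently outside the envelope)

Point samples for model fitting are drawn uniformly without replacement from
each pool, at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ClimateStack, OccurrenceSet, presence_cells

__all__ = ["EnvelopeModel", "CellPartition", "build_envelope",
           "partition_cells", "sample_points"]

BACKGROUND, EXCLUDED, PSEUDOABSENCE = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", EXCLUDED: "excluded",
               PSEUDOABSENCE: "pseudoabsence"}


@dataclass(frozen=True)
class EnvelopeModel:
    """Per-variable [min, max] intervals observed at presence cells."""

    limits: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.limits.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid interval for {name!r}: [{lo}, {hi}]")

    @property
    def variables(self) -> list[str]:
        return list(self.limits)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v, lo, hi) for v, (lo, hi) in self.limits.items()],
            columns=["variable", "min", "max"])


@dataclass
class CellPartition:
    """Per-cell class (background / excluded / pseudoabsence) and failure count."""

    grid_shape: tuple[int, int]
    classes: np.ndarray    # int codes, -1 on masked cells
    n_failed: np.ndarray   # failure counts, -1 on masked cells

    def pool(self, cls: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.classes == cls)

    def counts(self) -> pd.Series:
        return pd.Series({name: int((self.classes == code).sum())
                          for code, name in CLASS_NAMES.items()},
                         name="n_cells").reindex(
            ["background", "excluded", "pseudoabsence"]).astype(int)


def build_envelope(stack: ClimateStack, presences: OccurrenceSet,
                   selected: list[str] | None = None,
                   thin: bool = True) -> EnvelopeModel:
    """Presence-only envelope over the selected variables."""
    selected = selected or stack.variable_names
    rows, cols = presence_cells(stack, presences, thin=thin)
    vals = stack.values_at(rows, cols, selected)
    limits = {name: (float(vals[:, j].min()), float(vals[:, j].max()))
              for j, name in enumerate(selected)}
    return EnvelopeModel(limits)


def partition_cells(stack: ClimateStack, envelope: EnvelopeModel) -> CellPartition:
    """Classify every valid cell by its envelope failure count."""
    missing = [v for v in envelope.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks layer(s) {missing} required by the envelope")
    n_failed = np.zeros(stack.grid.shape, int)
    for name in envelope.variables:
        lo, hi = envelope.limits[name]
        layer = stack.layers[name]
        with np.errstate(invalid="ignore"):
            outside = (layer < lo) | (layer > hi)
        n_failed += np.where(stack.mask, outside, 0)
    classes = np.where(n_failed == 0, BACKGROUND,
                       np.where(n_failed >= 2, PSEUDOABSENCE, EXCLUDED))
    classes = np.where(stack.mask, classes, -1)
    n_failed = np.where(stack.mask, n_failed, -1)
    return CellPartition(stack.grid.shape, classes, n_failed)


def sample_points(partition: CellPartition, n_background: int,
                  n_pseudoabsence: int, seed: int,
                  ) -> tuple[tuple[np.ndarray, np.ndarray],
                             tuple[np.ndarray, np.ndarray]]:
    """Uniform without-replacement samples of cells from each pool.

    Returns ``((bg_rows, bg_cols), (pa_rows, pa_cols))``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for cls, n in ((BACKGROUND, n_background), (PSEUDOABSENCE, n_pseudoabsence)):
        rows, cols = partition.pool(cls)
        if n > len(rows):
            raise ValueError(
                f"requested {n} {CLASS_NAMES[cls]} points but the pool has "
                f"only {len(rows)} cells")
        idx = rng.choice(len(rows), size=n, replace=False)
        idx.sort()
        out.append((rows[idx], cols[idx]))
    return out[0], out[1]
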