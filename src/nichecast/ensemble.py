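"""Ensemble species distribution model: Model / Results objects.

:class:`EnsembleSDM` is built from a climate stack, occurrence records and an
envelope-based cell partition; :meth:`EnsembleSDM.fit` runs the full
multi-algorithm, multi-iteration ensemble and returns an
:class:`EnsembleSDMResults` carrying the consensus and bound suitability maps,
the per-run AUC table, external evaluation, permutation-based variable
contributions, binarization and point validation.

Procedure
---------
1. Presence cells are thinned to one per cell; pseudoabsence and background
   point sets are drawn from the envelope partition pools (defaults: one
   pseudoabsence per presence, ten background points per presence).
2. A stratified 25% *external* holdout of presences/pseudoabsences/background
   is set aside before the iteration loop and enters no fit.
3. Each iteration draws a fresh stratified 75/25 split of the remaining
   training pool, fits all six algorithms on the 75% side, and scores an
   *internal* AUC (presences vs pseudoabsences) on the 25% side.  Runs with
   internal AUC above the keep threshold (default 0.7, strict) contribute.
4. Kept runs are averaged cell-wise into the consensus map; the lower/upper
   bound maps are cell-wise 2.5th/97.5th percentiles of kept-run predictions
   (configurable to min/max).
5. The consensus, lower and upper maps are evaluated by external AUC on the
   held-out presences vs pseudoabsences.

All randomness descends from a single master seed through
``numpy.random.SeedSequence`` spawning, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .algorithms import ALGORITHMS, SuitabilityLearner, make_learner
from .envelope import (BACKGROUND, PSEUDOABSENCE, CellPartition, EnvelopeModel,
                       build_envelope, partition_cells, sample_points)
from .grid import ClimateStack, OccurrenceSet, SuitabilityMap, presence_cells
from .metrics import auc_roc

__all__ = ["EnsembleConfig", "EnsembleSDM", "EnsembleSDMResults",
           "binarize", "validate_points"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunable parameters of the ensemble procedure."""

    algorithms: tuple[str, ...] = ALGORITHMS
    n_iterations: int = 100
    external_fraction: float = 0.25   # held out once, before the loop
    internal_fraction: float = 0.25   # held in per iteration for internal AUC
    auc_keep: float = 0.7             # strict: kept iff AUC > auc_keep
    cutoff: float = 0.55              # suitable/unsuitable discrimination
    bounds: str = "percentile"        # or "minmax"
    bound_percentiles: tuple[float, float] = (2.5, 97.5)
    n_pseudoabsence: int | None = None  # default: one per presence
    n_background: int | None = None     # default: ten per presence
    learner_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.external_fraction < 1 or not 0 < self.internal_fraction < 1:
            raise ValueError("split fractions must be in (0, 1)")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        unknown = set(a.upper() for a in self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s) {sorted(unknown)}")


def _stratified_split(n: int, frac_out: float, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Random (kept, held-out) index split with ceil(frac_out * n) held out."""
    n_out = max(1, int(round(frac_out * n))) if n > 1 else 0
    perm = rng.permutation(n)
    return np.sort(perm[n_out:]), np.sort(perm[:n_out])


class EnsembleSDM:
    """Six-algorithm ensemble suitability model for a species on a landscape.

    Parameters
    ----------
    stack : ClimateStack
        Climate layers; only ``variables`` enter the model.
    presences : OccurrenceSet
        Training occurrences (role ``train``); duplicates within a cell are
        thinned for fitting.
    variables : list of str, optional
        Predictor subset (default: all layers).
    envelope, partition : optional
        Precomputed envelope / cell partition; built from the presences when
        omitted.
    config : EnsembleConfig
    """

    def __init__(self, stack: ClimateStack, presences: OccurrenceSet,
                 variables: list[str] | None = None,
                 envelope: EnvelopeModel | None = None,
                 partition: CellPartition | None = None,
                 config: EnsembleConfig | None = None):
        self.stack = stack
        self.presences = presences
        self.variables = list(variables) if variables else stack.variable_names
        self.config = config or EnsembleConfig()
        self.envelope = envelope or build_envelope(stack, presences, self.variables)
        self.partition = partition if partition is not None else partition_cells(
            stack.subset(self.variables), self.envelope)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0, shuffle_labels: bool = False) -> "EnsembleSDMResults":
        """Run the full ensemble.

        ``shuffle_labels=True`` randomly permutes the presence/pseudoabsence
        labels before the external split — a null-calibration diagnostic whose
        external AUC should sit near 0.5.
        """
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss.spawn(1)[0])

        p_rows, p_cols = presence_cells(self.stack, self.presences)
        n_pres = len(p_rows)
        n_pa = cfg.n_pseudoabsence or n_pres
        pa_pool = int((self.partition.classes == PSEUDOABSENCE).sum())
        bg_pool = int((self.partition.classes == BACKGROUND).sum())
        n_pa = min(n_pa, pa_pool)
        n_bg = min(cfg.n_background or 10 * n_pres, bg_pool)
        (bg_rows, bg_cols), (pa_rows, pa_cols) = sample_points(
            self.partition, n_bg, n_pa, seed=int(rng.integers(2**31)))

        Xp = self.stack.values_at(p_rows, p_cols, self.variables)
        Xa = self.stack.values_at(pa_rows, pa_cols, self.variables)
        Xb = self.stack.values_at(bg_rows, bg_cols, self.variables)

        if shuffle_labels:
            pool = np.vstack([Xp, Xa])
            lab = rng.permutation(np.r_[np.ones(len(Xp)), np.zeros(len(Xa))])
            Xp, Xa = pool[lab == 1], pool[lab == 0]

        tr_p, ho_p = _stratified_split(len(Xp), cfg.external_fraction, rng)
        tr_a, ho_a = _stratified_split(len(Xa), cfg.external_fraction, rng)
        tr_b, _ = _stratified_split(len(Xb), cfg.external_fraction, rng)
        Xp_tr, Xp_ho = Xp[tr_p], Xp[ho_p]
        Xa_tr, Xa_ho = Xa[tr_a], Xa[ho_a]
        Xb_tr = Xb[tr_b]

        v_rows, v_cols = self.stack.valid_indices()
        X_grid = self.stack.values_at(v_rows, v_cols, self.variables)

        records = []
        kept_preds: list[np.ndarray] = []
        kept_learners: list[SuitabilityLearner] = []
        iter_seeds = ss.spawn(cfg.n_iterations)
        for it, it_ss in enumerate(iter_seeds):
            it_rng = np.random.default_rng(it_ss)
            fit_p, ev_p = _stratified_split(len(Xp_tr), cfg.internal_fraction, it_rng)
            fit_a, ev_a = _stratified_split(len(Xa_tr), cfg.internal_fraction, it_rng)
            fit_b, _ = _stratified_split(len(Xb_tr), cfg.internal_fraction, it_rng)
            X_eval = np.vstack([Xp_tr[ev_p], Xa_tr[ev_a]])
            y_eval = np.r_[np.ones(len(ev_p)), np.zeros(len(ev_a))]
            for algo in cfg.algorithms:
                algo = algo.upper()
                run_seed = int(it_rng.integers(2**31))
                if algo == "MAXENT":
                    X_fit = np.vstack([Xp_tr[fit_p], Xb_tr[fit_b]])
                    y_fit = np.r_[np.ones(len(fit_p)), np.zeros(len(fit_b))]
                else:
                    X_fit = np.vstack([Xp_tr[fit_p], Xa_tr[fit_a]])
                    y_fit = np.r_[np.ones(len(fit_p)), np.zeros(len(fit_a))]
                rec = {"algorithm": algo, "iteration": it, "seed": run_seed,
                       "internal_auc": np.nan, "kept": False, "failed": False}
                try:
                    learner = make_learner(algo, run_seed, cfg.learner_config)
                    learner.fit(X_fit, y_fit)
                    rec["internal_auc"] = auc_roc(learner.predict(X_eval), y_eval)
                except Exception:   # non-convergence: run not kept, loop continues
                    rec["failed"] = True
                    records.append(rec)
                    continue
                if rec["internal_auc"] > cfg.auc_keep:
                    rec["kept"] = True
                    kept_preds.append(learner.predict(X_grid).astype(np.float32))
                    kept_learners.append(learner)
                records.append(rec)

        run_table = pd.DataFrame(records)
        if not kept_preds:
            raise RuntimeError(
                "no run passed the AUC keep filter; per-run AUC table:\n"
                + run_table.to_string())

        P = np.vstack(kept_preds)           # (n_kept, n_valid_cells)
        consensus_v = P.mean(axis=0)
        if cfg.bounds == "minmax":
            lower_v, upper_v = P.min(axis=0), P.max(axis=0)
        else:
            lo_q, hi_q = cfg.bound_percentiles
            lower_v = np.percentile(P, lo_q, axis=0)
            upper_v = np.percentile(P, hi_q, axis=0)
        lower_v = np.minimum(lower_v, consensus_v)
        upper_v = np.maximum(upper_v, consensus_v)

        def to_map(vals: np.ndarray) -> SuitabilityMap:
            arr = np.full(self.stack.grid.shape, np.nan)
            arr[v_rows, v_cols] = vals
            return SuitabilityMap(self.stack.grid, arr, self.stack.mask.copy())

        consensus, lower, upper = map(to_map, (consensus_v, lower_v, upper_v))

        # external AUC: the ensemble statistics evaluated at held-out points
        ho_X = np.vstack([Xp_ho, Xa_ho])
        ho_y = np.r_[np.ones(len(Xp_ho)), np.zeros(len(Xa_ho))]
        member_ho = np.vstack([ln.predict(ho_X) for ln in kept_learners])
        cons_ho = member_ho.mean(axis=0)
        if cfg.bounds == "minmax":
            low_ho, up_ho = member_ho.min(axis=0), member_ho.max(axis=0)
        else:
            low_ho = np.percentile(member_ho, cfg.bound_percentiles[0], axis=0)
            up_ho = np.percentile(member_ho, cfg.bound_percentiles[1], axis=0)
        external_auc = {"consensus": auc_roc(cons_ho, ho_y),
                        "lower": auc_roc(low_ho, ho_y),
                        "upper": auc_roc(up_ho, ho_y)}

        return EnsembleSDMResults(
            model=self, seed=seed, run_table=run_table,
            consensus=consensus, lower=lower, upper=upper,
            external_auc=external_auc, cutoff=cfg.cutoff,
            _kept_learners=kept_learners,
            _train_X={"contrast": np.vstack([Xp_tr, Xa_tr]),
                      "background": np.vstack([Xp_tr, Xb_tr])},
        )


@dataclass
class EnsembleSDMResults:
    """Fitted ensemble: maps, AUC bookkeeping, contributions, validation."""

    model: EnsembleSDM
    seed: int
    run_table: pd.DataFrame
    consensus: SuitabilityMap
    lower: SuitabilityMap
    upper: SuitabilityMap
    external_auc: dict[str, float]
    cutoff: float
    _kept_learners: list[SuitabilityLearner] = field(repr=False, default_factory=list)
    _train_X: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.run_table)

    @property
    def n_kept(self) -> int:
        return int(self.run_table["kept"].sum())

    def summary(self) -> pd.DataFrame:
        """Per-algorithm run counts and internal AUC, plus external AUC rows
        for the consensus and bound maps."""
        g = self.run_table.groupby("algorithm")
        tab = pd.DataFrame({
            "runs": g.size().astype(float),
            "kept": g["kept"].sum().astype(float),
            "mean_internal_auc": g["internal_auc"].mean(),
            "min_internal_auc": g["internal_auc"].min(),
            "external_auc": np.nan,
        })
        for name in ("consensus", "lower", "upper"):
            tab.loc[f"ensemble:{name}"] = [np.nan, np.nan, np.nan, np.nan,
                                           self.external_auc[name]]
        return tab

    def variable_contributions(self, seed: int = 0, n_repeats: int = 3,
                               ) -> pd.DataFrame:
        """Permutation importance per algorithm and variable, in percent.

        Contribution of a variable to an algorithm = ``1 - max(r, 0)`` where
        ``r`` is the Pearson correlation between the member's predictions on
        its training matrix and on the same matrix with that variable's column
        permuted, averaged over the algorithm's kept runs (and permutation
        repeats).
        """
        rng = np.random.default_rng(seed)
        variables = self.model.variables
        kept = self.run_table[self.run_table["kept"]]
        rows = {}
        by_algo: dict[str, list[SuitabilityLearner]] = {}
        for (_, rec), ln in zip(kept.iterrows(), self._kept_learners):
            by_algo.setdefault(rec["algorithm"], []).append(ln)
        for algo in self.model.config.algorithms:
            algo = algo.upper()
            members = by_algo.get(algo, [])
            if not members:
                rows[algo] = {v: np.nan for v in variables}
                continue
            X = self._train_X["background" if algo == "MAXENT" else "contrast"]
            contrib = {}
            for j, name in enumerate(variables):
                vals = []
                for ln in members:
                    base = ln.predict(X)
                    for _ in range(n_repeats):
                        Xp = X.copy()
                        Xp[:, j] = rng.permutation(Xp[:, j])
                        perm = ln.predict(Xp)
                        if base.std() == 0 or perm.std() == 0:
                            r = 0.0
                        else:
                            r = float(np.corrcoef(base, perm)[0, 1])
                        vals.append(1.0 - max(r, 0.0))
                contrib[name] = 100.0 * float(np.mean(vals))
            rows[algo] = contrib
        return pd.DataFrame(rows).T[variables]

    def binarize(self, cutoff: float | None = None) -> np.ndarray:
        return binarize(self.consensus, cutoff if cutoff is not None else self.cutoff)

    def validate(self, validation: OccurrenceSet, high_cutoff: float | None = None,
                 ) -> pd.DataFrame:
        return validate_points(self, validation, high_cutoff)

    def plot_map(self, which: str = "consensus", ax=None, **imshow_kw):
        """Render one of the suitability maps (matplotlib)."""
        import matplotlib.pyplot as plt

        m: SuitabilityMap = getattr(self, which)
        if ax is None:
            _, ax = plt.subplots()
        g = m.grid
        extent = (g.x0, g.x0 + g.n_cols * g.dx, g.y0 - g.n_rows * g.dy, g.y0)
        im = ax.imshow(m.values, vmin=0, vmax=1, extent=extent,
                       origin="upper", **imshow_kw)
        ax.set_title(f"{which} suitability")
        return im


def binarize(suitability: SuitabilityMap, cutoff: float = 0.55) -> np.ndarray:
    """Suitable (1) / unsuitable (0) with NaN on masked cells; closed >= rule."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie strictly between 0 and 1")
    out = np.where(suitability.values >= cutoff, 1.0, 0.0)
    out[~suitability.mask] = np.nan
    return out


def validate_points(result: EnsembleSDMResults, validation: OccurrenceSet,
                    high_cutoff: float | None = None) -> pd.DataFrame:
    """Consensus suitability at independent validation points.

    Returns per-point suitability and an ``above`` flag against the cutoff;
    the counts are in ``df.attrs['n_above'] / ['n_below']``.
    """
    cutoff = high_cutoff if high_cutoff is not None else result.cutoff
    suit = result.consensus.at_points(validation.lon, validation.lat)
    df = pd.DataFrame({"longitude": validation.lon, "latitude": validation.lat,
                       "suitability": suit,
                       "above": suit >= cutoff})
    df.attrs["n_above"] = int(np.nansum(suit >= cutoff))
    df.attrs["n_below"] = int(np.nansum(suit < cutoff))
    return df
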