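"""Synthetic landscapes, occurrences, crop maps, surveys and tree counts.

These generators emulate the statistical structure the downstream analyses
assume — spatially smooth climate fields, a known logistic true-niche surface,
presence sampling proportional to that truth, a three-category crop map, a
farmer survey with a logit-linked attack process and proportional-odds impact
ranks, and clumped (negative-binomial) per-tree counts — so every stage of the
pipeline can be exercised and validated end-to-end without any download.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import (CROP_CATEGORIES, ClimateStack, CropCategoryMap, Grid,
                   OccurrenceSet, SuitabilityMap)

__all__ = [
    "DEFAULT_VARIABLES",
    "TrueNiche",
    "SurveySpec",
    "generate_climate_stack",
    "sample_presences",
    "generate_crop_map",
    "generate_survey_table",
    "generate_tree_counts",
]

# Default variable names and plausible ranges for the six bioclimatic
# predictors retained in the Iberian analysis, so synthetic configs are
# interchangeable with real WorldClim-style data.
DEFAULT_VARIABLES: dict[str, tuple[float, float]] = {
    "BIO3": (30.0, 60.0),     # isothermality (%)
    "BIO7": (20.0, 42.0),     # temperature annual range (deg C)
    "BIO10": (12.0, 30.0),    # mean temperature of warmest quarter (deg C)
    "BIO15": (15.0, 80.0),    # precipitation seasonality (CV %)
    "BIO18": (5.0, 200.0),    # precipitation of warmest quarter (mm)
    "BIO19": (50.0, 450.0),   # precipitation of coldest quarter (mm)
}


@dataclass(frozen=True)
class TrueNiche:
    """Known logistic niche: s = expit(b0 + sum b_i z_i (+ sum g_i z_i^2)).

    Coefficients apply to *z-scored* variables (scored over the stack's valid
    cells), so the same truth is meaningful across stacks with different units.
    """

    intercept: float
    coef: dict[str, float]
    quad: dict[str, float] = field(default_factory=dict)

    def suitability(self, stack: ClimateStack) -> SuitabilityMap:
        eta = np.full(stack.grid.shape, float(self.intercept))
        for name, beta in self.coef.items():
            layer = stack.layers[name]
            mu = np.nanmean(layer)
            sd = np.nanstd(layer)
            z = (layer - mu) / (sd if sd > 0 else 1.0)
            eta = eta + beta * z
            if name in self.quad:
                eta = eta + self.quad[name] * z ** 2
        vals = expit(eta)
        vals[~stack.mask] = np.nan
        return SuitabilityMap(stack.grid, vals, stack.mask.copy())


def generate_climate_stack(seed: int, n_rows: int = 60, n_cols: int = 60,
                           n_vars: int = 6, smoothness: float = 5.0,
                           variables: dict[str, tuple[float, float]] | None = None,
                           mix: float = 0.0,
                           grid: Grid | None = None) -> ClimateStack:
    """Smooth spatial fields of named climate variables.

    Each layer is low-pass-filtered white noise (Gaussian kernel of width
    ``smoothness`` cells) rescaled linearly to the variable's stated range.
    ``mix`` in [0, 1] blends every layer with the first layer's field before
    rescaling, injecting pairwise correlation (``mix=1`` makes all layers
    perfectly correlated; rescaling is affine so correlations survive it).
    """
    if n_vars < 2:
        raise ValueError("need at least two variables")
    if smoothness < 0:
        raise ValueError("smoothness must be non-negative")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must be in [0, 1]")
    if variables is None:
        names = list(DEFAULT_VARIABLES)
        ranges = list(DEFAULT_VARIABLES.values())
        while len(names) < n_vars:
            k = len(names) + 1
            names.append(f"VAR{k}")
            ranges.append((0.0, 1.0))
        names, ranges = names[:n_vars], ranges[:n_vars]
    else:
        names = list(variables)
        ranges = list(variables.values())
    if grid is None:
        grid = Grid(n_rows, n_cols)
    rng = np.random.default_rng(seed)
    fields = []
    for _ in names:
        f = rng.standard_normal(grid.shape)
        if smoothness > 0:
            f = gaussian_filter(f, sigma=smoothness, mode="reflect")
        sd = f.std()
        fields.append((f - f.mean()) / (sd if sd > 0 else 1.0))
    layers: dict[str, np.ndarray] = {}
    for i, (name, (lo, hi)) in enumerate(zip(names, ranges)):
        f = fields[i] if (i == 0 or mix == 0.0) else (
            mix * fields[0] + (1.0 - mix) * fields[i])
        span = f.max() - f.min()
        scaled = lo + (hi - lo) * (f - f.min()) / (span if span > 0 else 1.0)
        layers[name] = scaled
    return ClimateStack(grid, layers)


def sample_presences(stack: ClimateStack, truth: TrueNiche, n: int,
                     seed: int) -> OccurrenceSet:
    """Draw occurrence records with cell probability proportional to the truth.

    Cells are drawn with replacement (a locality can be recorded repeatedly);
    points are placed at cell centers.  Downstream model fitting thins
    duplicates to one presence per cell.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    suit = truth.suitability(stack)
    rows, cols = stack.valid_indices()
    weights = suit.values[rows, cols]
    total = weights.sum()
    if not total > 0:
        raise ValueError("true suitability is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=True, p=weights / total)
    x, y = stack.grid.center(rows[idx], cols[idx])
    return OccurrenceSet.from_points(x, y, source="synthetic", role="train")


def generate_crop_map(stack: ClimateStack | None = None,
                      proportions: tuple[float, float, float] = (0.35, 0.25, 0.40),
                      seed: int = 0, grid: Grid | None = None,
                      smoothness: float = 6.0) -> CropCategoryMap:
    """Three-category crop-suitability map with stated areal proportions.

    Categories (suitable, conditioned, unsuitable) are carved out of a smooth
    latent field by its empirical quantiles, which yields contiguous-ish
    regions whose areas match ``proportions`` to within one cell of rounding.
    If a stack is given, its first layer is the latent field (crop suitability
    then co-varies with climate); otherwise a fresh smooth field is drawn.
    """
    props = np.asarray(proportions, float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if stack is not None:
        grid = stack.grid
        latent = stack.layers[stack.variable_names[0]].copy()
        mask = stack.mask
    else:
        if grid is None:
            grid = Grid(60, 60)
        rng = np.random.default_rng(seed)
        latent = gaussian_filter(rng.standard_normal(grid.shape),
                                 sigma=smoothness, mode="reflect")
        mask = np.ones(grid.shape, bool)
    cats = np.full(grid.shape, CROP_CATEGORIES["nodata"], int)
    vals = latent[mask]
    order = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
    n = vals.size
    bounds = np.floor(np.cumsum(props) * n + 1e-9).astype(int)
    codes = np.full(n, CROP_CATEGORIES["unsuitable"], int)
    codes[order < bounds[0]] = CROP_CATEGORIES["suitable"]
    codes[(order >= bounds[0]) & (order < bounds[1])] = CROP_CATEGORIES["conditioned"]
    cats[mask] = codes
    return CropCategoryMap(grid, cats)


# ---------------------------------------------------------------------------
# Survey and tree counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveySpec:
    """Data-generating process for a synthetic farmer-survey table.

    Field areas are log-normal (ha); surveys of Spanish pistachio growers span
    roughly 0.7-119 ha with a mean near 11, which the defaults reproduce.  Age composition mixes pure
    young / moderate / old fields with Dirichlet-mixed ones.  Attack is
    Bernoulli on a logit linear in area, age percentages and beetle
    suitability; perceived impact (0/1/2), defined only for attacked fields,
    follows a proportional-odds model with two thresholds.
    """

    n_fields: int = 165
    area_log_mean: float = 1.9
    area_log_sd: float = 1.0
    pure_probs: tuple[float, float, float] = (0.25, 0.30, 0.08)
    dirichlet_alpha: tuple[float, float, float] = (2.0, 2.0, 1.0)
    attack_intercept: float = -0.2
    attack_coef: dict[str, float] = field(default_factory=lambda: {
        "area_ha": 0.0, "pct_age_0_3": 0.0, "pct_age_4_8": 0.0,
        "pct_age_gt8": 0.0, "suitability": 0.8})
    impact_coef: dict[str, float] = field(default_factory=lambda: {
        "area_ha": 0.0, "pct_age_0_3": 0.0, "pct_age_4_8": 0.0,
        "pct_age_gt8": 0.0, "suitability": -0.8})
    impact_thresholds: tuple[float, float] = (-0.5, 1.0)
    regions: tuple[str, ...] = ("Castilla-La Mancha", "Andalucia", "Otros")
    region_probs: tuple[float, ...] = (0.75, 0.18, 0.07)

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("n_fields must be positive")
        if self.impact_thresholds[0] >= self.impact_thresholds[1]:
            raise ValueError("impact thresholds must be increasing")


SURVEY_COLUMNS = ["region", "municipality", "area_ha", "pct_age_0_3",
                  "pct_age_4_8", "pct_age_gt8", "attack", "impact",
                  "suitability"]


def generate_survey_table(spec: SurveySpec, suitability: np.ndarray | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic survey in the standard schema (one row per pistachio field)."""
    rng = np.random.default_rng(seed)
    n = spec.n_fields
    area = np.exp(rng.normal(spec.area_log_mean, spec.area_log_sd, n))
    # age composition: pure young / moderate / old fields, remainder mixed
    comp = rng.dirichlet(spec.dirichlet_alpha, size=n) * 100.0
    u = rng.random(n)
    cuts = np.cumsum(spec.pure_probs)
    for k in range(3):
        lo = 0.0 if k == 0 else cuts[k - 1]
        pure = (u >= lo) & (u < cuts[k])
        comp[pure] = 0.0
        comp[pure, k] = 100.0
    if suitability is None:
        suitability = rng.random(n)
    suitability = np.asarray(suitability, float)
    if suitability.shape != (n,):
        raise ValueError("suitability must have one value per field")

    covars = {"area_ha": area, "pct_age_0_3": comp[:, 0],
              "pct_age_4_8": comp[:, 1], "pct_age_gt8": comp[:, 2],
              "suitability": suitability}
    eta = np.full(n, spec.attack_intercept)
    for name, beta in spec.attack_coef.items():
        eta += beta * covars[name]
    attack = rng.random(n) < expit(eta)

    eta_imp = np.zeros(n)
    for name, beta in spec.impact_coef.items():
        eta_imp += beta * covars[name]
    t1, t2 = spec.impact_thresholds
    # cumulative logit: P(Y <= k) = expit(t_k - eta)
    p0 = expit(t1 - eta_imp)
    p01 = expit(t2 - eta_imp)
    v = rng.random(n)
    impact = np.where(v < p0, 0, np.where(v < p01, 1, 2)).astype(float)
    impact[~attack] = np.nan

    region = rng.choice(spec.regions, size=n, p=spec.region_probs)
    return pd.DataFrame({
        "region": region,
        "municipality": [f"M{i:03d}" for i in range(n)],
        "area_ha": area,
        "pct_age_0_3": comp[:, 0],
        "pct_age_4_8": comp[:, 1],
        "pct_age_gt8": comp[:, 2],
        "attack": attack.astype(int),
        "impact": impact,
        "suitability": suitability,
    })


def generate_tree_counts(n_trees: int = 59,
                         mean: float | dict[str, float] = None,  # type: ignore[assignment]
                         dispersion: float | dict[str, float] = None,  # type: ignore[assignment]
                         seed: int = 0) -> pd.DataFrame:
    """Clumped per-tree counts of males, females, copulae and egg clusters.

    Counts are negative binomial with mean ``m`` and dispersion ``k``
    (variance m + m^2/k); small ``k`` concentrates observations on few trees,
    reproducing the strongly right-tailed pattern seen on marked trees.
    ``dispersion = inf`` gives the Poisson limit.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    default_means = {"males": 18.0, "females": 18.0, "copulae": 8.0,
                     "egg_clusters": 1.5}
    default_k = {"males": 0.6, "females": 0.6, "copulae": 0.5,
                 "egg_clusters": 1.8}
    if mean is None:
        means = default_means
    elif np.isscalar(mean):
        means = {c: float(mean) for c in default_means}
    else:
        means = dict(mean)
    if dispersion is None:
        ks = {c: default_k.get(c, 1.0) for c in means}
    elif np.isscalar(dispersion):
        ks = {c: float(dispersion) for c in means}
    else:
        ks = dict(dispersion)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for col, m in means.items():
        if not m > 0:
            raise ValueError(f"mean for {col!r} must be positive")
        k = ks[col]
        if not k > 0:
            raise ValueError(f"dispersion for {col!r} must be positive")
        if np.isinf(k):
            out[col] = rng.poisson(m, n_trees)
        else:
            out[col] = rng.negative_binomial(k, k / (k + m), n_trees)
    df = pd.DataFrame(out)
    df.insert(0, "tree", np.arange(1, n_trees + 1))
    return df
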