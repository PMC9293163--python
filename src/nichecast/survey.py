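"""Field (per-tree) clumping statistics and farmer-survey regressions.

Per-tree counts of males, females, mating pairs and egg clusters are tested
for a clumped (non-normal, right-tailed) distribution via the Shapiro-Wilk
statistic and the sample skewness, and associated across count types with
Pearson correlations.

The survey regressions follow the one-covariate-at-a-time design: a binary
logistic regression of attack (0/1) on each covariate, reported as the
likelihood-ratio chi-square against the intercept-only model with deviance
explained D^2 = (null dev - resid dev)/null dev; and a proportional-odds
(cumulative logit) regression of the impact rank (0/1/2, attacked fields
only) on each covariate, reported as the Wald z-type statistic t = beta/SE
with a McFadden-style D^2.  The ordinal model's df is reported as 2 (its two
threshold parameters), matching the conventional presentation of such survey
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ClumpingResult", "RegressionResult", "read_survey_table",
           "read_tree_counts", "clumping_stats", "count_correlations",
           "attack_logistic", "impact_ordinal", "survey_summaries",
           "survey_regression_table", "COUNT_PAIRS"]

SURVEY_NUMERIC = ("area_ha", "pct_age_0_3", "pct_age_4_8", "pct_age_gt8")


def read_survey_table(path) -> pd.DataFrame:
    """Load a farmer-survey CSV and validate the schema.

    Expected columns: ``region, municipality, area_ha, pct_age_0_3,
    pct_age_4_8, pct_age_gt8, attack, impact[, suitability]``.  Impact must be
    present only on attacked fields; age percentages must sum to 100 +- 0.5.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_NUMERIC + ("attack",) if c not in df.columns]
    if missing:
        raise ValueError(f"survey table lacks column(s) {missing}")
    ages = df[["pct_age_0_3", "pct_age_4_8", "pct_age_gt8"]].sum(axis=1)
    bad = ~np.isclose(ages, 100.0, atol=0.5)
    if bad.any():
        raise ValueError(
            f"age percentages do not sum to 100 at rows {list(df.index[bad])}")
    if not df["attack"].isin([0, 1]).all():
        raise ValueError("attack must be binary 0/1")
    if "impact" in df.columns:
        has_imp = df["impact"].notna()
        if ((df.loc[has_imp, "attack"] == 0).any()):
            raise ValueError("impact is defined only for attacked fields")
        if not df.loc[has_imp, "impact"].isin([0, 1, 2]).all():
            raise ValueError("impact ranks must be 0, 1 or 2")
    if not (df["area_ha"] > 0).all():
        raise ValueError("field areas must be positive")
    return df


def read_tree_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    count_cols = [c for c in df.columns if c != "tree"]
    arr = df[count_cols].to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.rint(arr)):
        raise ValueError("tree counts must be non-negative integers")
    return df


# ---------------------------------------------------------------------------
# Clumping and correlations
# ---------------------------------------------------------------------------

@dataclass
class ClumpingResult:
    W: float            # Shapiro-Wilk statistic
    p: float
    skewness: float     # biased g1 = m3 / m2^(3/2)
    skewness_adjusted: float  # small-sample adjusted G1
    n: int


def clumping_stats(counts: np.ndarray) -> ClumpingResult:
    """Shapiro-Wilk normality test and skewness of a per-tree count vector.

    Large positive skewness with a small W diagnoses the clumped pattern in
    which a few trees accumulate most observations.
    """
    x = np.asarray(counts, float).ravel()
    if x.size < 3:
        raise ValueError("need at least three trees")
    if np.ptp(x) == 0:
        raise ValueError("constant counts: Shapiro-Wilk W is undefined")
    W, p = stats.shapiro(x)
    return ClumpingResult(W=float(W), p=float(p),
                          skewness=float(stats.skew(x, bias=True)),
                          skewness_adjusted=float(stats.skew(x, bias=False)),
                          n=x.size)


# pairs of count columns whose association is of interest; the last pair
# relates mating activity to realized egg laying per mating
COUNT_PAIRS = (("males", "females"),
               ("males", "copulae"),
               ("copulae", "egg_clusters"),
               ("copulae", "egg_clusters_per_copula"))


def count_correlations(table: pd.DataFrame,
                       pairs=COUNT_PAIRS) -> pd.DataFrame:
    """Pearson correlations between per-tree count types.

    The derived column ``egg_clusters_per_copula`` is computed on trees with
    at least one mating pair.  Degenerate (zero-variance) columns are flagged
    with NaN statistics rather than raising.
    """
    df = table.copy()
    if "egg_clusters_per_copula" not in df and {"egg_clusters", "copulae"} <= set(df):
        with np.errstate(divide="ignore", invalid="ignore"):
            df["egg_clusters_per_copula"] = np.where(
                df["copulae"] > 0, df["egg_clusters"] / df["copulae"], np.nan)
    rows = []
    for a, b in pairs:
        sub = df[[a, b]].dropna()
        n = len(sub)
        if n < 3 or sub[a].std(ddof=0) == 0 or sub[b].std(ddof=0) == 0:
            rows.append({"pair": f"{a} vs {b}", "n": n, "r": np.nan,
                         "p": np.nan, "note": "degenerate"})
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"pair": f"{a} vs {b}", "n": n, "r": float(r),
                     "p": float(p), "note": ""})
    return pd.DataFrame(rows).set_index("pair")


# ---------------------------------------------------------------------------
# Survey regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Single-covariate survey regression, formatted for the summary table."""

    covariate: str
    kind: str            # "binary" or "ordinal"
    statistic: float     # LR chi-square (binary) or Wald t (ordinal)
    df: int
    d2: float            # deviance explained
    p: float
    coef: float = np.nan
    se: float = np.nan
    note: str = ""


def attack_logistic(table: pd.DataFrame, covariate: str) -> RegressionResult:
    """Binary logistic regression of attack on one covariate.

    chi^2 is the likelihood-ratio statistic against the intercept-only model
    (df = 1); D^2 the fraction of null deviance explained.  Perfect separation
    is reported as non-estimable, not raised.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    sub = table[[covariate, "attack"]].dropna()
    y = sub["attack"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both attack outcomes must be present")
    x = sub[covariate].to_numpy(float)
    if np.ptp(x) == 0:
        # a constant covariate cannot move the likelihood: LR = 0 exactly
        return RegressionResult(covariate, "binary", 0.0, 1, 0.0, 1.0,
                                coef=0.0, se=np.nan, note="constant covariate")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
        if not np.isfinite(fit.bse).all():
            raise np.linalg.LinAlgError("singular fit")
        llf, llnull = fit.llf, fit.llnull
    except Exception:
        return RegressionResult(covariate, "binary", np.nan, 1, np.nan, np.nan,
                                note="non-estimable (separation or singular fit)")
    lr = max(0.0, 2.0 * (llf - llnull))
    d2 = 0.0 if llnull == 0 else max(0.0, 1.0 - llf / llnull)
    p = float(stats.chi2.sf(lr, df=1))
    return RegressionResult(covariate, "binary", float(lr), 1, float(d2), p,
                            coef=float(fit.params[1]), se=float(fit.bse[1]))


def impact_ordinal(table: pd.DataFrame, covariate: str) -> RegressionResult:
    """Proportional-odds regression of the impact rank on one covariate.

    Fits the cumulative-logit model on attacked fields (ranks 0/1/2), reports
    the Wald z-type statistic t = beta/SE with a two-sided normal p, a
    McFadden-style D^2, and df = 2 for the model's two thresholds.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    sub = table.loc[table["impact"].notna(), [covariate, "impact"]].dropna()
    ranks = sub["impact"].astype(int)
    if ranks.nunique() < 2:
        raise ValueError("need at least two distinct impact ranks")
    endog = pd.Series(pd.Categorical(ranks, categories=sorted(ranks.unique()),
                                     ordered=True))
    exog = sub[[covariate]].to_numpy(float)
    with np.errstate(all="ignore"):
        model = OrderedModel(endog, exog, distr="logit")
        fit = model.fit(method="bfgs", disp=0)
        null = OrderedModel(endog, np.zeros((len(sub), 0)), distr="logit"
                            ).fit(method="bfgs", disp=0)
    beta, se = float(np.asarray(fit.params)[0]), float(np.asarray(fit.bse)[0])
    t = beta / se if se > 0 else np.nan
    p = 2.0 * float(stats.norm.sf(abs(t))) if np.isfinite(t) else np.nan
    d2 = max(0.0, 1.0 - fit.llf / null.llf) if null.llf != 0 else 0.0
    n_thresh = ranks.nunique() - 1
    return RegressionResult(covariate, "ordinal", float(t), n_thresh, float(d2),
                            p, coef=beta, se=se)


def survey_regression_table(table: pd.DataFrame,
                            covariates: list[str] | None = None) -> pd.DataFrame:
    """One-covariate-at-a-time attack and impact regressions, tabulated."""
    if covariates is None:
        covariates = [c for c in (*SURVEY_NUMERIC, "suitability")
                      if c in table.columns]
    rows = []
    for cov in covariates:
        for fn in (attack_logistic, impact_ordinal):
            try:
                r = fn(table, cov)
            except ValueError as exc:
                rows.append({"covariate": cov, "model": fn.__name__,
                             "statistic": np.nan, "df": np.nan, "D2": np.nan,
                             "p": np.nan, "note": str(exc)})
                continue
            rows.append({"covariate": r.covariate,
                         "model": "binary_logistic" if r.kind == "binary"
                                  else "ordered_logistic",
                         "statistic": r.statistic, "df": r.df, "D2": r.d2,
                         "p": r.p, "note": r.note})
    return pd.DataFrame(rows)


def survey_summaries(table: pd.DataFrame) -> dict:
    """Descriptive survey statistics: field counts by age make-up and area."""
    if len(table) == 0:
        return {"n_fields": 0}
    area = table["area_ha"].to_numpy(float)
    young_only = int((table["pct_age_0_3"] >= 100 - 0.5).sum())
    mid_only = int((table["pct_age_4_8"] >= 100 - 0.5).sum())
    old_only = int((table["pct_age_gt8"] >= 100 - 0.5).sum())
    no_old = int((table["pct_age_gt8"] <= 0.5).sum())
    out = {
        "n_fields": int(len(table)),
        "n_attacked": int(table["attack"].sum()),
        "young_only": young_only, "moderate_only": mid_only,
        "old_only": old_only, "no_old_trees": no_old,
        "mixed": int(len(table)) - young_only - mid_only - old_only,
        "area_mean": float(area.mean()),
        "area_se": float(area.std(ddof=1) / np.sqrt(len(area)))
                   if len(area) > 1 else np.nan,
        "area_min": float(area.min()), "area_max": float(area.max()),
    }
    if "region" in table.columns:
        out["per_region"] = table["region"].value_counts().to_dict()
    return out
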