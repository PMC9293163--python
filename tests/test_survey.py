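"""Per-tree clumping statistics and survey regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichecast import (SurveySpec, generate_survey_table, generate_tree_counts)
from nichecast.survey import (attack_logistic, clumping_stats,
                              count_correlations, impact_ordinal,
                              read_survey_table, survey_regression_table,
                              survey_summaries)


class TestClumping:
    def test_normal_sample_near_normal(self):
        rng = np.random.default_rng(0)
        r = clumping_stats(rng.standard_normal(5000))
        assert r.W > 0.99
        assert abs(r.skewness) < 0.1

    def test_concentrated_counts_strongly_skewed(self):
        r = clumping_stats(np.array([0, 0, 0, 0, 10]))
        # direct moment computation: m3/m2^1.5 = 1.5 for this vector
        assert r.skewness == pytest.approx(1.5, abs=1e-12)
        assert r.skewness_adjusted > 1.5
        assert r.W < 0.7

    def test_w_in_unit_interval_and_sign_flip(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(1.0, size=200)
        r = clumping_stats(x)
        r_neg = clumping_stats(-x)
        assert 0 < r.W <= 1
        assert r.skewness == pytest.approx(-r_neg.skewness, rel=1e-9)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            clumping_stats(np.full(10, 3.0))

    def test_overdispersed_counts_flagged_nonnormal(self):
        t = generate_tree_counts(n_trees=59, seed=2)
        for col in ("males", "females", "copulae"):
            r = clumping_stats(t[col].to_numpy())
            assert r.p < 0.01
            assert r.skewness > 0.5


class TestCorrelations:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 60.0)
        df = pd.DataFrame({"males": x, "females": 2 * x,
                           "copulae": x, "egg_clusters": x})
        out = count_correlations(df)
        assert out.loc["males vs females", "r"] == pytest.approx(1.0)
        assert out.loc["males vs females", "p"] < 1e-10

    def test_independent_columns_null_distribution(self):
        # |r| for independent normals at n = 59 stays below the 95% null
        # quantile about 95% of the time
        rng = np.random.default_rng(3)
        crit = stats.t.ppf(0.975, 57)
        r_crit = crit / np.sqrt(57 + crit ** 2)
        hits = 0
        reps = 1000
        for _ in range(reps):
            r = stats.pearsonr(rng.normal(size=59), rng.normal(size=59))[0]
            hits += abs(r) < r_crit
        assert hits / reps == pytest.approx(0.95, abs=0.02)
        assert r_crit == pytest.approx(0.26, abs=0.01)

    def test_degenerate_column_flagged(self):
        df = pd.DataFrame({"males": np.arange(10.0), "females": np.arange(10.0),
                           "copulae": np.zeros(10), "egg_clusters": np.arange(10.0)})
        out = count_correlations(df)
        assert out.loc["males vs copulae", "note"] == "degenerate"
        assert np.isnan(out.loc["males vs copulae", "r"])

    def test_ratio_column_restricted_to_mating_trees(self):
        df = pd.DataFrame({"males": np.arange(6.0),
                           "females": np.arange(6.0),
                           "copulae": np.array([0, 0, 1, 2, 3, 4.0]),
                           "egg_clusters": np.array([0, 1, 1, 2, 3, 4.0])})
        out = count_correlations(df)
        assert out.loc["copulae vs egg_clusters_per_copula", "n"] == 4


class TestAttackLogistic:
    def test_constant_covariate_zero_chi2(self):
        t = generate_survey_table(SurveySpec(n_fields=120), seed=5)
        t["const_cov"] = 7.5
        r = attack_logistic(t, "const_cov")
        assert r.statistic == pytest.approx(0.0, abs=1e-8)
        assert r.d2 == pytest.approx(0.0, abs=1e-10)
        assert r.df == 1

    def test_separation_reported_not_raised(self):
        t = generate_survey_table(SurveySpec(n_fields=80), seed=6)
        t["copy"] = t["attack"].astype(float)
        r = attack_logistic(t, "copy")
        assert "non-estimable" in r.note

    def test_single_outcome_errors(self):
        t = generate_survey_table(SurveySpec(attack_intercept=60.0), seed=7)
        assert (t["attack"] == 1).all()
        with pytest.raises(ValueError):
            attack_logistic(t, "area_ha")

    def test_strong_effect_detected(self):
        spec = SurveySpec(n_fields=300,
                          attack_coef={"area_ha": 0.0, "pct_age_0_3": 0.0,
                                       "pct_age_4_8": 0.0, "pct_age_gt8": 0.0,
                                       "suitability": 4.0},
                          attack_intercept=-2.0)
        t = generate_survey_table(spec, seed=8)
        r = attack_logistic(t, "suitability")
        assert r.p < 1e-4
        assert r.coef > 0


class TestImpactOrdinal:
    def test_strong_positive_effect_gives_large_t(self):
        reps_hit = 0
        for rep in range(20):
            spec = SurveySpec(n_fields=500, attack_intercept=4.0,
                              impact_coef={"area_ha": 0.0, "pct_age_0_3": 0.0,
                                           "pct_age_4_8": 0.0,
                                           "pct_age_gt8": 0.0,
                                           "suitability": 2.0},
                              impact_thresholds=(0.2, 1.8))
            t = generate_survey_table(spec, seed=100 + rep)
            r = impact_ordinal(t, "suitability")
            reps_hit += r.statistic > 3
        assert reps_hit >= 19

    def test_null_covariate_t_centered_on_zero(self):
        ts = []
        for rep in range(60):
            spec = SurveySpec(n_fields=200, attack_intercept=4.0,
                              impact_coef={"area_ha": 0.0, "pct_age_0_3": 0.0,
                                           "pct_age_4_8": 0.0,
                                           "pct_age_gt8": 0.0,
                                           "suitability": 0.0},
                              impact_thresholds=(-0.5, 0.8))
            t = generate_survey_table(spec, seed=200 + rep)
            ts.append(impact_ordinal(t, "suitability").statistic)
        assert abs(np.mean(ts)) < 0.3

    def test_identical_impacts_error(self):
        spec = SurveySpec(attack_intercept=50.0, impact_thresholds=(-40, 40.0))
        t = generate_survey_table(spec, seed=9)
        with pytest.raises(ValueError):
            impact_ordinal(t, "area_ha")

    def test_df_reports_thresholds(self):
        t = generate_survey_table(SurveySpec(n_fields=400,
                                             attack_intercept=4.0), seed=10)
        r = impact_ordinal(t, "suitability")
        assert r.df == 2


class TestSummariesAndTable:
    def test_constructed_four_field_summary(self):
        t = pd.DataFrame({
            "region": ["A", "A", "B", "B"],
            "municipality": list("wxyz"),
            "area_ha": [1.0, 2.0, 4.0, 9.0],
            "pct_age_0_3": [100.0, 0.0, 50.0, 0.0],
            "pct_age_4_8": [0.0, 100.0, 50.0, 0.0],
            "pct_age_gt8": [0.0, 0.0, 0.0, 100.0],
            "attack": [1, 0, 1, 0],
            "impact": [2.0, np.nan, 0.0, np.nan],
        })
        s = survey_summaries(t)
        assert s["n_fields"] == 4 and s["n_attacked"] == 2
        assert s["young_only"] == 1 and s["moderate_only"] == 1
        assert s["old_only"] == 1 and s["mixed"] == 1
        assert s["no_old_trees"] == 3
        assert s["area_mean"] == pytest.approx(4.0)
        assert s["area_min"] == 1.0 and s["area_max"] == 9.0
        assert s["per_region"] == {"A": 2, "B": 2}

    def test_schema_validation_rejects_bad_tables(self, tmp_path):
        t = generate_survey_table(SurveySpec(n_fields=20), seed=11)
        bad = t.copy()
        bad.loc[0, "pct_age_0_3"] += 30.0
        p = tmp_path / "bad.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(ValueError, match="sum to 100"):
            read_survey_table(p)
        bad2 = t.copy()
        bad2.loc[bad2["attack"] == 0, "impact"] = 1.0
        p2 = tmp_path / "bad2.csv"
        bad2.to_csv(p2, index=False)
        with pytest.raises(ValueError, match="attacked"):
            read_survey_table(p2)

    def test_regression_table_shape(self):
        t = generate_survey_table(SurveySpec(n_fields=165), seed=12)
        out = survey_regression_table(t)
        assert len(out) == 10  # 5 covariates x (binary, ordinal)
        assert set(out["model"]) == {"binary_logistic", "ordered_logistic"}
        binary = out[out["model"] == "binary_logistic"]
        assert (binary["df"] == 1).all()
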