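"""Variable selection: correlation distance, Ward clustering oracle, VIF."""

import numpy as np
import pandas as pd
import pytest

from nichecast.grid import ClimateStack, Grid
from nichecast.selection import (SelectionReport, compute_vif,
                                 correlation_distance, select_variables,
                                 vif_filter)


def stack_from_columns(cols: dict[str, np.ndarray], shape=(10, 10)) -> ClimateStack:
    grid = Grid(*shape)
    return ClimateStack(grid, {k: np.asarray(v, float).reshape(shape)
                               for k, v in cols.items()})


def greedy_ward(d: np.ndarray) -> list[float]:
    """Exhaustive greedy Ward agglomeration via the Lance-Williams update.

    Independent oracle: at each step merge the globally closest pair and
    update distances with the Ward formula; returns merge heights in order.
    """
    n = d.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(active) > 1:
        (s, t), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        ns, nt = sizes[s], sizes[t]
        merged = nxt
        nxt += 1
        sizes[merged] = ns + nt
        new = {}
        for v in active:
            if v in (s, t):
                continue
            nv = sizes[v]
            dvs = dist[tuple(sorted((v, s)))]
            dvt = dist[tuple(sorted((v, t)))]
            dst = h
            new_d = np.sqrt(((nv + ns) * dvs ** 2 + (nv + nt) * dvt ** 2
                             - nv * dst ** 2) / (nv + ns + nt))
            new[tuple(sorted((v, merged)))] = new_d
        active = [v for v in active if v not in (s, t)] + [merged]
        dist = {k: val for k, val in dist.items()
                if s not in k and t not in k}
        dist.update(new)
    return heights


class TestDistance:
    def test_distance_properties(self):
        rng = np.random.default_rng(0)
        cols = {f"V{i}": rng.normal(size=100) for i in range(5)}
        d = correlation_distance(pd.DataFrame(cols))
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= -1e-12).all() and (arr <= 1 + 1e-12).all()
        # anti-correlation counts as similarity: d(x, -x) = 0
        cols["neg"] = -cols["V0"]
        d2 = correlation_distance(pd.DataFrame(cols))
        assert d2.loc["V0", "neg"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_layer_errors_by_name(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"A": rng.normal(size=50), "FLAT": np.ones(50)})
        with pytest.raises(ValueError, match="FLAT"):
            correlation_distance(df)


class TestClustering:
    def test_identical_pair_plus_independent(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=100)
        c = rng.normal(size=100)
        stack = stack_from_columns({"A": a, "B": a.copy(), "C": c})
        report = select_variables(stack, threshold=0.3)
        members = sorted(tuple(sorted(v)) for v in report.clusters.values())
        assert members == [("A", "B"), ("C",)]
        assert len(report.selected) == 2

    def test_mutually_uncorrelated_layers_all_selected(self):
        rng = np.random.default_rng(3)
        stack = stack_from_columns({f"V{i}": rng.normal(size=100)
                                    for i in range(5)})
        d = correlation_distance(stack.table())
        assert (d.to_numpy()[np.triu_indices(5, 1)] > 0.3).all()
        report = select_variables(stack, threshold=0.3)
        assert sorted(report.selected) == [f"V{i}" for i in range(5)]
        assert len(report.clusters) == 5

    def test_threshold_extremes(self):
        rng = np.random.default_rng(4)
        stack = stack_from_columns({f"V{i}": rng.normal(size=100)
                                    for i in range(4)})
        one = select_variables(stack, threshold=2.0)
        assert len(one.clusters) == 1
        tiny = select_variables(stack, threshold=1e-12)
        assert len(tiny.clusters) == 4  # only exact duplicates merge below 0

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_greedy_ward_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_vars = int(rng.integers(3, 7))
        base = rng.normal(size=(120, n_vars))
        # inject some correlation so merges are non-trivial
        base[:, 0] = base[:, 0] + base[:, -1]
        cols = {f"V{i}": base[:, i] for i in range(n_vars)}
        stack = stack_from_columns(cols, shape=(12, 10))
        report = select_variables(stack, threshold=0.3)
        d = 1.0 - stack.table().corr().abs().to_numpy()
        np.fill_diagonal(d, 0.0)
        expected = greedy_ward(d)
        np.testing.assert_allclose(np.sort(report.merge_heights),
                                   np.sort(expected), rtol=1e-10)

    def test_force_keep_overrides_representative(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=100)
        b = a + 0.01 * rng.normal(size=100)  # tightly correlated pair
        stack = stack_from_columns({"A": a, "B": b})
        rep = select_variables(stack, force_keep=["A"])
        assert rep.selected == ["A"]
        rep2 = select_variables(stack, force_keep=["B"])
        assert rep2.selected == ["B"]


class TestVIF:
    def test_two_predictors_r08_closed_form(self):
        # VIF = 1/(1 - r^2) = 1/(1 - 0.64) = 2.7778 for both
        rng = np.random.default_rng(7)
        n = 200_000
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        df = pd.DataFrame({"X": x, "Y": y})
        r = np.corrcoef(x, y)[0, 1]
        vifs = compute_vif(df)
        expected = 1.0 / (1.0 - r ** 2)
        assert vifs["X"] == pytest.approx(expected, abs=1e-6)
        assert vifs["Y"] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(1 / (1 - 0.64), rel=0.02)

    def test_orthogonal_predictors_vif_one(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({"A": np.cos(2 * np.pi * t / n),
                           "B": np.sin(2 * np.pi * t / n),
                           "C": np.cos(4 * np.pi * t / n)})
        vifs = compute_vif(df)
        assert np.allclose(vifs.to_numpy(), 1.0, atol=1e-6)

    def test_exact_collinearity_dropped_with_finite_remainder(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        stack = stack_from_columns({"A": a, "B": b, "SUM": a + b})
        vifs = compute_vif(stack.table())
        assert np.isinf(vifs).all()  # each is a linear combo of the others
        report = select_variables(stack, threshold=0.3)
        report = vif_filter(stack, report, max_vif=5.0)
        assert len(report.dropped) == 1
        assert np.isfinite(report.vif_steps[-1][report.selected]).all()
        assert (report.vif_steps[-1][report.selected] <= 5.0).all()

    def test_agrees_with_statsmodels_vif(self):
        from statsmodels.stats.outliers_influence import \
            variance_inflation_factor as sm_vif
        rng = np.random.default_rng(10)
        base = rng.normal(size=(300, 4))
        base[:, 1] = 0.7 * base[:, 0] + 0.3 * base[:, 1]
        df = pd.DataFrame(base, columns=list("ABCD"))
        ours = compute_vif(df)
        z = ((df - df.mean()) / df.std(ddof=0)).to_numpy()
        X = np.column_stack([np.ones(len(z)), z])
        theirs = [sm_vif(X, i + 1) for i in range(4)]
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=1e-8)

    def test_vif_at_least_one_and_filter_bound(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(200, 5))
        base[:, 1] = 0.95 * base[:, 0] + 0.05 * base[:, 1]
        stack = stack_from_columns({f"V{i}": base[:, i] for i in range(5)},
                                   shape=(20, 10))
        report = SelectionReport(
            candidates=stack.variable_names,
            correlation=stack.table().corr(),
            merge_heights=np.array([]), clusters={}, representatives={},
            threshold=0.3, selected=list(stack.variable_names))
        report = vif_filter(stack, report, max_vif=5.0)
        final = report.vif_steps[-1][report.selected]
        assert (final >= 1.0 - 1e-9).all()
        assert final.max() <= 5.0
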