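"""Covariate extraction and the statistical battery.

The RDA / variation-partitioning implementation is cross-checked against an
independent constrained-ordination oracle (R vegan's rda / RsquareAdj /
varpart) on a frozen fixture; the oracle's outputs are frozen below so the
suite runs without R.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beescape.landscape_stats import (
    best_subset_regression,
    extract_covariates,
    rda,
    select_parsimonious,
    spearman_fdr,
    varpart3,
    vif_screen,
)


# --- independent oracles ----------------------------------------------------


def bh_stepup(pvals):
    """Brute-force Benjamini-Hochberg from the step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end  # rank of this p-value (1-based)
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


# --- extraction -------------------------------------------------------------


class TestExtractCovariates:
    def _tables(self):
        overlaps = pd.DataFrame(
            [
                (0, "income", "a", 1.0),
                (1, "income", "a", 0.3),
                (1, "income", "b", 0.7),
                (0, "parks", "p1", 0.25),
                (1, "parks", "p2", 0.1),
            ],
            columns=["cell_id", "layer", "feature_id", "fraction"],
        )
        attributes = pd.DataFrame(
            [("income", "a", 10.0), ("income", "b", 20.0)],
            columns=["layer", "feature_id", "value"],
        )
        points = pd.DataFrame([(0, "trees")] * 3 + [(1, "trees")], columns=["cell_id", "layer"])
        return overlaps, attributes, points

    def test_cell_fully_inside_one_polygon(self):
        overlaps, attributes, points = self._tables()
        out = extract_covariates(overlaps, attributes, {"income": "wavg"}, points)
        assert out.loc[out.cell_id == 0, "income"].iloc[0] == pytest.approx(10.0)

    def test_weighted_average_hand_computed(self):
        # 30% at 10 + 70% at 20 -> 17.0
        overlaps, attributes, points = self._tables()
        out = extract_covariates(overlaps, attributes, {"income": "wavg"}, points)
        assert out.loc[out.cell_id == 1, "income"].iloc[0] == pytest.approx(17.0)

    def test_percent_mode(self):
        overlaps, attributes, points = self._tables()
        out = extract_covariates(overlaps, attributes, {"parks": "percent"})
        assert out.loc[out.cell_id == 0, "parks"].iloc[0] == pytest.approx(25.0)

    def test_count_mode_and_zero_fill(self):
        overlaps, attributes, points = self._tables()
        out = extract_covariates(overlaps, attributes, {"trees": "count"}, points, cell_ids=[0, 1, 2])
        assert out.set_index("cell_id")["trees"].tolist() == [3, 1, 0]

    def test_unknown_mode_rejected(self):
        overlaps, attributes, points = self._tables()
        with pytest.raises(ValueError, match="unknown extraction mode"):
            extract_covariates(overlaps, attributes, {"income": "median"})

    def test_fraction_sum_above_one_rejected(self):
        bad = pd.DataFrame(
            [(0, "x", "a", 0.8), (0, "x", "b", 0.5)],
            columns=["cell_id", "layer", "feature_id", "fraction"],
        )
        with pytest.raises(ValueError, match="sum above 1"):
            extract_covariates(bad, None, {"x": "percent"})


# --- Spearman + BH ----------------------------------------------------------


class TestSpearmanFdr:
    def test_monotone_relationship_is_one(self):
        x = pd.Series(np.arange(10, dtype=float))
        t = pd.DataFrame({"x": x, "y": 2 * x + 3})
        rho, _ = spearman_fdr(t)
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self):
        x = np.arange(10, dtype=float)
        t = pd.DataFrame({"x": x, "y": -x})
        rho, _ = spearman_fdr(t)
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_rho_equals_pearson_on_midranks(self):
        # with ties: Spearman must equal Pearson applied to mid-ranked data
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.integers(0, 5, size=30).astype(float)
            b = rng.integers(0, 5, size=30).astype(float)
            t = pd.DataFrame({"a": a, "b": b})
            rho, _ = spearman_fdr(t)
            ra = stats.rankdata(a)
            rb = stats.rankdata(b)
            assert rho.loc["a", "b"] == pytest.approx(stats.pearsonr(ra, rb)[0], abs=1e-12)

    def test_bh_known_example(self):
        # p = (.01,.02,.03,.04,.05) with m=5: all adjust to 0.05
        assert np.allclose(bh_stepup([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05)

    def test_bh_matches_bruteforce_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        grid_vals = np.round(np.arange(0.01, 1.01, 0.01), 2)
        # exhaustive for length 2
        for p1, p2 in combinations(grid_vals[::7], 2):
            _, adj, _, _ = multipletests([p1, p2], method="fdr_bh")
            assert np.allclose(adj, bh_stepup([p1, p2]), atol=1e-12)
        # randomized grid vectors for lengths 3..6
        for m in range(3, 7):
            for _ in range(200):
                p = rng.choice(grid_vals, size=m)
                _, adj, _, _ = multipletests(p, method="fdr_bh")
                assert np.allclose(adj, bh_stepup(p), atol=1e-12)

    def test_adjusted_p_covers_tested_pairs(self):
        rng = np.random.default_rng(14)
        t = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        rho, padj = spearman_fdr(t)
        assert padj.shape == (4, 4)
        assert np.allclose(padj.to_numpy(), padj.to_numpy().T)


# --- VIF --------------------------------------------------------------------


class TestVifScreen:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        X = pd.DataFrame({"s": np.sin(t), "c": np.cos(t), "s2": np.sin(2 * t)})
        out = vif_screen(X)
        assert np.allclose(out["vif"], 1.0, atol=1e-8)

    def test_correlated_pair_closed_form(self):
        # two predictors with r = 0.9, third orthogonal: VIF = 1/(1-0.81)
        rng = np.random.default_rng(15)
        n = 20000
        z = rng.standard_normal(n)
        x1 = z
        x2 = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        out = vif_screen(pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}))
        expected = 1 / (1 - 0.81)
        assert out.loc[out.variable == "x1", "vif"].iloc[0] == pytest.approx(expected, rel=0.05)
        assert out.loc[out.variable == "x2", "vif"].iloc[0] == pytest.approx(expected, rel=0.05)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(30)
        out = vif_screen(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)}))
        assert np.isinf(out.loc[out.variable == "a", "vif"].iloc[0])

    def test_keep_list_is_advisory(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": x + 1e-8 * rng.standard_normal(30)})
        out = vif_screen(X, keep=("a",)).set_index("variable")
        assert bool(out.loc["a", "flagged"]) and not bool(out.loc["a", "recommend_drop"])
        assert bool(out.loc["b", "recommend_drop"])


# --- best-subset regression -------------------------------------------------


class TestBestSubset:
    def test_exact_linear_pair_wins(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame(rng.standard_normal((40, 6)), columns=[f"x{i}" for i in range(6)])
        y = pd.Series(2.0 * X.x1 - 3.0 * X.x4, name="y")
        models = best_subset_regression(y, X, max_size=3)
        best = select_parsimonious(models)
        assert set(best.predictors) == {"x1", "x4"}
        assert best.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_noise_predictor_lowers_adjusted_r2_majority(self):
        # adding a pure-noise predictor reduces adjusted R^2 iff its partial
        # F < 1, which happens with probability P(F(1, n-3) < 1) ~ 0.68; a
        # clear majority of replicates (n = 49) must drop
        rng = np.random.default_rng(19)
        worse = 0
        reps = 200
        for _ in range(reps):
            x = rng.standard_normal(49)
            noise = rng.standard_normal(49)
            y = pd.Series(x + 0.5 * rng.standard_normal(49), name="y")
            X1 = pd.DataFrame({"x": x})
            X2 = pd.DataFrame({"x": x, "junk": noise})
            m1 = best_subset_regression(y, X1, max_size=1)[0]
            m2 = [m for m in best_subset_regression(y, X2, max_size=2) if set(m.predictors) == {"x", "junk"}][0]
            worse += m2.adj_r2 < m1.adj_r2
        assert worse >= 0.6 * reps

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame({"x": rng.standard_normal(30)})
        y = pd.Series(X.x + rng.standard_normal(30), name="y")
        models = best_subset_regression(y, X, max_size=1)
        assert len(models) == 1 and models[0].predictors == ("x",)

    def test_variance_explained_is_adj_r2_drop(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
        y = pd.Series(X.a + 0.5 * X.b + rng.standard_normal(40), name="y")
        models = best_subset_regression(y, X, max_size=3)
        full = [m for m in models if set(m.predictors) == {"a", "b", "c"}][0]
        sub_ab = [m for m in models if set(m.predictors) == {"a", "b"}][0]
        assert full.variance_explained["c"] == pytest.approx(full.adj_r2 - sub_ab.adj_r2, abs=1e-12)

    def test_requires_enough_observations(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((8, 6)))
        y = pd.Series(np.arange(8.0), name="y")
        with pytest.raises(ValueError):
            best_subset_regression(y, X, max_size=6)


# --- RDA --------------------------------------------------------------------


class TestRda:
    def test_single_response_equals_ols_r2(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        y = X.a - 0.5 * X.c + rng.standard_normal(30)
        res = rda(pd.DataFrame({"y": y}), X, n_perm=99, seed=0)
        Xs = (X - X.mean()) / X.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ols = sm.OLS(ys, sm.add_constant(Xs)).fit()
        assert res.r2 == pytest.approx(ols.rsquared, abs=1e-10)

    def test_matches_vegan_oracle_frozen(self):
        # fixture: seed-42 normal draws, n=20, 5 predictors, 2 responses
        rng = np.random.default_rng(42)
        n = 20
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=["x1", "x2", "x3", "x4", "x5"])
        Y = pd.DataFrame(
            {
                "y1": 0.8 * X.x1 - 0.5 * X.x3 + rng.standard_normal(n) * 0.7,
                "y2": 0.6 * X.x2 + 0.4 * X.x4 + rng.standard_normal(n) * 0.7,
            }
        )
        X = X.round(6)
        Y = Y.round(6)
        res = rda(Y, X, n_perm=99, seed=1)
        # frozen vegan 2.7-1 outputs: rda(scale(Y) ~ ., data=scale(X))
        assert res.eigenvalues[0] == pytest.approx(0.8357889268, abs=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.2419460612, abs=1e-9)
        assert res.r2 == pytest.approx(0.5388674940, abs=1e-9)
        assert res.adj_r2 == pytest.approx(0.3741773133, abs=1e-9)

    def test_orthogonal_responses_null(self):
        # responses constructed orthogonal to predictors
        n = 40
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        X = pd.DataFrame({"a": np.sin(t), "b": np.cos(t)})
        Y = pd.DataFrame({"y1": np.sin(3 * t), "y2": np.cos(3 * t)})
        res = rda(Y, X, n_perm=199, seed=2)
        assert res.r2 < 0.01
        assert res.perm_p > 0.5

    def test_proportions_of_model_sum_to_one(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.standard_normal((25, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.standard_normal((25, 2)), columns=["y1", "y2"])
        res = rda(Y, X, n_perm=49, seed=3)
        assert res.proportion_of_model.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)), columns=["a", "b"])
        Y = pd.DataFrame({"y": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            rda(Y, X, n_perm=9)

    def test_permutation_p_uniform_under_null(self):
        # 49 rows x 10 predictors, 200 replicate null datasets
        rng = np.random.default_rng(24)
        ps = []
        for rep in range(200):
            X = pd.DataFrame(rng.standard_normal((49, 10)), columns=[f"x{i}" for i in range(10)])
            Y = pd.DataFrame(rng.standard_normal((49, 2)), columns=["y1", "y2"])
            ps.append(rda(Y, X, n_perm=199, seed=rep).perm_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


# --- variation partitioning -------------------------------------------------


class TestVarpart:
    def test_matches_vegan_oracle_frozen(self):
        rng = np.random.default_rng(42)
        n = 20
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=["x1", "x2", "x3", "x4", "x5"])
        Y = pd.DataFrame(
            {
                "y1": 0.8 * X.x1 - 0.5 * X.x3 + rng.standard_normal(n) * 0.7,
                "y2": 0.6 * X.x2 + 0.4 * X.x4 + rng.standard_normal(n) * 0.7,
            }
        )
        X = X.round(6)
        Y = Y.round(6)
        vp = varpart3(Y, X[["x1", "x2"]], X[["x3", "x4"]], X[["x5"]], names=("s1", "s2", "s3"))
        # frozen vegan varpart indfract column
        assert vp.unique["s1"] == pytest.approx(0.188770483, abs=1e-8)
        assert vp.unique["s2"] == pytest.approx(0.151793329, abs=1e-8)
        assert vp.unique["s3"] == pytest.approx(0.009204577, abs=1e-8)
        assert vp.pair_shared[("s1", "s2")] == pytest.approx(0.061771407, abs=1e-8)
        assert vp.pair_shared[("s2", "s3")] == pytest.approx(0.017820429, abs=1e-8)
        assert vp.pair_shared[("s1", "s3")] == pytest.approx(-0.037822393, abs=1e-8)
        assert vp.triple_shared == pytest.approx(-0.017360520, abs=1e-8)
        assert vp.residual == pytest.approx(0.625822687, abs=1e-8)

    def test_orthogonal_sets_additive_response(self):
        # orthogonal single-predictor sets: unique fractions ~ per-set adjusted
        # R^2, shared fractions ~ 0 (exact only asymptotically: the
        # adjusted-R^2 penalty depends on model size, so use a larger n)
        n = 200
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x1, x2, x3 = np.sin(t), np.cos(t), np.sin(2 * t)
        y = 1.0 * x1 + 0.5 * x2 + 0.25 * x3
        Y = pd.DataFrame({"y": y})
        from beescape.landscape_stats import _rda_adj_r2

        vp = varpart3(Y, pd.DataFrame({"x1": x1}), pd.DataFrame({"x2": x2}), pd.DataFrame({"x3": x3}))
        assert vp.unique["set1"] == pytest.approx(_rda_adj_r2(Y, pd.DataFrame({"x1": x1})), abs=0.02)
        assert abs(vp.pair_shared[("set1", "set2")]) < 0.02
        assert abs(vp.triple_shared) < 0.02

    def test_duplicated_set_moves_to_shared(self):
        rng = np.random.default_rng(25)
        x = rng.standard_normal(40)
        z = rng.standard_normal(40)
        y = pd.DataFrame({"y": x + 0.3 * rng.standard_normal(40)})
        s1 = pd.DataFrame({"a": x})
        s2 = pd.DataFrame({"b": x + 1e-6 * rng.standard_normal(40)})
        s3 = pd.DataFrame({"c": z})
        vp = varpart3(y, s1, s2, s3)
        assert abs(vp.unique["set1"]) < 0.02
        assert vp.pair_shared[("set1", "set2")] > 0.5

    def test_fraction_sum_identity(self):
        rng = np.random.default_rng(26)
        Y = pd.DataFrame(rng.standard_normal((30, 2)), columns=["y1", "y2"])
        s1 = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a1", "a2"])
        s2 = pd.DataFrame(rng.standard_normal((30, 2)), columns=["b1", "b2"])
        s3 = pd.DataFrame(rng.standard_normal((30, 1)), columns=["c1"])
        vp = varpart3(Y, s1, s2, s3)
        assert vp.total_explained() == pytest.approx(vp.full_adj_r2, abs=1e-9)
        assert vp.total_explained() + vp.residual == pytest.approx(1.0, abs=1e-9)
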