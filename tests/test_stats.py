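"""Concordance statistics: Spearman, tertile kappa, Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosig.stats import (
    cohens_kappa,
    group_comparisons,
    mann_whitney,
    per_gene_comparison,
    spearman_matrix,
    tertile_dichotomize,
)


class TestSpearmanMatrix:
    def test_diagonal_is_one(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [4, 1, 3, 2]}, dtype=float)
        rho, _ = spearman_matrix(df)
        assert rho.loc["a", "a"] == 1.0 and rho.loc["b", "b"] == 1.0

    def test_reversed_ranking_is_minus_one(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]}, dtype=float)
        assert spearman_matrix(df)[0].loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_value(self):
        # ranks d^2 sum = 2 -> rho = 1 - 6*2/(4*15) = 0.8
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]}, dtype=float)
        assert spearman_matrix(df)[0].loc["x", "y"] == pytest.approx(0.8)

    def test_pairwise_complete_and_n_recorded(self):
        df = pd.DataFrame(
            {"a": [1, 2, 3, 4, np.nan], "b": [2, 1, 4, np.nan, 5]}, dtype=float
        )
        rho, n = spearman_matrix(df)
        assert n.loc["a", "b"] == 3
        assert np.isfinite(rho.loc["a", "b"])

    def test_too_few_pairs_undefined(self):
        df = pd.DataFrame({"a": [1, np.nan, 3], "b": [np.nan, 2, 3]}, dtype=float)
        rho, _ = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        df1 = pd.DataFrame({"a": x, "b": y})
        df2 = pd.DataFrame({"a": np.exp(x), "b": y**3})
        assert spearman_matrix(df1)[0].loc["a", "b"] == pytest.approx(
            spearman_matrix(df2)[0].loc["a", "b"]
        )


class TestTertileDichotomize:
    def test_six_distinct_values_two_high(self):
        s = pd.Series([10.0, 5, 8, 1, 7, 3], index=list("abcdef"))
        labels = tertile_dichotomize(s)
        assert (labels == "high").sum() == 2
        assert set(labels[labels == "high"].index) == {"a", "c"}

    def test_cohort_of_132_gives_44_high(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=132))
        assert (tertile_dichotomize(s) == "high").sum() == math.ceil(132 / 3) == 44

    def test_constant_vector_all_intermediate_low(self):
        s = pd.Series([2.0] * 9)
        assert (tertile_dichotomize(s) == "intermediate-low").all()

    def test_ties_at_cut_resolved_by_stable_id_order(self):
        s = pd.Series({"s1": 5.0, "s2": 5.0, "s3": 5.0, "s4": 1.0, "s5": 0.0,
                       "s6": 0.0})
        labels = tertile_dichotomize(s)
        assert list(labels[labels == "high"].index) == ["s1", "s2"]

    def test_missing_values_stay_missing(self):
        s = pd.Series([3.0, np.nan, 2.0, 1.0, 5.0, 4.0])
        labels = tertile_dichotomize(s)
        assert labels.isna().sum() == 1

    def test_kappa_of_score_with_itself_is_one(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.normal(size=30))
        labels = tertile_dichotomize(s)
        assert cohens_kappa(labels, labels) == pytest.approx(1.0)


class TestCohensKappa:
    def test_identical_vectors(self):
        assert cohens_kappa(list("AABB"), list("AABB")) == pytest.approx(1.0)

    def test_chance_level_zero(self):
        assert cohens_kappa(list("AABB"), list("ABAB")) == pytest.approx(0.0)

    def test_2x2_hand_table(self):
        # [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.choice(list("XYZ"), size=60).tolist()
        b = rng.choice(list("XYZ"), size=60).tolist()
        k = cohens_kappa(a, b)
        assert cohens_kappa(b, a) == pytest.approx(k)
        relabel = {"X": "1", "Y": "2", "Z": "3"}
        assert cohens_kappa([relabel[v] for v in a],
                            [relabel[v] for v in b]) == pytest.approx(k)

    def test_constant_identical_raters_convention(self):
        assert cohens_kappa(["A"] * 5, ["A"] * 5) == 1.0

    def test_missing_pairs_dropped(self):
        assert cohens_kappa(["A", None, "B"], ["A", "B", "B"]) == pytest.approx(1.0)

    def test_matches_sklearn_on_random_multiclass(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.choice(list("PQRS"), size=40)
            b = rng.choice(list("PQRS"), size=40)
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled values
    to the two groups; two-tailed p = min(1, 2 * min(P(U <= u), P(U >= u)))."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    u_obs = u_stat(x, y)
    us = []
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        # 2 / C(6,3) = 0.1 under exact enumeration
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.mode == "exact"
        assert res.p == pytest.approx(0.1)

    def test_two_vs_two(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.p == pytest.approx(2 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_or_tied_samples_use_approximation(self):
        assert mann_whitney(list(range(10)), list(range(10, 20))).mode == "approximate"
        assert mann_whitney([1, 1, 2], [2, 3, 4]).mode == "approximate"

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        nx=st.integers(1, 6),
        ny=st.integers(1, 6),
        data=st.data(),
    )
    def test_exact_mode_matches_brute_force_enumeration(self, nx, ny, data):
        """Exact-mode p equals the full-enumeration oracle for all group
        sizes up to 6 (distinct values, so the exact path is taken)."""
        vals = data.draw(
            st.lists(
                st.integers(-50, 50), min_size=nx + ny, max_size=nx + ny,
                unique=True,
            )
        )
        x, y = vals[:nx], vals[nx:]
        res = mann_whitney(x, y)
        assert res.mode == "exact"
        assert res.p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)


class TestGroupComparisons:
    def test_identical_groups_p_one(self):
        scores = pd.DataFrame({"s": [1.0, 2, 3, 1, 2, 3]},
                              index=[f"x{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        out = group_comparisons(scores, groups)
        assert out["s"].loc["a", "b"] == pytest.approx(1.0)

    def test_non_applicable_group_cell_is_nan(self):
        scores = pd.DataFrame(
            {"s": [1.0, 2, np.nan, np.nan]}, index=list("wxyz")
        )
        groups = pd.Series(["a", "a", "b", "b"], index=scores.index)
        out = group_comparisons(scores, groups)
        assert np.isnan(out["s"].loc["a", "b"])

    def test_upper_triangular_layout(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame({"s": rng.normal(size=30)})
        groups = pd.Series(rng.choice(["a", "b", "c"], size=30), index=scores.index)
        mat = group_comparisons(scores, groups, group_order=["a", "b", "c"])["s"]
        assert np.isnan(mat.loc["b", "a"]) and np.isfinite(mat.loc["a", "b"])


class TestPerGeneComparison:
    def _expr(self, rng, shift_genes=(), n=12, shift=2.0):
        genes = [f"g{i}" for i in range(10)]
        a = rng.normal(size=(10, n))
        b = rng.normal(size=(10, n))
        for g in shift_genes:
            b[genes.index(g)] += shift
        vals = np.hstack([a, b])
        cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        expr = pd.DataFrame(vals, index=genes, columns=cols)
        groups = pd.Series(["a"] * n + ["b"] * n, index=cols)
        return expr, groups

    def test_identical_distributions_all_p_one(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 1, 2, 3], [4.0, 5, 6, 4, 5, 6]],
            index=["g1", "g2"],
            columns=list("uvwxyz"),
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=list("uvwxyz"))
        out = per_gene_comparison(expr, groups, ("a", "b"))
        assert (out["p"] == 1.0).all()

    def test_shifted_genes_rank_first(self):
        rng = np.random.default_rng(6)
        expr, groups = self._expr(rng, shift_genes=("g3", "g7"))
        out = per_gene_comparison(expr, groups, ("a", "b"))
        assert set(out.index[:2]) == {"g3", "g7"}

    def test_constant_gene_flagged(self):
        expr = pd.DataFrame([[1.0] * 6], index=["flat"], columns=list("uvwxyz"))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=list("uvwxyz"))
        out = per_gene_comparison(expr, groups, ("a", "b"))
        assert out.loc["flat", "p"] == 1.0 and out.loc["flat", "mode"] == "constant"

    def test_bh_adjustment_optional(self):
        rng = np.random.default_rng(7)
        expr, groups = self._expr(rng)
        out = per_gene_comparison(expr, groups, ("a", "b"), adjust="bh")
        assert "q" in out.columns and (out["q"] >= out["p"] - 1e-12).all()

    def test_empty_group_rejected(self):
        expr = pd.DataFrame([[1.0, 2, 3]], index=["g"], columns=list("uvw"))
        groups = pd.Series(["a"] * 3, index=list("uvw"))
        with pytest.raises(ValueError):
            per_gene_comparison(expr, groups, ("a", "b"))
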