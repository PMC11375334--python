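import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microsubtype import (
    AbundanceTable,
    SampleMetadata,
    adjust_pvalues,
    clinical_association,
    common_differential,
    contingency_chi2,
    kruskal_wallis,
    lda_effect_size,
)


def exact_kw_tail(values, groups):
    """Independent enumeration oracle for the KW permutation p-value.

    Ranks the pooled values once, then walks every distinct assignment of
    group labels to positions (multiset permutations) accumulating the
    tie-corrected H tail probability.
    """
    from sympy.utilities.iterables import multiset_permutations

    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values)
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)

    def h_of(label_seq):
        h = 0.0
        for g in set(label_seq):
            mask = np.array([l == g for l in label_seq])
            h += ranks[mask].sum() ** 2 / mask.sum()
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        return h / tie if tie > 0 else 0.0

    h_obs = h_of(list(groups))
    hits = total = 0
    for perm in multiset_permutations(list(groups)):
        total += 1
        if h_of(perm) >= h_obs - 1e-12:
            hits += 1
    return h_obs, hits / total


class TestKruskalWallis:
    def test_textbook_three_group_example(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9], list("aaabbbccc"))
        assert h == pytest.approx(7.2)

    def test_all_identical_values_degenerate(self):
        h, p = kruskal_wallis([5.0] * 6, list("aabbcc"))
        assert (h, p) == (0.0, 1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        groups = list("aaaabbbbcccc")
        h1, _ = kruskal_wallis(x, groups)
        h2, _ = kruskal_wallis(np.exp(3 * x) + 7, groups)
        assert h1 == pytest.approx(h2, abs=1e-9)

    @pytest.mark.parametrize(
        "values,groups",
        [
            ([3, 1, 4, 1, 5, 9, 2, 6, 5], list("aaabbbccc")),  # with ties
            ([1, 1, 2, 2, 3, 3, 4, 4], list("aabbccdd")),
            ([10, 20, 30, 10, 50, 60], list("aaabbb")),
        ],
    )
    def test_permutation_p_matches_enumeration_oracle(self, values, groups):
        h_impl, p_impl = kruskal_wallis(values, groups, method="permutation")
        h_oracle, p_oracle = exact_kw_tail(values, groups)
        assert h_impl == pytest.approx(h_oracle, abs=1e-9)
        assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_chi2_approximation_near_exact_at_small_n(self):
        values = [3, 1, 4, 1, 5, 9, 2, 6, 5]
        groups = list("aaabbbccc")
        _, p_chi2 = kruskal_wallis(values, groups)
        _, p_exact = kruskal_wallis(values, groups, method="permutation")
        assert abs(p_chi2 - p_exact) < 0.1


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert (adjust_pvalues([1.0, 1.0, 1.0]) == 1.0).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6), st.integers(min_value=1, max_value=40))
    def test_bh_never_below_raw_and_rank_monotone(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        q = adjust_pvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bonferroni(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.3], "bonferroni"), [0.02, 0.6])


def rel_table(values, taxa):
    frame = pd.DataFrame(
        values, index=[f"s{i}" for i in range(len(values))], columns=taxa
    )
    frame = frame.div(frame.sum(axis=1), axis=0)
    return AbundanceTable(frame, is_relative=True)


class TestLdaEffectSize:
    def test_extreme_taxon_scores_six(self, rng):
        # one taxon carries the whole community in group A, none in B
        n = 20
        a = np.column_stack([np.full(n, 1.0), rng.random(n) * 1e-9 + 1e-9])
        b = np.column_stack([np.full(n, 1e-12), np.ones(n)])
        table = rel_table(np.vstack([a, b]), ["marker", "filler"])
        groups = ["A"] * n + ["B"] * n
        out = lda_effect_size(table, groups, alpha=0.05, lda_cutoff=2.0, seed=0)
        row = out[out["taxon"] == "marker"].iloc[0]
        assert row["lda_score"] == pytest.approx(6.0, abs=0.05)
        assert row["enriched_group"] == "A"

    def test_alpha_zero_empty(self, rng):
        table = rel_table(rng.random((12, 4)) + 0.1, list("wxyz"))
        out = lda_effect_size(table, ["A"] * 6 + ["B"] * 6, alpha=0.0)
        assert out.empty

    def test_output_shrinks_as_cutoff_grows(self, rng):
        vals = rng.random((40, 8)) + 0.05
        vals[:20, :4] *= 3  # several shifted taxa
        table = rel_table(vals, [f"t{i}" for i in range(8)])
        groups = ["A"] * 20 + ["B"] * 20
        sizes = [
            len(lda_effect_size(table, groups, lda_cutoff=c, seed=1))
            for c in (1.0, 3.0, 5.0)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_small_group_excluded_with_warning(self, rng):
        table = rel_table(rng.random((11, 3)) + 0.1, list("abc"))
        groups = ["A"] * 5 + ["B"] * 4 + ["C"] * 2
        with pytest.warns(UserWarning, match="excluding"):
            lda_effect_size(table, groups)

    def test_null_data_few_false_positives(self, rng):
        # identical generators in both groups: expected hits <= alpha * m
        m, hits, reps = 30, 0, 40
        for rep in range(reps):
            vals = rng.random((30, m)) + 0.05
            table = rel_table(vals, [f"t{i}" for i in range(m)])
            out = lda_effect_size(
                table, ["A"] * 15 + ["B"] * 15, alpha=0.05, lda_cutoff=0.0, seed=rep
            )
            hits += len(out)
        rate = hits / (reps * m)
        assert rate < 0.05 + 3 * math.sqrt(0.05 * 0.95 / (reps * m))


class TestClinicalAssociation:
    @staticmethod
    def meta_with(cov):
        return [
            SampleMetadata(f"s{i}", "NC", {k: v[i] for k, v in cov.items()})
            for i in range(len(next(iter(cov.values()))))
        ]

    def test_constant_covariate_skipped(self):
        meta = self.meta_with({"flat": [1.0] * 8})
        out = clinical_association(meta, ["A"] * 4 + ["B"] * 4)
        assert out.iloc[0]["test"] == "skipped"

    def test_binary_covariate_matches_contingency_chi2(self):
        sex = ["M", "M", "M", "F", "F", "M", "F", "F", "M", "F"]
        strata = ["A"] * 5 + ["B"] * 5
        meta = self.meta_with({"sex": sex})
        out = clinical_association(meta, strata)
        tab = pd.crosstab(pd.Series(sex), pd.Series(strata)).to_numpy()
        stat, _, p = contingency_chi2(tab)
        assert out.iloc[0]["statistic"] == pytest.approx(stat)
        assert out.iloc[0]["p"] == pytest.approx(p)

    def test_power_on_shifted_covariate(self):
        # 2-SD location shift in one stratum, n=50 per stratum
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            meta = self.meta_with({"marker": np.concatenate([a, b])})
            out = clinical_association(meta, ["A"] * 50 + ["B"] * 50)
            hits += out.iloc[0]["p"] < 0.05
        assert hits >= 95


class TestCommonDifferential:
    def test_identical_sets(self):
        inter, counts, pct = common_differential({"x", "y"}, {"x", "y"})
        assert inter == {"x", "y"} and pct == 100.0

    def test_disjoint_sets(self):
        inter, counts, pct = common_differential({"x"}, {"y"})
        assert inter == set() and pct == 0.0

    def test_percentage_of_union(self):
        a = {f"a{i}" for i in range(95)} | {f"c{i}" for i in range(5)}
        b = {f"b{i}" for i in range(44)} | {f"c{i}" for i in range(5)}
        inter, counts, pct = common_differential(a, b)
        assert counts["common"] == 5 and counts["union"] == 144
        assert pct == 3.47
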