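"""Trait summaries, Levene, Shapiro-Wilk, Mann-Whitney, ART, qPCR scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

from replivar import (
    DegenerateVarianceError,
    InsufficientDataError,
    TraitSample,
    adjusted_rank_transform,
    frequency_distribution,
    levene_test,
    mann_whitney_u,
    percent_reduction,
    qpcr_relative_scale,
    round_half_up,
    shapiro_wilk,
    significance_stars,
    summarize_trait,
)
from helpers import mw_exact_u_and_p, statsmodels_two_way

positive_vectors = st.lists(st.floats(0.1, 1e4), min_size=2, max_size=40)


class TestSummarizeTrait:
    def test_constant_vector(self):
        s = summarize_trait([5.0, 5.0, 5.0, 5.0])
        assert s.variance == 0.0 and s.cv == 0.0 and s.median == 5.0

    def test_hand_computation(self):
        s = summarize_trait([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.variance == pytest.approx(1.0)  # n-1 denominator
        assert s.cv == pytest.approx(0.5)

    def test_even_n_median_midpoint(self):
        assert summarize_trait([1.0, 2.0, 3.0, 10.0]).median == 2.5

    def test_n_below_two_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_trait([1.0])

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="CV undefined"):
            summarize_trait([-1.0, 1.0])

    @given(positive_vectors, st.floats(0.01, 100))
    def test_cv_scale_invariant(self, v, c):
        base = summarize_trait(v)
        scaled = summarize_trait([c * x for x in v])
        assert scaled.cv == pytest.approx(base.cv, rel=1e-9, abs=1e-12)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "ref,test,ndigits,expected",
        [(40.7, 31.9, 1, 21.6), (4.67, 3.35, 1, 28.3), (10.0, 10.0, 1, 0.0)],
    )
    def test_reported_values(self, ref, test, ndigits, expected):
        assert round_half_up(percent_reduction(ref, test), ndigits) == expected

    def test_rounds_half_up(self):
        assert round_half_up(21.65, 1) == 21.7
        assert round_half_up(0.1645, 3) == 0.165

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestLevene:
    def test_hand_evaluated_w(self):
        res = levene_test([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], center="mean")
        assert res.statistic == pytest.approx(0.8)
        assert res.df == (1, 4)

    def test_identical_copies_give_zero(self):
        g = [1.0, 5.0, 9.0, 2.0]
        res = levene_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_scipy_on_random_groups(self, center):
        rng = np.random.default_rng(5)
        groups = [rng.normal(10, s, n) for s, n in [(1, 15), (3, 20), (2, 12)]]
        res = levene_test(groups, center=center)
        ref = stats.levene(*groups, center=center)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    @given(positive_vectors, positive_vectors, st.floats(-50, 50))
    def test_location_free(self, a, b, shift):
        try:
            base = levene_test([a, b])
        except DegenerateVarianceError:
            assume(False)  # W genuinely undefined (all |deviations| equal)
        # near-degenerate denominators amplify float rounding; skip the knife edge
        assume(np.isfinite(base.statistic) and base.statistic < 1e6)
        moved = levene_test([[x + shift for x in a], b])
        assert moved.statistic == pytest.approx(base.statistic, rel=1e-6, abs=1e-9)

    def test_all_constant_groups_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            levene_test([[2.0, 2.0], [5.0, 5.0]])


class TestShapiroWilk:
    @pytest.mark.parametrize("n", [2, 5001])
    def test_out_of_range_n_rejected(self, n):
        with pytest.raises(ValueError):
            shapiro_wilk(np.linspace(1, 2, n))

    def test_constant_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            shapiro_wilk([3.0] * 10)

    def test_bimodal_sample_rejected_as_normal(self):
        rng = np.random.default_rng(8)
        v = np.concatenate([rng.normal(0, 0.3, 20), rng.normal(10, 0.3, 20)])
        assert shapiro_wilk(v).p_value < 0.05

    def test_p_uniform_under_null(self):
        """p-values over repeated normal samples pass a Kolmogorov check."""
        rng = np.random.default_rng(9)
        ps = [shapiro_wilk(rng.normal(size=30)).p_value for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method.endswith("exact")

    def test_identical_multisets_symmetric_p(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        a = rng.normal(size=n1)
        b = rng.normal(loc=rng.uniform(-2, 2), size=n2)
        res = mann_whitney_u(a, b)
        u_oracle, p_oracle = mw_exact_u_and_p(a, b)
        assert res.statistic == u_oracle
        assert res.p_value == pytest.approx(p_oracle)

    @given(
        a=st.lists(st.floats(0.1, 50), min_size=3, max_size=15),
        b=st.lists(st.floats(0.1, 50), min_size=3, max_size=15),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        base = mann_whitney_u(a, b)
        cubed = mann_whitney_u([x**3 for x in a], [x**3 for x in b])
        assert cubed.statistic == pytest.approx(base.statistic)
        assert cubed.p_value == pytest.approx(base.p_value)

    def test_large_shift_power(self):
        """Shifted normals (2 pooled SD apart, n=40) reject at alpha=0.001."""
        rng = np.random.default_rng(10)
        rejections = sum(
            mann_whitney_u(rng.normal(0, 1, 40), rng.normal(2, 1, 40)).p_value
            < 0.001
            for _ in range(1000)
        )
        assert rejections >= 990


class TestAdjustedRankTransform:
    @staticmethod
    def _design(cells):
        y, fa, fb = [], [], []
        for (a, b), values in cells.items():
            for v in values:
                y.append(v)
                fa.append(a)
                fb.append(b)
        return np.array(y), fa, fb

    def test_additive_zero_noise_interaction_is_zero(self):
        cells = {("wt", "ctl"): [1.0, 1.0], ("wt", "str"): [3.0, 3.0],
                 ("mu", "ctl"): [2.0, 2.0], ("mu", "str"): [4.0, 4.0]}
        res = adjusted_rank_transform(*self._design(cells))
        assert res.interaction.statistic == 0.0
        assert res.interaction.p_value == 1.0

    def test_matches_brute_force_anova_on_adjusted_ranks(self):
        cells = {("a1", "b1"): [1.0, 2.0], ("a1", "b2"): [3.0, 4.0],
                 ("a2", "b1"): [5.0, 6.0], ("a2", "b2"): [11.0, 12.0]}
        y, fa, fb = self._design(cells)
        res = adjusted_rank_transform(y, fa, fb)
        # independent route: adjust, rank, classical ANOVA via statsmodels
        ya = np.asarray(y, float)
        codes_a = (np.asarray(fa) == "a2").astype(int)
        codes_b = (np.asarray(fb) == "b2").astype(int)
        adj = (ya - np.array([ya[codes_a == i].mean() for i in (0, 1)])[codes_a]
               - np.array([ya[codes_b == j].mean() for j in (0, 1)])[codes_b]
               + ya.mean())
        ranks = stats.rankdata(adj)
        oracle = statsmodels_two_way(ranks, fa, fb)
        assert res.interaction.statistic == pytest.approx(oracle["F_int"])
        assert res.interaction.p_value == pytest.approx(oracle["p_int"])
        assert res.interaction.df == (1, 4)

    def test_main_effects_match_statsmodels_rank_anova(self):
        rng = np.random.default_rng(12)
        fa = np.repeat(["wt", "mu"], 12)
        fb = np.tile(np.repeat(["c", "s"], 6), 2)
        y = rng.normal(0, 1, 24) + (fa == "mu") * 1.5 + (fb == "s") * 0.7
        res = adjusted_rank_transform(y, fa, fb)
        oracle = statsmodels_two_way(stats.rankdata(y), fa, fb)
        assert res.factor_a.statistic == pytest.approx(oracle["F_a"])
        assert res.factor_b.statistic == pytest.approx(oracle["F_b"])

    def test_unbalanced_type_two_matches_statsmodels(self):
        rng = np.random.default_rng(13)
        fa = ["a1"] * 9 + ["a2"] * 13
        fb = (["b1"] * 4 + ["b2"] * 5) + (["b1"] * 7 + ["b2"] * 6)
        y = rng.normal(0, 1, 22)
        res = adjusted_rank_transform(y, fa, fb)
        oracle = statsmodels_two_way(stats.rankdata(y), fa, fb)
        assert res.factor_a.statistic == pytest.approx(oracle["F_a"])
        assert res.factor_b.statistic == pytest.approx(oracle["F_b"])

    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_interaction_invariant_to_main_effect_shifts(self, row_c, col_c):
        rng = np.random.default_rng(14)
        fa = np.repeat(["a1", "a2"], 10)
        fb = np.tile(np.repeat(["b1", "b2"], 5), 2)
        y = rng.normal(0, 1, 20)
        shifted = y + (fa == "a2") * row_c + (fb == "b2") * col_c
        base = adjusted_rank_transform(y, fa, fb)
        moved = adjusted_rank_transform(shifted, fa, fb)
        assert moved.interaction.statistic == pytest.approx(
            base.interaction.statistic, rel=1e-9, abs=1e-9
        )

    def test_deficient_cell_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            adjusted_rank_transform(
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
                ["a1", "a1", "a1", "a1", "a2", "a2", "a2"],
                ["b1", "b1", "b2", "b2", "b1", "b1", "b2"],
            )


class TestQpcrScaling:
    def test_min_scaling(self):
        out = qpcr_relative_scale(pd.DataFrame([[2.0, 4.0, 8.0]], index=["g"]),
                                  [1.0, 1.0, 1.0])
        assert out.loc["g"].tolist() == [1.0, 2.0, 4.0]

    def test_all_equal_become_one(self):
        out = qpcr_relative_scale(pd.DataFrame([[3.0, 3.0]], index=["g"]),
                                  [1.0, 1.0])
        assert out.loc["g"].tolist() == [1.0, 1.0]

    def test_two_step_hand_computation(self):
        out = qpcr_relative_scale(pd.DataFrame([[10.0, 20.0]], index=["g"]),
                                  [2.0, 2.0])
        assert out.loc["g"].tolist() == [1.0, 2.0]

    def test_minimum_is_exactly_one_per_gene(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.uniform(0.5, 20, (5, 6)),
                          index=[f"g{i}" for i in range(5)])
        out = qpcr_relative_scale(df, rng.uniform(0.5, 2, 6))
        assert np.allclose(out.min(axis=1), 1.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            qpcr_relative_scale(pd.DataFrame([[1.0, 2.0]], index=["g"]),
                                [1.0, 0.0])


class TestFrequencyDistribution:
    def test_enumerated_bins_and_median(self):
        counts, median = frequency_distribution([1.0, 1.0, 2.0, 9.0], 1.0, 0.0)
        assert counts == {1.0: 2, 2.0: 1, 9.0: 1}
        assert median == 1.5

    def test_empty_input(self):
        assert frequency_distribution([], 1.0) == ({}, None)

    def test_single_bin(self):
        counts, _ = frequency_distribution([1.1, 1.2, 1.9], 1.0, 1.0)
        assert counts == {1.0: 3}

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(16)
        v = rng.uniform(-5, 25, 100)
        counts, _ = frequency_distribution(v, 2.5, -5.0)
        assert sum(counts.values()) == 100


def test_significance_star_convention():
    assert [significance_stars(p) for p in (0.2, 0.04, 0.009, 0.0009)] == \
        ["", "*", "**", "***"]


def test_trait_sample_rejects_nonpositive_values():
    with pytest.raises(ValueError):
        TraitSample(line="wt", values=np.array([1.0, 0.0]))
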