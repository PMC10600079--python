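import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petcompare import (
    PairedSeries,
    ScoreCrossTab,
    bland_altman,
    cohen_kappa,
    icc_absolute_agreement,
    paired_tests,
    relative_differences,
    transition_analysis,
    wilcoxon_signed_rank,
)
from petcompare.phantom import table5_fixture


def series(a, b):
    return PairedSeries.from_values(a, b)


class TestRelativeDifferences:
    def test_equal_pairs_are_zero_in_both_modes(self):
        s = series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.allclose(relative_differences(s, "reference_a"), 0)
        assert np.allclose(relative_differences(s, "mean_of_pair"), 0)

    def test_reference_a_convention(self):
        s = series([10.0, 10.0], [11.0, 11.0])
        assert np.allclose(relative_differences(s, "reference_a"), 10.0)

    def test_mean_of_pair_convention(self):
        s = series([10.0, 10.0], [11.0, 11.0])
        # 100 * 1 / 10.5
        assert np.allclose(relative_differences(s, "mean_of_pair"), 9.5238095238, rtol=1e-9)

    def test_zero_denominator_lists_offending_ids(self):
        s = PairedSeries(("n1", "n2"), np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="n1"):
            relative_differences(s, "reference_a")


class TestBlandAltman:
    def test_identical_series(self):
        assert bland_altman(series([1, 2, 3], [1, 2, 3])) == (0.0, 0.0, 0.0)

    def test_constant_relative_difference_has_zero_width(self):
        # b = 1.1 a everywhere: every mean-based difference is 100/10.5 %
        s = series([10.0, 20.0, 30.0], [11.0, 22.0, 33.0])
        bias, lo, hi = bland_altman(s)
        d = 100 * 0.1 / 1.05
        assert bias == pytest.approx(d) and lo == pytest.approx(d) and hi == pytest.approx(d)

    def test_two_pair_hand_arithmetic(self):
        # differences 0% and 10%: bias 5, SD = 10/sqrt(2) = 7.0711
        s = series([10.0, 10.0], [10.0, 11.0])
        rel = relative_differences(s, "mean_of_pair")
        bias, lo, hi = bland_altman(s)
        assert bias == pytest.approx(np.mean(rel))
        sd = float(np.std(rel, ddof=1))
        assert lo == pytest.approx(bias - 1.96 * sd)
        assert hi == pytest.approx(bias + 1.96 * sd)
        # and the second difference really is 100/10.5
        assert rel[1] == pytest.approx(100 / 10.5)


def _anova_icc_oracle(a, b):
    """From-scratch two-way ANOVA mean squares by explicit loops."""
    x = [[ai, bi] for ai, bi in zip(a, b)]
    n, k = len(x), 2
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement(self):
        a = [1.0, 2.0, 3.0, 4.0]
        icc, (lo, hi) = icc_absolute_agreement(series(a, a))
        assert icc == pytest.approx(1.0)

    def test_offset_penalized_despite_perfect_rank_correlation(self):
        a = np.array([1.0, 1.1, 0.9, 1.05, 0.95])
        icc, _ = icc_absolute_agreement(series(a, a + 10.0))
        assert icc < 0.1

    def test_matches_anova_oracle_to_1e10(self):
        a = [7.1, 9.4, 5.2, 8.8, 6.0, 7.7]
        b = [8.0, 10.1, 5.9, 9.9, 6.4, 8.6]
        icc, _ = icc_absolute_agreement(series(a, b))
        assert icc == pytest.approx(_anova_icc_oracle(a, b), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        a = rng.normal(5, 2, 20)
        b = a + 0.5 + rng.normal(0, 0.7, 20)
        icc, (lo, hi) = icc_absolute_agreement(series(a, b))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(20), 2),
                "raters": np.tile(["A", "B"], 20),
                "ratings": np.column_stack([a, b]).ravel(),
            }
        )
        res = pg.intraclass_corr(df, "targets", "raters", "ratings").set_index("Type")
        row = res.loc["ICC(A,1)"] if "ICC(A,1)" in res.index else res.loc["ICC2"]
        ci_col = "CI95" if "CI95" in res.columns else "CI95%"
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        assert lo == pytest.approx(row[ci_col][0], abs=0.01)
        assert hi == pytest.approx(row[ci_col][1], abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_absolute_agreement(series([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))


def _wilcoxon_enumeration_oracle(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [np.sum(ranks[np.array(signs, bool)]) for signs in itertools.product([0, 1], repeat=n)]
    )
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_low, p_high))


class TestPairedTests:
    def test_symmetric_differences_give_p_one(self):
        _, p = wilcoxon_signed_rank(series([0.0, 0.0], [-1.0, 1.0]))
        assert p == pytest.approx(1.0)

    def test_t_on_zero_mean_differences(self):
        stat, p = paired_tests(series([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]), "t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_positive_differences_exact_p(self):
        # all-positive signs: most extreme of the 2^6 assignments, p = 2/64
        s = series([0.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p = wilcoxon_signed_rank(s)
        assert p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_null_matches_sign_enumeration(self, seed):
        """DP-computed exact p equals the full 2^n enumeration, ties and
        zeros included, for n <= 12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        # half-integer values force ties in |d| regularly
        d = rng.integers(-6, 7, n) / 2.0
        if np.all(d == 0):
            d[0] = 1.0
        # zero baseline: differences are exactly d, so ties stay ties
        s = PairedSeries(tuple(range(n)), np.zeros(n), d.astype(float))
        _, p = wilcoxon_signed_rank(s)
        assert p == pytest.approx(_wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_large_n_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 60)
        b = a + rng.normal(0.3, 1, 60)
        s = series(a, b)
        stat, p = wilcoxon_signed_rank(s)
        from scipy import stats as ss

        ref = ss.wilcoxon(b, a, zero_method="wilcox", correction=False, mode="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(series([1.0, 2.0], [1.0, 2.0]))


class TestCohenKappa:
    def test_purely_diagonal_table(self):
        assert cohen_kappa(np.diag([5, 3, 2, 7])) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        # counts proportional to marginal products
        row = np.array([0.5, 0.5])
        col = np.array([0.3, 0.7])
        tab = 100 * np.outer(row, col)
        assert cohen_kappa(tab) == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_hand_value(self):
        assert cohen_kappa(np.array([[20, 5], [10, 15]])) == pytest.approx(0.4)

    def test_relabeling_invariance(self):
        tab = np.array([[20, 5, 1], [3, 30, 2], [0, 4, 10]])
        perm = [2, 0, 1]
        assert cohen_kappa(tab[np.ix_(perm, perm)]) == pytest.approx(cohen_kappa(tab))

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 30), min_size=16, max_size=16).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_kappa_bounded(self, counts):
        tab = np.array(counts).reshape(4, 4)
        n = tab.sum()
        p_e = np.sum(tab.sum(1) * tab.sum(0)) / n**2
        if p_e == 1.0:
            return
        assert -1.0 - 1e-12 <= cohen_kappa(tab) <= 1.0 + 1e-12

    def test_degenerate_marginals_rejected(self):
        tab = np.zeros((4, 4), int)
        tab[0, 0] = 10
        with pytest.raises(ValueError, match="kappa undefined"):
            cohen_kappa(tab)

    def test_dichotomized_fixture(self):
        # {1,2} vs {3,4}: rows of the packaged table collapse to [[110,12],[0,53]]
        d = table5_fixture().dichotomized()
        assert d.tolist() == [[110, 12], [0, 53]]
        assert 0 < cohen_kappa(table5_fixture(), dichotomize=True) < 1


class TestTransitions:
    def test_identity_table_has_no_off_diagonal_transitions(self):
        tr = transition_analysis(ScoreCrossTab(np.diag([5, 6, 7, 8])))
        off = tr.row_proportions[~np.eye(4, dtype=bool)]
        assert np.all(off == 0)
        assert tr.upstaged == 0 and tr.downstaged == 0

    def test_rows_sum_to_one_where_nonempty(self):
        tr = transition_analysis(table5_fixture())
        assert np.allclose(np.nansum(tr.row_proportions, axis=1), 1.0)
        assert tr.empty_rows == ()

    def test_empty_row_reported_as_undefined(self):
        tab = ScoreCrossTab(np.array([[5, 0, 0, 0], [0, 0, 0, 0], [0, 0, 3, 0], [0, 0, 0, 2]]))
        tr = transition_analysis(tab)
        assert tr.empty_rows == (2,)
        assert np.all(np.isnan(tr.row_proportions[1]))

    def test_crosstab_csv_roundtrip(self, tmp_path):
        tab = table5_fixture()
        tab.to_csv(tmp_path / "tab.csv")
        back = ScoreCrossTab.from_csv(tmp_path / "tab.csv")
        assert np.array_equal(back.counts, tab.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ScoreCrossTab(np.full((4, 4), -1))
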