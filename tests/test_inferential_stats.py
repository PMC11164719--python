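import math

import numpy as np
import pytest
from scipy import stats

from faceiq.exceptions import DegenerateDataError, InvalidInputError
from faceiq.inferential_stats import (
    bonferroni,
    icc_3_1,
    kruskal_wallis,
    pairwise_wilcoxon,
    weighted_kappa,
)


def kruskal_oracle(groups):
    """H from first principles: mid-ranks, tie correction, no scipy."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)  # mid-ranks
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - ((counts**3 - counts).sum()) / (n_total**3 - n_total)
    return h / correction


def kappa_oracle(a, b):
    """Quadratic-weight kappa by explicit double sums over the 2-way table."""
    cats = sorted(set(a) | set(b))
    k = len(cats)
    n = len(a)
    po = pe = 0.0
    for i, ci in enumerate(cats):
        for j, cj in enumerate(cats):
            w = 1 - ((i - j) / (k - 1)) ** 2
            obs = sum(1 for x, y in zip(a, b) if x == ci and y == cj) / n
            pi = sum(1 for x in a if x == ci) / n
            pj = sum(1 for y in b if y == cj) / n
            po += w * obs
            pe += w * pi * pj
    return (po - pe) / (1 - pe)


def icc_oracle(table):
    """ICC(3,1) via explicit sums of squares."""
    data = np.asarray(table, float)
    n, k = data.shape
    grand = data.mean()
    bms = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    jms = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ems = (((data - grand) ** 2).sum() - bms * (n - 1) - jms) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestKruskalWallis:
    def test_separated_groups_hand_value(self):
        result = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert result.statistic == pytest.approx(3.857, abs=5e-4)
        assert result.df == 1

    def test_identical_groups_high_p(self):
        result = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert result.p_raw > 0.9
        assert result.statistic == pytest.approx(
            kruskal_oracle([[1, 2, 3], [1, 2, 3]]), abs=1e-9
        )

    def test_matches_first_principles_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = [
                rng.integers(0, 8, size=rng.integers(3, 12)).tolist()
                for _ in range(rng.integers(2, 5))
            ]
            if len(np.unique(np.concatenate(groups))) == 1:
                continue
            result = kruskal_wallis(groups)
            assert result.statistic == pytest.approx(
                kruskal_oracle(groups), abs=1e-9
            )

    def test_label_permutation_symmetry(self):
        a, b, c = [1, 5, 9], [2, 6, 10], [3, 7, 11]
        h1 = kruskal_wallis([a, b, c]).statistic
        h2 = kruskal_wallis([c, a, b]).statistic
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_two_group_kw_equals_ranksum_chi_square(self):
        # algebraic identity: H = z^2 of the normal-approx rank-sum test
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 15).tolist()
        y = rng.normal(0.7, 1, 12).tolist()
        h = kruskal_wallis([x, y]).statistic
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        z = stats.norm.isf(res.pvalue / 2)
        assert h == pytest.approx(z**2, abs=1e-8)

    def test_degenerate_all_tied(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[3, 3], [3, 3]])

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            kruskal_wallis([[1, 2], []])


class TestPairwiseWilcoxon:
    def test_exact_two_sided_enumeration(self):
        result = pairwise_wilcoxon({"a": [1, 2], "b": [3, 4]})
        pair = result[("a", "b")]
        assert pair.p_raw == pytest.approx(1 / 3, abs=1e-12)
        assert pair.method == "wilcoxon-exact"
        assert pair.p_adjusted == pair.p_raw  # single pair

    def test_ties_switch_to_normal_approximation(self):
        result = pairwise_wilcoxon({"a": [1, 2, 2], "b": [2, 3, 4]})
        assert result[("a", "b")].method == "wilcoxon-normal-cc"

    def test_large_groups_switch_to_normal_approximation(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.permutation(np.arange(0, 60, dtype=float))[:30].tolist(),
            "b": (np.arange(60, 90, dtype=float) + 0.5).tolist(),
        }
        assert result_method(groups) == "wilcoxon-normal-cc"

    def test_bonferroni_multiplies_by_pair_count(self):
        groups = {
            "a": [1.0, 2.5, 3.1], "b": [4.2, 5.9, 6.3], "c": [7.7, 8.1, 9.4],
        }
        results = pairwise_wilcoxon(groups)
        assert len(results) == 3
        for r in results.values():
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))
            assert r.p_adjusted >= r.p_raw

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            results = pairwise_wilcoxon({"a": [1, 2], "b": [3, 4], "c": []})
        assert set(results) == {("a", "b")}

    @pytest.mark.parametrize(
        "p_raw, n, expected", [(0.01, 6, 0.06), (0.4, 10, 1.0), (0.2, 1, 0.2)]
    )
    def test_bonferroni_values(self, p_raw, n, expected):
        assert bonferroni(p_raw, n) == pytest.approx(expected)

    def test_bonferroni_order_preserving_and_idempotent_at_cap(self):
        ps = [0.001, 0.01, 0.3, 0.9]
        adj = [bonferroni(p, 4) for p in ps]
        assert adj == sorted(adj)
        assert bonferroni(bonferroni(0.9, 4), 1) == 1.0


def result_method(groups):
    return pairwise_wilcoxon(groups)[tuple(sorted(groups)[:2])].method


class TestWeightedKappa:
    def test_perfect_agreement(self):
        result = weighted_kappa([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert result.estimate == pytest.approx(1.0, abs=1e-12)
        assert result.p < 0.05

    def test_independent_raters_zero(self):
        result = weighted_kappa([1, 1, 2, 2], [1, 2, 1, 2])
        assert result.estimate == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            a = rng.integers(1, 4, size=n).tolist()
            b = rng.integers(1, 4, size=n).tolist()
            if len(set(a) | set(b)) < 2:
                continue
            result = weighted_kappa(a, b)
            assert result.estimate == pytest.approx(kappa_oracle(a, b), abs=1e-9)

    def test_matches_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        a = rng.integers(1, 7, size=40)
        b = np.clip(a + rng.integers(-1, 2, size=40), 1, 6)
        ours = weighted_kappa(a.tolist(), b.tolist(), categories=range(1, 7))
        theirs = sklearn_metrics.cohen_kappa_score(
            a, b, labels=list(range(1, 7)), weights="quadratic"
        )
        assert ours.estimate == pytest.approx(theirs, abs=1e-12)

    def test_item_relabelling_invariance(self):
        a, b = [1, 2, 3, 4, 2, 5], [1, 3, 3, 4, 2, 6]
        perm = [3, 0, 5, 1, 4, 2]
        direct = weighted_kappa(a, b)
        shuffled = weighted_kappa([a[i] for i in perm], [b[i] for i in perm])
        assert direct.estimate == pytest.approx(shuffled.estimate, abs=1e-12)

    def test_both_raters_constant_degenerate(self):
        result = weighted_kappa([2, 2, 2], [2, 2, 2])
        assert result.degenerate and result.p is None

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            weighted_kappa([1, 2], [1, 2, 3])


class TestIcc:
    def test_identical_columns_perfect(self):
        result = icc_3_1([[1, 1], [2, 2], [3, 3], [4, 4]])
        assert result.estimate == pytest.approx(1.0, abs=1e-12)
        assert result.f_statistic == math.inf and result.p == 0.0

    def test_matches_anova_oracle(self):
        table = [[9.0, 2.0], [4.5, 4.1], [7.2, 6.9], [10.0, 8.8]]
        result = icc_3_1(table)
        assert result.estimate == pytest.approx(icc_oracle(table), abs=1e-9)
        assert result.df1 == 3 and result.df2 == 3

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        table = rng.normal(50, 10, size=(10, 3)) + rng.normal(
            0, 5, size=(10, 1)
        )
        long = pd.DataFrame(
            {
                "item": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "value": table.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="item", raters="rater", ratings="value"
        )
        # consistency, single measures: labelled ICC3 or ICC(C,1) by version
        mask = ref["Type"].isin(["ICC3", "ICC(C,1)"])
        expected = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc_3_1(table).estimate == pytest.approx(expected, abs=1e-9)

    def test_rater_offset_invariance(self):
        table = np.array([[9.0, 2.0], [4.5, 4.1], [7.2, 6.9], [10.0, 8.8]])
        shifted = table.copy()
        shifted[:, 1] += 100.0  # consistency form ignores rater means
        assert icc_3_1(shifted).estimate == pytest.approx(
            icc_3_1(table).estimate, abs=1e-9
        )

    def test_item_relabelling_invariance(self):
        table = [[1.0, 2.0], [5.0, 4.0], [9.0, 9.5]]
        assert icc_3_1(table).estimate == pytest.approx(
            icc_3_1(table[::-1]).estimate, abs=1e-12
        )

    def test_zero_between_item_variance_degenerate(self):
        result = icc_3_1([[5.0, 5.0], [5.0, 5.0]])
        assert result.degenerate

    def test_incomplete_table_rejected(self):
        with pytest.raises(InvalidInputError):
            icc_3_1([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(InvalidInputError):
            icc_3_1([[1.0, 2.0]])
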