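"""Discrimination statistics vs exhaustive counting and permutation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import complexqa as cq
from complexqa.discrimination import (
    DiscriminationError,
    ScoreTable,
    binary_auc,
    bootstrap_ci,
    multiclass_auc,
    optimal_cutpoint,
    pearson,
    rank_sum_test,
    significance_stars,
)


def make_table(pos_scores, neg_scores, column="score", direction="higher",
               pos_class="high", neg_class="incorrect"):
    rows = []
    for i, s in enumerate(pos_scores):
        rows.append({"case": f"p{i}", "rank": 1, "capri_class": pos_class, column: s})
    for i, s in enumerate(neg_scores):
        rows.append({"case": f"n{i}", "rank": 1, "capri_class": neg_class, column: s})
    return ScoreTable(pd.DataFrame(rows), {column: direction})


def pair_count_auc(pos, neg):
    """Exhaustive concordant-pair counting, ties counted half."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def permutation_ranksum_p(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(xs, ys):
        return sum(np.sum(xi > ys) + 0.5 * np.sum(xi == ys) for xi in xs)

    obs = u_stat(x, y)
    center = n * len(y) / 2.0
    count = total = 0
    all_idx = set(range(len(pooled)))
    for combo in itertools.combinations(range(len(pooled)), n):
        rest = sorted(all_idx - set(combo))
        u = u_stat(pooled[list(combo)], pooled[rest])
        if abs(u - center) >= abs(obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestBinaryAuc:
    def test_perfect_separation(self):
        table = make_table([3, 4], [1, 2])
        assert binary_auc(table, "score", {"high"}, {"incorrect"}, n_boot=0).auc == 1.0

    def test_interleaved_quarter(self):
        # pos {1,3}, neg {2,4}: 1 of 4 pairs concordant
        table = make_table([1, 3], [2, 4])
        assert binary_auc(table, "score", {"high"}, {"incorrect"}, n_boot=0).auc == 0.25

    def test_direction_flip_is_complement(self):
        rng = np.random.default_rng(0)
        pos, neg = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        hi = make_table(pos, neg, direction="higher")
        lo = make_table(pos, neg, direction="lower")
        a_hi = binary_auc(hi, "score", {"high"}, {"incorrect"}, n_boot=0).auc
        a_lo = binary_auc(lo, "score", {"high"}, {"incorrect"}, n_boot=0).auc
        assert a_hi == pytest.approx(1.0 - a_lo)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=6),
           st.lists(st.integers(0, 20), min_size=1, max_size=6))
    def test_equals_exhaustive_pair_counting(self, pos, neg):
        """Mann-Whitney midrank AUC == concordant-pair count on small tables."""
        table = make_table(pos, neg)
        res = binary_auc(table, "score", {"high"}, {"incorrect"}, n_boot=0)
        assert res.auc == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        a1 = binary_auc(make_table(pos, neg), "score", {"high"}, {"incorrect"},
                        n_boot=0).auc
        a2 = binary_auc(make_table(np.exp(pos), np.exp(neg)), "score",
                        {"high"}, {"incorrect"}, n_boot=0).auc
        assert a1 == pytest.approx(a2)

    def test_curve_endpoints_and_monotone(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        curve = binary_auc(table, "score", {"high"}, {"incorrect"}, n_boot=0).curve
        np.testing.assert_allclose(curve[0], [0.0, 0.0])
        np.testing.assert_allclose(curve[-1], [1.0, 1.0])
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_empty_group_errors(self):
        table = make_table([1, 2], [3])
        with pytest.raises(DiscriminationError):
            binary_auc(table, "score", {"medium"}, {"incorrect"}, n_boot=0)


class TestBootstrapCi:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        ci1 = bootstrap_ci(table, "score", {"high"}, {"incorrect"}, n_boot=200, seed=5)
        ci2 = bootstrap_ci(table, "score", {"high"}, {"incorrect"}, n_boot=200, seed=5)
        assert ci1 == ci2

    def test_degenerate_limit_narrow(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.uniform(10, 11, 200), rng.uniform(0, 1, 200))
        lo, hi = bootstrap_ci(table, "score", {"high"}, {"incorrect"},
                              n_boot=300, seed=1)
        assert hi - lo < 0.01 and lo > 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_contains_point_auc(self, seed):
        rng = np.random.default_rng(seed)
        pos, neg = rng.normal(0.5, 1, 12), rng.normal(0, 1, 15)
        table = make_table(pos, neg)
        res = binary_auc(table, "score", {"high"}, {"incorrect"},
                         n_boot=200, seed=seed)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_width_shrinks_with_group_size(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (10, 40, 160):
            table = make_table(rng.normal(0.8, 1, n), rng.normal(0, 1, n))
            lo, hi = bootstrap_ci(table, "score", {"high"}, {"incorrect"},
                                  n_boot=300, seed=2)
            widths.append(hi - lo)
        assert widths[2] < widths[0]


class TestMulticlassAuc:
    def test_two_class_reduces_to_binary(self):
        rng = np.random.default_rng(7)
        pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        table = make_table(pos, neg)
        mc = multiclass_auc(table, "score", n_boot=0)
        bi = binary_auc(table, "score", {"high"}, {"incorrect"}, n_boot=0)
        assert mc.auc == pytest.approx(bi.auc)

    def test_perfectly_ordered_classes(self):
        rows = []
        for i, (cls, lo) in enumerate([("incorrect", 0), ("acceptable", 10),
                                       ("medium", 20), ("high", 30)]):
            for j in range(5):
                rows.append({"case": f"c{i}{j}", "rank": 1, "capri_class": cls,
                             "score": lo + j})
        table = ScoreTable(pd.DataFrame(rows))
        assert multiclass_auc(table, "score", n_boot=0).auc == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(8)
        rows = [{"case": f"c{i}", "rank": 1,
                 "capri_class": rng.choice(["incorrect", "acceptable",
                                            "medium", "high"]),
                 "score": rng.normal()} for i in range(500)]
        table = ScoreTable(pd.DataFrame(rows))
        assert multiclass_auc(table, "score", n_boot=0).auc == pytest.approx(0.5, abs=0.05)

    def test_lower_is_better_direction(self):
        rows = []
        for i, (cls, lo) in enumerate([("incorrect", 30), ("medium", 20),
                                       ("high", 10)]):
            for j in range(4):
                rows.append({"case": f"c{i}{j}", "rank": 1, "capri_class": cls,
                             "pae": lo + j})
        table = ScoreTable(pd.DataFrame(rows), {"pae": "lower"})
        assert multiclass_auc(table, "pae", n_boot=0).auc == 1.0


class TestOptimalCutpoint:
    def test_separable_lowest_positive_convention(self):
        table = make_table([5, 6, 7], [1, 2, 3])
        res = optimal_cutpoint(table, "score", {"high"}, {"incorrect"})
        assert res.threshold == 5
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.objective == 2.0

    def test_interleaved_below_two(self):
        table = make_table([1, 3, 5], [2, 4, 6])
        res = optimal_cutpoint(table, "score", {"high"}, {"incorrect"})
        assert 1.0 <= res.objective < 2.0

    @pytest.mark.parametrize("seed", range(4))
    def test_recovers_planted_threshold(self, seed):
        rng = np.random.default_rng(seed)
        planted = 50.0
        pos = rng.uniform(planted, planted + 30, 40)
        neg = rng.uniform(planted - 30, planted - 1e-6, 40)
        table = make_table(pos, neg)
        res = optimal_cutpoint(table, "score", {"high"}, {"incorrect"})
        # within one observed score step of the planted boundary
        assert neg.max() < res.threshold <= pos.min() + 1e-9
        assert res.objective == 2.0

    def test_lower_is_better_column(self):
        table = make_table([1.0, 2.0], [8.0, 9.0], direction="lower")
        res = optimal_cutpoint(table, "score", {"high"}, {"incorrect"})
        assert res.objective == 2.0
        assert 2.0 <= res.threshold < 8.0

    def test_objective_at_least_one(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            table = make_table(rng.normal(size=6), rng.normal(size=6))
            assert optimal_cutpoint(table, "score", {"high"}, {"incorrect"}).objective >= 1.0


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0, abs=0.01)

    def test_extreme_separation_exact(self):
        # 2 of C(6,3)=20 assignments are at least as extreme (both tails)
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(0, 14, 1.0))[:6]
        y = np.setdiff1d(np.arange(0, 14, 1.0), x)[:6]
        assert rank_sum_test(x, y) == pytest.approx(permutation_ranksum_p(x, y), abs=1e-9)

    def test_normal_approximation_close_to_exact(self):
        # n = 9 takes the asymptotic path; compare with full enumeration
        rng = np.random.default_rng(10)
        x = rng.normal(0.0, 1.0, 9)
        y = rng.normal(0.8, 1.0, 9)
        exact = permutation_ranksum_p(x, y)
        assert rank_sum_test(x, y) == pytest.approx(exact, abs=0.01)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = pearson(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        r_direct = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
        assert r == pytest.approx(r_direct, abs=1e-12)
        from scipy import stats
        t = r_direct * np.sqrt(28 / (1 - r_direct**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(DiscriminationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSignificanceStars:
    @pytest.mark.parametrize("p,label", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.04, "*"),
        (0.01, "**"), (0.002, "**"), (0.001, "***"), (0.0005, "***"),
    ])
    def test_bins(self, p, label):
        assert significance_stars(p) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestScoreTable:
    def test_duplicate_case_rank_rejected(self):
        df = pd.DataFrame([
            {"case": "a", "rank": 1, "capri_class": "high", "s": 1.0},
            {"case": "a", "rank": 1, "capri_class": "incorrect", "s": 2.0},
        ])
        with pytest.raises(DiscriminationError):
            ScoreTable(df)

    def test_unknown_class_rejected(self):
        df = pd.DataFrame([{"case": "a", "rank": 1, "capri_class": "great", "s": 1.0}])
        with pytest.raises(DiscriminationError):
            ScoreTable(df)

    def test_missing_values_excluded_per_column(self):
        df = pd.DataFrame([
            {"case": "a", "rank": 1, "capri_class": "high", "s": 5.0},
            {"case": "b", "rank": 1, "capri_class": "high", "s": np.nan},
            {"case": "c", "rank": 1, "capri_class": "incorrect", "s": 1.0},
        ])
        res = binary_auc(ScoreTable(df), "s", {"high"}, {"incorrect"}, n_boot=0)
        assert res.n_pos == 1 and res.n_neg == 1

    def test_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame([
            {"case": "a", "rank": 1, "capri_class": "high", "s": 5.0},
            {"case": "a", "rank": 2, "capri_class": "incorrect", "s": 1.0},
        ])
        p = tmp_path / "scores.tsv"
        ScoreTable(df).to_tsv(p)
        back = ScoreTable.from_tsv(p)
        pd.testing.assert_frame_equal(back.frame, df)
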