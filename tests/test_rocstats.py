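"""Core two-group statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from papmeth.rocstats import (
    HIGHER_IS_POSITIVE,
    LOWER_IS_POSITIVE,
    bootstrap_ci,
    closest_topleft_cutoff,
    combine_genes_logistic,
    fit_logistic_ridge,
    group_comparison,
    mann_whitney_two_tailed,
    roc_auc,
    roc_analysis,
)

# ---------------------------------------------------------------- oracles


def mw_exact_p_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of group splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1.0 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1.0 for xi in xs for yi in ys if xi == yi
        )

    obs = min(u_stat(x, y), n1 * n2 - u_stat(x, y))
    count = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if min(u, n1 * n2 - u) <= obs + 1e-12:
            count += 1
    return count / total


def auc_pair_counting(values, labels, direction):
    v = np.asarray(values, float)
    if direction == LOWER_IS_POSITIVE:
        v = -v
    y = np.asarray(labels, bool)
    num = den = 0.0
    for vc in v[y]:
        for vn in v[~y]:
            den += 1
            if vc > vn:
                num += 1
            elif vc == vn:
                num += 0.5
    return num / den


def topleft_exhaustive(values, labels, direction):
    """Scan thresholds at every observed value and +/- inf with >=/<= calls."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    best = None
    for t in np.r_[-np.inf, np.unique(v), np.inf]:
        pos = v <= t if direction == LOWER_IS_POSITIVE else v >= t
        sens = pos[y].mean()
        spec = (~pos[~y]).mean()
        obj = (1 - sens) ** 2 + (1 - spec) ** 2
        if best is None or obj < best[0] - 1e-12:
            best = (obj, sens, spec)
    return best


# ---------------------------------------------------------------- Mann-Whitney


class TestMannWhitney:
    def test_exact_matches_enumeration_all_small_sizes(self, rng):
        """Exact p equals full enumeration for every group-size pair <= 7."""
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                vals = rng.permutation(np.arange(n1 + n2, dtype=float))
                x, y = vals[:n1], vals[n1:]
                _, p = mann_whitney_two_tailed(x, y)
                assert p == pytest.approx(mw_exact_p_enumeration(x, y), abs=1e-12)

    def test_complete_separation_3v3(self):
        u, p = mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_complete_separation_6v6(self):
        _, p = mann_whitney_two_tailed(
            [0.8, 0.9, 0.7, 0.85, 0.95, 0.75], [0.1, 0.2, 0.15, 0.05, 0.25, 0.3]
        )
        assert p == pytest.approx(2 / 924)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_constant_data_degenerate(self):
        _, p = mann_whitney_two_tailed([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([], [1.0])


# ---------------------------------------------------------------- AUC


class TestRocAuc:
    def test_matches_pair_counting_oracle(self, rng):
        """Rank-based AUC equals brute-force pair counting (with ties)."""
        for _ in range(300):
            n1, n2 = rng.integers(1, 31, size=2)
            v = np.round(rng.normal(size=n1 + n2), 1)  # rounding forces ties
            y = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            for d in (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE):
                assert roc_auc(v, y, d) == pytest.approx(
                    auc_pair_counting(v, y, d), abs=1e-12
                )

    def test_direction_example(self):
        # case dcp [1,3] vs control [2,4], lower is disease-positive
        auc = roc_auc([1, 3, 2, 4], [True, True, False, False], LOWER_IS_POSITIVE)
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 9, 10], [True, True, False, False],
                       LOWER_IS_POSITIVE) == 1.0

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=40)
        y = rng.random(40) < 0.5
        y[0], y[1] = True, False
        a0 = roc_auc(v, y, HIGHER_IS_POSITIVE)
        assert roc_auc(np.exp(v), y, HIGHER_IS_POSITIVE) == pytest.approx(a0)
        assert roc_auc(3 * v - 7, y, HIGHER_IS_POSITIVE) == pytest.approx(a0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True], HIGHER_IS_POSITIVE)


# ---------------------------------------------------------------- cutoff


class TestClosestTopleft:
    def test_matches_exhaustive_scan(self, rng):
        """Achieved (sens, spec) equals the exhaustive-threshold oracle."""
        for _ in range(300):
            n1, n2 = rng.integers(2, 31, size=2)
            v = np.round(rng.normal(size=n1 + n2), 1)
            y = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            for d in (LOWER_IS_POSITIVE, HIGHER_IS_POSITIVE):
                cutoff, sens, spec = closest_topleft_cutoff(v, y, d)
                obj_o, _, _ = topleft_exhaustive(v, y, d)
                assert (1 - sens) ** 2 + (1 - spec) ** 2 == pytest.approx(
                    obj_o, abs=1e-12
                )

    def test_separated_data_perfect(self):
        c, sens, spec = closest_topleft_cutoff(
            [1, 2, 3, 7, 8, 9], [True] * 3 + [False] * 3, LOWER_IS_POSITIVE
        )
        assert sens == 1.0 and spec == 1.0
        assert 3 < c < 7

    def test_classification_convention_at_cutoff(self):
        # a delta_cp below the cutoff is called positive, above negative
        cutoff = 6.37
        assert (5.0 <= cutoff) is True
        assert (7.0 <= cutoff) is False


# ---------------------------------------------------------------- bootstrap


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        v = rng.normal(size=30)
        y = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        lo, hi = bootstrap_ci(lambda vv, yy: 0.42, v, y, n_boot=50, seed=1)
        assert lo == hi == 0.42

    def test_reproducible_with_seed(self, rng):
        v = rng.normal(size=40)
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        f = lambda vv, yy: roc_auc(vv, yy, HIGHER_IS_POSITIVE)
        assert bootstrap_ci(f, v, y, seed=7) == bootstrap_ci(f, v, y, seed=7)

    def test_interval_contains_point_estimate_usually(self, rng):
        """Percentile bootstrap CI should cover the plug-in AUC nearly always."""
        hit = 0
        for i in range(40):
            v = rng.normal(size=36) + np.r_[np.full(18, 0.8), np.zeros(18)]
            y = np.r_[np.ones(18, bool), np.zeros(18, bool)]
            auc = roc_auc(v, y, HIGHER_IS_POSITIVE)
            lo, hi = bootstrap_ci(
                lambda vv, yy: roc_auc(vv, yy, HIGHER_IS_POSITIVE),
                v, y, n_boot=200, seed=i,
            )
            hit += lo - 1e-9 <= auc <= hi + 1e-9
        assert hit >= 38

    def test_stratification_keeps_both_classes(self, rng):
        v = rng.normal(size=12)
        y = np.r_[np.ones(2, bool), np.zeros(10, bool)]  # rare cases
        lo, hi = bootstrap_ci(
            lambda vv, yy: roc_auc(vv, yy, HIGHER_IS_POSITIVE), v, y, seed=0
        )
        assert np.isfinite(lo) and np.isfinite(hi)


def test_roc_analysis_bundles_consistent_pieces(rng):
    v = np.r_[rng.normal(2, 1, 20), rng.normal(5, 1, 25)]
    y = np.r_[np.ones(20, bool), np.zeros(25, bool)]
    res = roc_analysis(v, y, LOWER_IS_POSITIVE, seed=5)
    assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
    assert res.n_case == 20 and res.n_control == 25
    pos = v <= res.cutoff
    assert res.sensitivity == pytest.approx(pos[y].mean())
    assert res.specificity == pytest.approx((~pos[~y]).mean())


# ---------------------------------------------------------------- logistic


class TestLogistic:
    def test_matches_sklearn_unpenalized(self, rng):
        """IRLS fit agrees with an independent solver on well-behaved data."""
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(200, 3))
        eta = 0.5 - 1.0 * X[:, 0] + 0.7 * X[:, 1]
        y = rng.random(200) < 1 / (1 + np.exp(-eta))
        ours = fit_logistic_ridge(X, y.astype(float), ridge=1e-6)
        ref = LogisticRegression(C=1e6, tol=1e-10, max_iter=1000).fit(X, y)
        assert ours.coef == pytest.approx(ref.coef_[0], abs=1e-3)
        assert ours.intercept == pytest.approx(ref.intercept_[0], abs=1e-3)

    def test_separation_flagged_not_fatal(self):
        X = np.r_[np.full((5, 1), -2.0), np.full((5, 1), 2.0)]
        y = np.r_[np.zeros(5), np.ones(5)]
        fit = fit_logistic_ridge(X, y)
        assert np.isfinite(fit.coef).all()
        assert fit.separation_flag

    def test_single_gene_combination_preserves_auc(self, rng):
        """A 1-gene logistic score is monotone in delta_cp, so AUC is unchanged."""
        dcp = pd.DataFrame({"g": np.r_[rng.normal(2, 1, 20), rng.normal(4, 1, 20)]})
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        scores, _ = combine_genes_logistic(dcp, y)
        auc_gene = roc_auc(dcp["g"], y, LOWER_IS_POSITIVE)
        auc_score = roc_auc(scores, y, HIGHER_IS_POSITIVE)
        assert auc_score == pytest.approx(auc_gene)

    def test_noise_gene_coefficient_shrinks_with_n(self):
        rng = np.random.default_rng(202)
        mags = []
        for n in (100, 4000):
            X = rng.normal(size=(n, 2))
            eta = -1.2 * X[:, 0]
            y = rng.random(n) < 1 / (1 + np.exp(-eta))
            fit = fit_logistic_ridge(X, y.astype(float))
            mags.append(abs(fit.coef[1]))  # second column is label-independent
        assert mags[1] < mags[0]

    def test_missing_values_rejected(self):
        dcp = pd.DataFrame({"g": [1.0, np.nan, 2.0, 3.0]})
        with pytest.raises(ValueError):
            combine_genes_logistic(dcp, [True, True, False, False])


# ---------------------------------------------------------------- Kruskal-Wallis


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        res = group_comparison([1.0, 2, 3, 1, 2, 3, 1, 2, 3],
                               list("aaabbbccc"))
        assert res.p_value > 0.5
        assert res.posthoc.empty

    def test_shifted_group_flagged_in_posthoc(self, rng):
        v = np.r_[rng.normal(0, 0.1, 8), rng.normal(0, 0.1, 8), rng.normal(5, 0.1, 8)]
        g = np.repeat(["a", "b", "c"], 8)
        res = group_comparison(v, g)
        assert res.p_value < 0.05
        flagged = res.posthoc[res.posthoc["significant"]]
        assert set(map(tuple, flagged[["group1", "group2"]].to_numpy())) == {
            ("a", "c"), ("b", "c"),
        }

    def test_two_groups_consistent_with_rank_sum(self, rng):
        """For 2 groups, H is the squared standardized rank-sum statistic."""
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 15)
        res = group_comparison(np.r_[x, y], ["a"] * 12 + ["b"] * 15)
        from scipy import stats

        z = stats.norm.isf(
            mann_whitney_two_tailed(x, y)[1] / 2
        )  # two-sided p -> |z| (no continuity in KW, so compare loosely)
        assert res.statistic == pytest.approx(z**2, rel=0.15)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            group_comparison([1, 2, 3], ["a", "a", "a"])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    shift=st.floats(-5, 5, allow_nan=False),
    scale=st.floats(0.1, 10, allow_nan=False),
)
def test_auc_affine_invariance_property(shift, scale):
    rng = np.random.default_rng(99)
    v = rng.normal(size=30)
    y = np.r_[np.ones(14, bool), np.zeros(16, bool)]
    base = roc_auc(v, y, HIGHER_IS_POSITIVE)
    assert roc_auc(scale * v + shift, y, HIGHER_IS_POSITIVE) == pytest.approx(base)
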