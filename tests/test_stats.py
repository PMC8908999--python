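"""ANCOVA, correlations, Mann-Whitney and ROC against independent oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from peridmi.forward_model import ValidationError
from peridmi.stats import (
    ancova_group_effect,
    mann_whitney,
    pearson_correlation,
    roc_analysis,
)


def ancova_oracle(y, group, cov):
    """Normal-equations F-test of the group term, written from scratch."""
    y = np.asarray(y, float)
    g = (np.asarray(group) == np.unique(group)[1]).astype(float)
    cov = np.asarray(cov, float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), g, cov])
    X_red = np.column_stack([np.ones(n), cov])

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    sse_f, sse_r = sse(X_full), sse(X_red)
    df_den = n - 3
    F = (sse_r - sse_f) / (sse_f / df_den)
    p = float(sps.f.sf(F, 1, df_den))
    return F, p


def auc_pair_counting(scores, positive, direction):
    """(concordant + ties/2) / (n1*n2); concordance per the direction."""
    pos = scores[positive][:, None]
    neg = scores[~positive][None, :]
    conc = (pos > neg) if direction == ">=" else (pos < neg)
    return (conc.sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.shape[1])


class TestAncova:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 12
            y = rng.normal(size=n)
            grp = np.array(["A"] * 6 + ["B"] * 6)
            cov = rng.normal(size=n)
            res = ancova_group_effect(y, grp, cov)
            F, p = ancova_oracle(y, grp, cov)
            assert res.F == pytest.approx(F, abs=1e-8)
            assert res.p_raw == pytest.approx(p, abs=1e-8)
            assert res.df == (1, n - 3)

    def test_null_by_construction(self):
        cov = np.arange(8.0)
        y = 2.0 + 0.5 * cov + np.sin(cov)  # same y and cov in both groups
        res = ancova_group_effect(np.concatenate([y, y]),
                                  np.repeat(["A", "B"], 8),
                                  np.concatenate([cov, cov]))
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("p_raw,m,expected", [(0.02, 3, 0.06), (0.5, 3, 1.0)])
    def test_bonferroni_arithmetic(self, p_raw, m, expected):
        assert min(1.0, m * p_raw) == pytest.approx(expected)

    def test_bonferroni_applied_to_result(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        res = ancova_group_effect(y, np.repeat(["A", "B"], 6),
                                  rng.normal(size=12), m_comparisons=3)
        assert res.p_bonferroni == pytest.approx(min(1.0, 3 * res.p_raw))

    def test_collinear_covariate_inestimable(self):
        grp = np.repeat(["A", "B"], 6)
        cov = (grp == "B").astype(float)  # covariate == group indicator
        with pytest.raises(ValidationError, match="rank"):
            ancova_group_effect(np.random.default_rng(1).normal(size=12), grp, cov)

    def test_adjusted_means_order_follows_effect(self):
        rng = np.random.default_rng(5)
        cov = rng.normal(size=30)
        grp = np.repeat(["A", "B"], 15)
        y = 1.0 * (grp == "B") + 0.5 * cov + rng.normal(0, 0.1, 30)
        res = ancova_group_effect(y, grp, cov)
        assert res.adjusted_means["B"] > res.adjusted_means["A"]


class TestPearson:
    def test_exact_collinearity(self):
        r, _ = pearson_correlation([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 10))
        r, p = pearson_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
        t = r_direct * np.sqrt(8 / (1 - r_direct**2))
        p_direct = float(2 * sps.t.sf(abs(t), 8))
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        """Fully separated n=3 samples: U=0, p = 2/C(6,3) = 0.1."""
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            u, p = mann_whitney(a, b)
            u_s, p_s = sps.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact")
            assert u == pytest.approx(float(u_s))
            assert p == pytest.approx(float(p_s), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert p == 1.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        a=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=5),
        b=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=5),
    )
    def test_two_sided_symmetry(self, a, b):
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1],
                                                      abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(6)
        a = np.round(rng.normal(size=30), 1)
        b = np.round(rng.normal(0.5, size=25), 1)
        _, p = mann_whitney(a, b)
        _, p_s = sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        assert p == pytest.approx(float(p_s), abs=1e-12)


class TestRoc:
    def test_pair_counting_example(self):
        """GBM (1,2,3) vs metastasis (2,3,4), metastasis positive -> 7/9."""
        scores = np.array([1, 2, 3, 2, 3, 4], float)
        labels = np.array(["G"] * 3 + ["M"] * 3)
        res = roc_analysis(scores, labels, "M")
        assert res.direction == ">="
        assert res.auc == pytest.approx(7 / 9, abs=1e-12)

    def test_perfect_separation(self):
        res = roc_analysis(np.array([1, 2, 3, 10, 11, 12], float),
                           np.array(["n"] * 3 + ["p"] * 3), "p")
        assert res.auc == 1.0
        assert res.sens == 1.0 and res.spec == 1.0
        assert res.ppv == 1.0 and res.npv == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.choice(["a", "b"], size=30)
        if len(set(labels)) < 2:
            labels[0] = "a"; labels[1] = "b"
        r1 = roc_analysis(scores, labels, "b")
        r2 = roc_analysis(np.exp(scores), labels, "b")
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert (r1.sens, r1.spec, r1.ppv, r1.npv) == (r2.sens, r2.spec,
                                                      r2.ppv, r2.npv)

    def test_lower_scores_can_predict_positive(self):
        res = roc_analysis(np.array([10, 11, 12, 1, 2, 3], float),
                           np.array(["n"] * 3 + ["p"] * 3), "p")
        assert res.direction == "<="
        assert res.auc == 1.0

    def test_trapezoid_equals_pair_counting_on_random_data(self):
        """Empirical-curve trapezoid AUC == Mann-Whitney pair count, 100 draws."""
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.normal(size=n), 1)  # ties included
            labels = rng.choice(["x", "y"], size=n)
            if (labels == "y").sum() in (0, n):
                labels[0], labels[1] = "x", "y"
            res = roc_analysis(scores, labels, "y")
            oracle = auc_pair_counting(scores, labels == "y", res.direction)
            assert res.auc == pytest.approx(oracle, abs=1e-12)

    def test_cutpoint_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            scores = np.round(rng.normal(size=20), 1)
            labels = np.array(["x"] * 10 + ["y"] * 10)
            res = roc_analysis(scores, labels, "y")
            pos = labels == "y"
            distinct = np.unique(scores)
            cands = np.concatenate([[-np.inf],
                                    (distinct[:-1] + distinct[1:]) / 2,
                                    [np.inf]])
            best, best_c = -1.0, None
            for c in cands:  # smallest candidate wins ties
                pred = scores >= c if res.direction == ">=" else scores <= c
                sens = (pred & pos).sum() / pos.sum()
                spec = (~pred & ~pos).sum() / (~pos).sum()
                if sens + spec > best + 1e-12:
                    best, best_c = sens + spec, c
            assert res.optimal_cutpoint == best_c
            assert res.sens + res.spec == pytest.approx(best, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_analysis(np.array([1.0, 2.0]), np.array(["a", "a"]), "a")
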