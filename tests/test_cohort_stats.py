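"""Statistical battery: frozen oracles and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ferrofat.cohort_stats import (
    chi_square,
    compare_groups,
    compare_paired,
    delong_compare,
    derive_normative_limit,
    friedman_repeated,
    predictive_values,
    roc_with_youden,
    spearman,
    stepwise_multivariate,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def auc_bruteforce(scores, labels):
    """Pairwise AUC with ties counted 1/2."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_scan_oracle(scores, labels):
    """Exhaustive midpoint scan, ties to higher specificity then higher cutoff."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 1.0]
    best = None
    for c in candidates:
        sens = np.mean(pos > c)
        spec = np.mean(neg <= c)
        key = (round(sens + spec, 12), round(spec, 12), c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    return best[1], best[2], best[3]


class TestNormativeLimit:
    def test_constant_sample_returns_the_constant(self):
        lim = derive_normative_limit([4.2, 4.2, 4.2, 4.2], epsilon=0.1)
        assert lim.upper_limit == pytest.approx(4.2, abs=1e-12)
        assert lim.log_sd == 0.0

    def test_four_point_hand_calculation(self):
        """{1,1,1,e^2} with eps=0: logs {0,0,0,2}, mean 0.5, sample SD 1,
        limit exp(0.5 + 2) = e^2.5."""
        lim = derive_normative_limit([1.0, 1.0, 1.0, np.exp(2.0)], epsilon=0.0)
        assert lim.log_mean == pytest.approx(0.5)
        assert lim.log_sd == pytest.approx(1.0)
        assert lim.upper_limit == pytest.approx(np.exp(2.5), rel=1e-12)

    def test_law_of_large_numbers(self, rng):
        mu, sigma = np.log(2.0), 0.6
        draws = np.exp(rng.normal(mu, sigma, 100_000))
        lim = derive_normative_limit(draws, epsilon=0.0)
        assert lim.upper_limit == pytest.approx(np.exp(mu + 2 * sigma), rel=0.01)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            derive_normative_limit([1.0, -0.5, 2.0])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_with_youden([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 2.0 < res.cutoff <= 3.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert (res.tp, res.fp, res.fn, res.tn) == (2, 0, 0, 2)

    def test_interleaved_brute_force(self):
        """Positives {2,4} vs negatives {1,3}: 3 of 4 pairs ordered -> 0.75."""
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        res = roc_with_youden(scores, labels)
        assert res.auc == pytest.approx(0.75)
        assert res.auc == auc_bruteforce(scores, labels)

    def test_permutation_null(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.permutation(np.repeat([0, 1], 1000))
        res = roc_with_youden(scores, labels)
        assert abs(res.auc - 0.5) < 0.03

    def test_direction_less(self):
        """Low scores mark the condition (e.g. short T2* marks iron)."""
        res = roc_with_youden([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], direction="less")
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 2.0 <= res.cutoff < 3.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_youden([1.0, 2.0], [1, 1])

    def test_matches_sklearn_auc_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(0, 8, 200).astype(float)
        labels = rng.random(200) < 0.4
        res = roc_with_youden(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_and_cutoff_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[: int(rng.integers(1, n))] ] = 1
        if labels.all() or not labels.any():
            return
        res = roc_with_youden(scores, labels)
        assert res.auc == auc_bruteforce(scores, labels)
        cut, sens, spec = youden_scan_oracle(scores, labels)
        assert res.cutoff == pytest.approx(cut)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        delta, p = delong_compare(scores, scores, labels)
        assert delta == 0.0 and p == 1.0

    def test_delta_sign_matches_auc_difference(self, rng):
        labels = rng.random(300) < 0.5
        a = labels + rng.normal(0, 1.0, 300)
        b = labels + rng.normal(0, 2.0, 300)
        delta, _ = delong_compare(a, b, labels)
        auc_a = roc_with_youden(a, labels).auc
        auc_b = roc_with_youden(b, labels).auc
        assert delta == pytest.approx(auc_a - auc_b, abs=1e-12)

    def test_detects_a_clearly_better_marker(self, rng):
        labels = rng.random(400) < 0.5
        good = labels * 2.0 + rng.normal(0, 1.0, 400)
        noise = rng.normal(0, 1.0, 400)
        _, p = delong_compare(good, noise, labels)
        assert p < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0], [1.0], [0, 1])


class TestPredictiveValues:
    def test_zero_false_negatives_give_perfect_npv(self):
        res = predictive_values([1, 1, 0, 0], [1, 1, 0, 0])
        assert res.npv == 1.0 and res.sensitivity == 1.0

    def test_hand_computed_table(self):
        test = [1] * 10 + [0] * 10
        cond = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        res = predictive_values(test, cond)
        assert (res.tp, res.fp, res.fn, res.tn) == (8, 2, 1, 9)
        assert res.sensitivity == pytest.approx(8 / 9)
        assert res.specificity == pytest.approx(9 / 11)
        assert res.ppv == pytest.approx(0.8)
        assert res.npv == pytest.approx(0.9)

    def test_all_test_negative_flags_undefined_ppv(self):
        res = predictive_values([0, 0, 0], [1, 0, 1])
        assert np.isnan(res.ppv)
        assert "ppv" in res.undefined

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ratios_recompute_from_counts(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.random(30) < 0.5
        c = rng.random(30) < 0.5
        res = predictive_values(t, c)
        assert res.tp + res.fp + res.fn + res.tn == 30
        if res.tp + res.fp:
            assert res.ppv == res.tp / (res.tp + res.fp)
        if res.tn + res.fn:
            assert res.npv == res.tn / (res.tn + res.fn)


class TestNonparametricSuite:
    def test_identical_groups_are_not_significant(self):
        rep = compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert rep.p_value > 0.99

    def test_kruskal_wallis_hand_computed(self):
        """Disjoint groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6/15/24 give
        H = 12/(9*10) * (36+225+576)/3 - 3*10 = 7.2."""
        rep = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert rep.test == "kruskal_wallis"
        assert rep.statistic == pytest.approx(7.2)
        assert set(rep.details["posthoc"]) == {"a vs b", "a vs c", "b vs c"}

    def test_all_identical_values_flagged(self):
        rep = compare_groups({"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5, 5]})
        assert rep.p_value == 1.0
        assert "all_identical" in rep.flags

    def test_insufficient_group_flagged(self):
        rep = compare_groups({"a": [1.0], "b": [1, 2, 3], "c": [2, 3, 4]})
        assert any(f.startswith("insufficient_n") for f in rep.flags)

    def test_paired_identical(self):
        rep = compare_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rep.p_value == 1.0

    def test_friedman_on_identical_triples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rep = friedman_repeated(x, x, x)
        assert rep.p_value > 0.99

    def test_spearman_strictly_monotone(self):
        rep = spearman([1, 2, 3, 4, 5], [10, 100, 1000, 10000, 100000])
        assert rep.statistic == pytest.approx(1.0)

    def test_spearman_drops_nan_pairs(self):
        rep = spearman([1, 2, 3, np.nan, 5], [2, 4, 6, 8, np.nan])
        assert rep.n == 3
        assert rep.statistic == pytest.approx(1.0)

    def test_chi_square_independent_table(self):
        rep = chi_square([[20, 20], [20, 20]])
        assert rep.p_value == pytest.approx(1.0)

    def test_chi_square_drops_empty_rows(self):
        rep = chi_square([[10, 5], [0, 0], [5, 10]])
        assert np.isfinite(rep.p_value)


class TestStepwise:
    @staticmethod
    def make_data(seed, n=500, k_noise=2, signal=2.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, k_noise + 2)})
        df["y"] = signal * df["x1"] + rng.normal(size=n)
        return df

    def test_recovers_true_predictor(self):
        df = self.make_data(seed=1)
        res = stepwise_multivariate(df, "y", ["x1", "x2", "x3"])
        assert res.retained == ["x1"]
        assert res.variables["x1"].p_univariate < 1e-10
        assert res.model_f is not None and res.model_f > 100

    def test_duplicate_predictor_keeps_exactly_one(self):
        df = self.make_data(seed=2)
        df["x1_copy"] = df["x1"]
        res = stepwise_multivariate(df, "y", ["x1", "x1_copy", "x2"])
        kept = set(res.retained)
        assert len(kept & {"x1", "x1_copy"}) == 1

    def test_candidate_order_invariance(self):
        df = self.make_data(seed=3, k_noise=3)
        df["y"] = 1.5 * df["x1"] - 1.0 * df["x2"] + np.random.default_rng(4).normal(size=len(df))
        a = stepwise_multivariate(df, "y", ["x1", "x2", "x3", "x4"])
        b = stepwise_multivariate(df, "y", ["x4", "x3", "x2", "x1"])
        assert set(a.retained) == set(b.retained)

    def test_collinearity_diagnostics_reported(self):
        rng = np.random.default_rng(5)
        n = 400
        x1 = rng.normal(size=n)
        x2 = x1 * 0.9 + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        df["y"] = x1 + x2 + rng.normal(size=n)
        res = stepwise_multivariate(df, "y", ["x1", "x2"])
        for name in res.retained:
            v = res.variables[name]
            assert v.vif is not None and v.vif <= 5.0
            assert v.tolerance is not None and v.tolerance >= 0.20

    def test_pure_noise_outcome_gives_empty_or_tiny_model(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({f"x{i}": rng.normal(size=300) for i in range(1, 4)})
        df["y"] = rng.normal(size=300)
        res = stepwise_multivariate(df, "y", ["x1", "x2", "x3"])
        if not res.retained:
            assert res.model_f is None
            assert all(
                v.stage in ("dropped-by-screen", "dropped-by-stepwise")
                for v in res.variables.values()
            )

    def test_summary_reports_model_f(self):
        res = stepwise_multivariate(self.make_data(seed=7), "y", ["x1", "x2", "x3"])
        assert res.summary().startswith("F = ")
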