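"""Diagnostic-accuracy statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from fractalperf.diagstats import (
    AgreementResult,
    ConfusionCounts,
    cohens_kappa,
    compare_auc,
    exact_proportion,
    group_tests,
    pooled_counts,
    reader_agreement,
    roc_auc,
    round_half_up,
    sens_spec,
    weighted_kappa,
    youden_cutoff,
)
from fractalperf.errors import InputError, UndefinedStatisticError


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with ties scored 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSensSpec:
    def test_direct_ratio_arithmetic(self):
        counts = ConfusionCounts(tp=42, fn=7, tn=11, fp=12)
        sens, spec = sens_spec(counts)
        assert sens.point == pytest.approx(42 / 49)
        assert spec.point == pytest.approx(11 / 23)

    def test_ci_matches_beta_quantile_oracle(self):
        """Exact interval bounds equal the beta-quantile closed form to 4
        decimals (before percent rounding)."""
        for k, n in [(49, 49), (21, 23), (19, 23), (11, 14), (0, 10), (3, 7)]:
            est = exact_proportion(k, n)
            lo = stats.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
            hi = stats.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
            assert est.ci_low == pytest.approx(lo, abs=1e-4)
            assert est.ci_high == pytest.approx(hi, abs=1e-4)

    def test_zero_denominator_undefined_not_zero(self):
        sens, spec = sens_spec(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert sens is None
        assert spec is not None

    def test_rounding_half_up(self):
        assert round_half_up(90.5) == 91
        assert round_half_up(90.49) == 90

    def test_pooled_counts_totals(self):
        pred = [1, 2, 3, 4, 2, 1]
        ref = [1, 2, 4, 4, 1, 2]
        counts = pooled_counts(pred, ref, split=2)
        assert counts.total == 6
        assert counts.tp == 3 and counts.fn == 1 and counts.tn == 1 and counts.fp == 1


class TestWeightedKappa:
    def test_perfect_agreement(self):
        assert weighted_kappa([1, 2, 3, 2, 1], [1, 2, 3, 2, 1]) == pytest.approx(1.0)

    def test_hand_computed_confusion_matrix(self):
        """3-class confusion [[2,1,0],[1,2,1],[0,1,2]]: kappa = 2/3 by direct
        formula evaluation (sum wO = 1, sum wE = 3)."""
        pred, ref = [], []
        conf = [[2, 1, 0], [1, 2, 1], [0, 1, 2]]
        for i in range(3):
            for j in range(3):
                pred += [i + 1] * conf[i][j]
                ref += [j + 1] * conf[i][j]
        assert weighted_kappa(pred, ref) == pytest.approx(2.0 / 3.0)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        a = rng.integers(1, 5, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 1, 4)
        assert weighted_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b, weights="quadratic"))
        assert weighted_kappa(a, b, weighting="linear") == pytest.approx(
            cohen_kappa_score(a, b, weights="linear"))

    def test_chance_agreement_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 5, 4000)
        b = rng.permutation(a)
        assert abs(weighted_kappa(a, b)) < 0.06

    def test_binary_equals_unweighted(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert weighted_kappa(a, b, weighting="quadratic") == pytest.approx(cohens_kappa(a, b))

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            weighted_kappa([1, 1, 1], [1, 1, 1])

    def test_bootstrap_ci_seeded_and_covering(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 5, 40)
        b = np.clip(a + rng.integers(-1, 2, 40), 1, 4)
        k1, ci1 = weighted_kappa(a, b, ci=True, seed=7)
        k2, ci2 = weighted_kappa(a, b, ci=True, seed=7)
        assert ci1 == ci2
        assert ci1[0] <= k1 <= ci1[1]


class TestRocAuc:
    def test_toy_set_equals_pair_counting(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.8, 0.2]
        labels = [True, True, True, False, False, False]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(7.5 / 9.0)
        assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_rank_estimator_equals_brute_force_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(6, 21))
            scores = rng.choice(np.linspace(0, 1, 7), n)  # force ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_perfect_separation(self):
        auc, (lo, hi) = roc_auc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert auc == 1.0
        assert hi == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 400)
        labels = np.arange(400) % 2 == 0
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.07

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([1, 2, 3], [True, True, True])


class TestYoudenCutoff:
    def test_perfectly_separated(self):
        cut = youden_cutoff([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert 0.2 <= cut < 0.8

    def test_tie_resolves_to_lower_cutoff(self):
        # J is maximal (=1) only between the classes; among equal-J candidates
        # the smaller score wins
        cut = youden_cutoff([1, 2, 3, 10, 20, 30], [0, 0, 0, 1, 1, 1])
        assert cut == 3


class TestCompareAuc:
    def test_clearly_different_aucs_small_p(self):
        rng = np.random.default_rng(6)
        n = 150
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        good = np.concatenate([rng.normal(2.5, 1, n), rng.normal(0, 1, n)])
        noise = rng.normal(0, 1, 2 * n)
        auc_a, auc_b, p = compare_auc(good, noise, labels)
        assert auc_a > 0.9 and abs(auc_b - 0.5) < 0.15
        assert p < 0.001

    def test_identical_scores_p_one(self):
        scores = [0.1, 0.5, 0.9, 0.2, 0.6, 0.8]
        labels = [0, 1, 1, 0, 0, 1]
        _, _, p = compare_auc(scores, scores, labels)
        assert p == 1.0


class TestGroupTests:
    def test_identical_groups_large_p(self):
        res = group_tests({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
        assert res.pairwise[("a", "b")] > 0.99

    def test_exact_separation_matches_enumeration(self):
        """{1,2,3} vs {10,11,12}: exact two-sided p = 2 / C(6,3) = 0.1."""
        res = group_tests({"lo": [1, 2, 3], "hi": [10, 11, 12]})
        assert res.pairwise[("lo", "hi")] == pytest.approx(0.1)

    def test_bonferroni_arithmetic(self):
        res = group_tests({"a": [1, 2, 3], "b": [10, 11, 12], "c": [20, 21, 22]})
        assert len(res.pairwise) == 3
        for pair, p in res.pairwise.items():
            assert res.pairwise_adjusted[pair] == pytest.approx(min(1.0, 3 * p))

    def test_all_identical_values_p_one(self):
        res = group_tests({"a": [5, 5], "b": [5, 5, 5]})
        assert res.kruskal_p == 1.0
        assert res.pairwise[("a", "b")] == 1.0


class TestReaderAgreement:
    def test_identical_readings(self):
        res = reader_agreement([2.1, 2.3, 2.5, 2.2], [2.1, 2.3, 2.5, 2.2])
        assert res.bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.kappa == 1.0

    def test_hand_computed_bias_and_limits(self):
        """Differences {0.01, 0.03, 0.02}: bias 0.02, limits from sd oracle."""
        a = np.array([2.21, 2.33, 2.42])
        b = a - np.array([0.01, 0.03, 0.02])
        res = reader_agreement(a, b)
        sd = np.std([0.01, 0.03, 0.02], ddof=1)
        assert res.bias == pytest.approx(0.02)
        assert res.loa_low == pytest.approx(0.02 - 1.96 * sd)
        assert res.loa_high == pytest.approx(0.02 + 1.96 * sd)

    def test_categorized_kappa(self):
        from fractalperf import predict_group_fd

        a = [2.1, 2.25, 2.35, 2.45]
        b = [2.15, 2.28, 2.36, 2.5]
        res = reader_agreement(a, b, categorize=predict_group_fd)
        assert res.kappa == 1.0  # same predicted group everywhere

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            reader_agreement([1.0], [1.0])
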