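"""ROC/Youden/DeLong statistics, Mann-Whitney, and exact binomial intervals."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ctdnaflow.diagnostics import (
    ConfusionMatrix,
    auc_ztest,
    clopper_pearson,
    confusion_metrics,
    delong_compare,
    mann_whitney,
    roc_auc,
    youden_cutoff,
)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k, n, lo, hi",
        [
            (6, 6, 54.1, 100.0),
            (29, 29, 88.1, 100.0),
            (26, 26, 86.8, 100.0),
            (4, 4, 39.8, 100.0),
            (5, 5, 47.8, 100.0),
        ],
    )
    def test_k_equals_n_bounds(self, k, n, lo, hi):
        got_lo, got_hi = clopper_pearson(k, n)
        assert round(got_lo, 1) == lo and round(got_hi, 1) == hi

    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 1)
        assert lo == 0.0 and hi == pytest.approx(97.5, abs=0.05)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    @pytest.mark.parametrize("p_true", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("n", [10, 37])
    def test_empirical_coverage_at_least_nominal(self, p_true, n, rng):
        bounds = np.array([clopper_pearson(k, n) for k in range(n + 1)]) / 100.0
        ks = rng.binomial(n, p_true, size=2000)
        covered = (bounds[ks, 0] <= p_true) & (p_true <= bounds[ks, 1])
        assert covered.mean() >= 0.95


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            # (tp, fp, tn, fn) -> sens, spec, ppv, npv, accuracy in percent
            ((6, 2, 29, 0), (100.0, 93.5, 75.0, 100.0, 94.6)),
            ((4, 2, 25, 0), (100.0, 92.6, 66.7, 100.0, 93.5)),
            ((5, 1, 24, 0), (100.0, 96.0, 83.3, 100.0, 96.7)),
            ((4, 0, 26, 1), (80.0, 100.0, 100.0, 96.3, 96.8)),
        ],
    )
    def test_performance_table_rows(self, matrix, expected):
        metrics = confusion_metrics(ConfusionMatrix(*matrix))
        got = tuple(
            round(metrics[name].estimate, 1)
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        )
        assert got == expected

    def test_ci_bounds_bracket_estimate(self):
        metrics = confusion_metrics(ConfusionMatrix(6, 2, 29, 0))
        for m in metrics.values():
            assert 0 <= m.ci_low <= m.estimate <= m.ci_high <= 100

    def test_zero_denominator_flagged_not_fatal(self):
        metrics = confusion_metrics(ConfusionMatrix(0, 0, 5, 0))
        assert not metrics["ppv"].defined and math.isnan(metrics["ppv"].estimate)
        assert metrics["accuracy"].estimate == 100.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(0, 0, 0, 0)


def _exact_mwu_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group assignments."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = sum(x > y for x in a for y in b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(x > y for x in ga for y in gb))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestMannWhitney:
    def test_identical_single_elements(self):
        assert mann_whitney([1.0], [1.0]).p == 1.0

    def test_complete_separation_of_triples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_exact_p_matches_full_enumeration(self, rng):
        a = rng.normal(0, 1, 8).tolist()
        b = rng.normal(0.8, 1, 8).tolist()
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p == pytest.approx(_exact_mwu_oracle(a, b), abs=1e-12)

    def test_large_or_tied_samples_use_tie_corrected_normal(self, rng):
        a = rng.integers(0, 5, 15).astype(float).tolist()
        b = rng.integers(1, 6, 15).astype(float).tolist()
        assert mann_whitney(a, b).method == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_count_oracle_and_sklearn(self, rng):
        scores = rng.normal(size=20)
        scores[3] = scores[12]  # inject a tie across classes
        labels = np.array([0] * 10 + [1] * 10)
        pos, neg = scores[labels == 1], scores[labels == 0]
        oracle = np.mean(
            [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        )
        auc = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle, abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_equals_u_statistic_identity(self, rng):
        for _ in range(10):
            pos = rng.normal(0.5, 1, 9)
            neg = rng.normal(0, 1, 13)
            auc = roc_auc(
                np.concatenate([pos, neg]), [1] * len(pos) + [0] * len(neg)
            )
            u = mann_whitney(pos, neg).u
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestAucZtest:
    def test_pure_chance_gives_p_one(self):
        res = auc_ztest([1.0] * 8, [0, 1] * 4)
        assert res.auc == 0.5 and res.p == 1.0

    def test_perfect_tiny_sample_flagged(self):
        res = auc_ztest([1, 2, 10, 11], [0, 0, 1, 1])
        assert res.auc == 1.0 and res.small_sample

    def test_doubling_sample_strengthens_evidence(self):
        scores = [0.0, 1.5, 2.5, 4.0, 1.0, 2.0, 3.0, 5.0]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        z1 = abs(auc_ztest(scores, labels).z)
        z2 = abs(auc_ztest(scores * 2, labels * 2).z)
        assert z2 > z1

    def test_strong_separation_at_study_scale_is_significant(self, rng):
        neg = rng.normal(-1.5, 0.6, 31)
        pos = rng.normal(0.5, 0.6, 6)
        scores = np.concatenate([neg, pos])
        labels = [0] * 31 + [1] * 6
        res = auc_ztest(scores, labels)
        assert res.auc > 0.9
        assert res.p < 0.01

    def test_matches_placement_variance_hand_computation(self):
        pos = np.array([0.9, 0.4, 0.7])
        neg = np.array([0.2, 0.5, 0.1, 0.3])
        v10 = np.array([np.mean([(p > n) + 0.5 * (p == n) for n in neg]) for p in pos])
        v01 = np.array([np.mean([(p > n) + 0.5 * (p == n) for p in pos]) for n in neg])
        auc = v10.mean()
        se = math.sqrt(np.var(v10, ddof=1) / 3 + np.var(v01, ddof=1) / 4)
        z = (auc - 0.5) / se
        res = auc_ztest(np.concatenate([pos, neg]), [1, 1, 1, 0, 0, 0, 0])
        assert res.z == pytest.approx(z, abs=1e-12)


class TestYoudenCutoff:
    def test_perfect_split_uses_midpoint(self):
        res = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.cutoff == 2.5
        assert res.j == pytest.approx(1.0)
        assert res.sens_at_cutoff == 100.0 and res.spec_at_cutoff == 100.0

    def test_all_scores_equal_is_degenerate(self):
        res = youden_cutoff([3.0] * 6, [0, 0, 0, 1, 1, 1])
        assert res.degenerate
        assert res.cutoff == -math.inf
        assert res.sens_at_cutoff == 100.0 and res.spec_at_cutoff == 0.0

    def test_matches_exhaustive_threshold_oracle(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=12), 2)
            labels = rng.integers(0, 2, 12)
            if labels.sum() in (0, 12):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            best_j = -2.0
            grid = np.unique(scores)
            for c in np.concatenate([[-np.inf], (grid[:-1] + grid[1:]) / 2, [np.inf]]):
                j = np.mean(pos > c) + np.mean(neg <= c) - 1
                best_j = max(best_j, j)
            res = youden_cutoff(scores, labels)
            assert res.j == pytest.approx(best_j, abs=1e-12)

    def test_reported_sens_spec_match_induced_confusion_matrix(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:3] = 1
        labels[-3:] = 0
        res = youden_cutoff(scores, labels)
        matrix = ConfusionMatrix.from_predictions(scores > res.cutoff, labels == 1)
        metrics = confusion_metrics(matrix)
        assert res.sens_at_cutoff == pytest.approx(metrics["sensitivity"].estimate)
        assert res.spec_at_cutoff == pytest.approx(metrics["specificity"].estimate)

    def test_observed_style_returns_an_observed_score(self):
        scores = [0.1, 0.4, 0.9, 1.3]
        res = youden_cutoff(scores, [0, 0, 1, 1], cutoff_style="observed")
        assert res.cutoff in scores


def _delong_oracle_p(s1, s2, labels):
    """Explicit-loop DeLong comparison for the test's independent check."""
    s1, s2, labels = np.asarray(s1), np.asarray(s2), np.asarray(labels, bool)
    pos1, neg1 = s1[labels], s1[~labels]
    pos2, neg2 = s2[labels], s2[~labels]
    m, n = pos1.size, neg1.size

    def placements(pos, neg):
        v10 = np.array([np.mean([(p > x) + 0.5 * (p == x) for x in neg]) for p in pos])
        v01 = np.array([np.mean([(x > p) + 0.5 * (x == p) for p in pos]) for x in neg])
        # v01 here is 1 - placement; convert to the same orientation
        return v10, 1 - v01

    v10_1, v01_1 = placements(pos1, neg1)
    v10_2, v01_2 = placements(pos2, neg2)
    auc1, auc2 = v10_1.mean(), v10_2.mean()

    def cov(x, y):
        return np.sum((x - x.mean()) * (y - y.mean())) / (len(x) - 1)

    var = (
        cov(v10_1, v10_1) + cov(v10_2, v10_2) - 2 * cov(v10_1, v10_2)
    ) / m + (cov(v01_1, v01_1) + cov(v01_2, v01_2) - 2 * cov(v01_1, v01_2)) / n
    from scipy.stats import norm

    z = (auc1 - auc2) / math.sqrt(var)
    return 2 * norm.sf(abs(z))


class TestDeLongCompare:
    def test_identical_scores_give_p_one(self):
        s = [0.1, 0.9, 0.3, 0.7, 0.5, 0.2]
        labels = [0, 1, 0, 1, 1, 0]
        assert delong_compare(s, s, labels).p == 1.0

    def test_monotone_transform_preserves_auc_and_p(self):
        s = [0.1, 0.9, 0.3, 0.7, 0.5, 0.2]
        labels = [0, 1, 0, 1, 1, 0]
        res = delong_compare(s, [math.tanh(3 * x) for x in s], labels)
        assert res.auc_1 == res.auc_2
        assert res.p == 1.0

    def test_matches_hand_computed_placement_covariance(self):
        s1 = [0.2, 0.5, 0.6, 0.9, 0.1, 0.4, 0.35, 0.8]
        s2 = [0.3, 0.2, 0.7, 0.6, 0.25, 0.5, 0.1, 0.4]
        labels = [0, 0, 1, 1, 0, 0, 1, 1]
        res = delong_compare(s1, s2, labels)
        assert res.p == pytest.approx(_delong_oracle_p(s1, s2, labels), abs=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2], [1, 2, 3], [0, 1])
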