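"""Chi-square association statistic, utility sensitivities and top-K release."""

import itertools

import numpy as np
import pytest
from scipy import stats

from privgwas import (
    EnumerationError,
    ParameterError,
    ValidationError,
    chi2_sensitivity,
    chi2_stat,
    hamming_utility,
    release_topk,
    topk_overlap,
    true_topk,
)
from privgwas.topk import (
    TopKRelease,
    _CHI2_SENSITIVITY_CACHE,
    association_statistics,
    chi2_pvalues,
)


class TestChi2Stat:
    def test_identical_proportions_give_zero(self):
        assert chi2_stat(50, 100, 50, 100) == 0.0

    @pytest.mark.parametrize(
        "a,ct,c,cot",
        [(30, 100, 10, 100), (3, 20, 15, 30), (0, 10, 5, 10), (199, 400, 170, 348)],
    )
    def test_matches_contingency_table_oracle(self, a, ct, c, cot):
        table = np.array([[a, ct - a], [c, cot - c]])
        expected = stats.chi2_contingency(table, correction=False).statistic
        assert chi2_stat(a, ct, c, cot) == pytest.approx(expected, abs=1e-9)

    def test_label_swap_symmetry(self):
        assert chi2_stat(30, 100, 10, 80) == pytest.approx(chi2_stat(10, 80, 30, 100))

    def test_degenerate_margin_is_zero(self):
        assert chi2_stat(100, 100, 80, 80) == 0.0
        assert chi2_stat(0, 100, 0, 80) == 0.0

    def test_minor_above_total_rejected(self):
        with pytest.raises(ValidationError):
            chi2_stat(101, 100, 0, 100)

    def test_pvalues_monotone_in_statistic(self):
        s = np.array([0.0, 1.0, 5.0, 25.0])
        p = chi2_pvalues(s)
        assert (np.diff(p) < 0).all() and p[0] == 1.0


def _chi2_sensitivity_bruteforce(n_case, n_control):
    """Independent oracle: plain loops over tables and removal moves."""
    worst = 0.0
    for a in range(2 * n_case + 1):
        for c in range(2 * n_control + 1):
            before = chi2_stat(a, 2 * n_case, c, 2 * n_control)
            for d in range(3):
                if a - d < 0 or (2 * n_case - a) - (2 - d) < 0 or n_case < 2:
                    continue
                after = chi2_stat(a - d, 2 * (n_case - 1), c, 2 * n_control)
                worst = max(worst, abs(after - before))
    return worst


class TestChi2Sensitivity:
    @pytest.mark.parametrize("n_case,n_control", [(2, 3), (5, 4), (8, 8)])
    def test_matches_bruteforce_oracle(self, n_case, n_control):
        assert chi2_sensitivity(n_case, n_control) == pytest.approx(
            _chi2_sensitivity_bruteforce(n_case, n_control), abs=1e-12
        )

    def test_identical_neighbor_changes_nothing(self):
        # the d = 0 move at a balanced table: removing an all-major individual
        before = chi2_stat(10, 20, 10, 20)
        after = chi2_stat(10, 18, 10, 20)
        assert abs(after - before) <= chi2_sensitivity(10, 10)

    def test_enumeration_budget_requires_explicit_approx(self):
        key = (5000, 5000)
        _CHI2_SENSITIVITY_CACHE.pop(key, None)
        with pytest.raises(EnumerationError):
            chi2_sensitivity(*key)
        bound = chi2_sensitivity(*key, allow_approx=True)
        assert bound == 2 * (key[0] + key[1])

    def test_cached(self):
        chi2_sensitivity(6, 6)
        assert (6, 6) in _CHI2_SENSITIVITY_CACHE


class TestHammingUtility:
    def test_zero_at_boundary(self):
        b = chi2_stat(15, 40, 5, 40)
        assert hamming_utility(15, 40, 5, 40, b) == 0.0

    def test_sign_reflects_side(self):
        b = chi2_stat(12, 40, 5, 40)
        assert hamming_utility(20, 40, 5, 40, b) > 0  # far above the boundary
        assert hamming_utility(6, 40, 5, 40, b) < 0

    def test_strong_association_scores_highest(self):
        b = 1.0
        scores = [
            hamming_utility(a, 200, 0, 200, b) for a in (200, 100, 30, 10)
        ]
        assert scores[0] == max(scores)
        assert scores == sorted(scores, reverse=True)

    @pytest.mark.parametrize("boundary", [0.5, 2.0, 6.5])
    def test_lipschitz_in_single_moves_small_cohort(self, boundary):
        # one individual's change moves any score by at most 1 (n = 6 here;
        # the full n = 10 sweep runs in the acceptance suite)
        n = 6
        for a in range(2 * n + 1):
            for c in range(0, 2 * n + 1, 3):
                s0 = hamming_utility(a, 2 * n, c, 2 * n, boundary)
                for d in range(3):
                    if a - d < 0 or (2 * n - a) - (2 - d) < 0:
                        continue
                    s1 = hamming_utility(a - d, 2 * (n - 1), c, 2 * n, boundary)
                    assert abs(s1 - s0) <= 1.0 + 1e-12


class TestRelease:
    def test_zero_noise_recovers_exact_topk(self, task2_counts):
        case, control = task2_counts
        for k in (1, 5):
            rel = release_topk(case, control, k, 1e12, utility="chi2", seed=0)
            assert topk_overlap(rel, true_topk(case, control, k)) == 1.0

    def test_release_everything_is_trivially_correct(self, task1_counts):
        case, control = task1_counts
        m = case.n_snvs
        rel = release_topk(case, control, m, 0.5, utility="chi2", seed=3)
        assert topk_overlap(rel, true_topk(case, control, m)) == 1.0

    def test_k_out_of_range_rejected(self, task1_counts):
        case, control = task1_counts
        with pytest.raises(ParameterError):
            release_topk(case, control, case.n_snvs + 1, 1.0, seed=0)

    def test_beats_random_baseline(self, task2_counts):
        case, control = task2_counts
        k, m = 5, case.n_snvs
        tt = true_topk(case, control, k)
        overlaps = [
            topk_overlap(release_topk(case, control, k, 1.0, "chi2", seed=s), tt)
            for s in range(40)
        ]
        assert np.mean(overlaps) > k / m  # uniform-selection baseline

    def test_hamming_release_runs_and_respects_k(self, task1_counts):
        case, control = task1_counts
        rel = release_topk(case, control, 3, 1.0, utility="hamming", seed=7)
        assert len(rel.released_snvs) == 3
        assert len(set(rel.released_snvs)) == 3

    def test_sensitivity_ordering_hamming_below_chi2(self):
        for sizes in [(4, 4), (8, 8), (10, 12)]:
            assert 1.0 <= chi2_sensitivity(*sizes)

    def test_overlap_monotone_in_epsilon(self, task2_counts):
        case, control = task2_counts
        k = 5
        tt = true_topk(case, control, k)
        means = []
        for eps in (0.1, 1.0, 10.0, 1e6):
            means.append(
                np.mean(
                    [
                        topk_overlap(
                            release_topk(case, control, k, eps, "chi2", seed=s), tt
                        )
                        for s in range(25)
                    ]
                )
            )
        # non-decreasing in eps, small Monte-Carlo slack
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 0.08


class TestOverlapMetric:
    def test_identical_sets(self):
        assert topk_overlap(["a", "b"], ["b", "a"]) == 1.0

    def test_disjoint_sets(self):
        assert topk_overlap(["a", "b"], ["c", "d"]) == 0.0

    def test_partial_overlap(self):
        assert topk_overlap(list("abcde"), list("abfgh")) == pytest.approx(0.4)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            topk_overlap(["a"], ["a", "b"])

    def test_release_container_rejects_duplicates(self):
        with pytest.raises(ValidationError):
            TopKRelease(K=2, released_snvs=["a", "a"], utility_name="chi2", epsilon_total=1.0)


class TestTrueTopK:
    def test_ties_broken_by_snv_id(self, task1_counts):
        case, control = task1_counts
        stats_ = association_statistics(case, control)
        k = 10
        top = true_topk(case, control, k)
        assert len(top) == k
        # deterministic: repeated calls agree
        assert top == true_topk(case, control, k)
        # every member's statistic is >= every non-member's (up to id tie rule)
        kth = sorted(stats_, reverse=True)[k - 1]
        lookup = dict(zip(case.snv_ids, stats_))
        assert all(lookup[s] >= kth - 1e-12 for s in top)
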