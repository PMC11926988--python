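"""Evaluation statistics vs hand computations and brute-force oracles."""

import numpy as np
import pytest
from lifelines.utils import concordance_index as ll_concordance

from dualsurv.stats import (assign_bins, concordance_index, discretize_times,
                            km_curve, logrank_test, median_risk_split,
                            stratify_8, stratum_weights)


class TestDiscretizeTimes:
    def test_quartile_edges_and_labels_hand_case(self):
        times = np.arange(10.0, 90.0, 10.0)  # 10..80
        censor = np.zeros(8, dtype=int)
        edges, labels = discretize_times(times, censor)
        assert np.allclose(edges, [27.5, 45.0, 62.5])
        assert np.array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_identical_times_rejected(self):
        with pytest.raises(ValueError):
            discretize_times(np.full(10, 7.0), np.zeros(10, dtype=int))

    def test_censored_labeled_by_same_edges(self):
        times = np.array([10, 20, 30, 40, 50, 60, 70, 80, 100.0])
        censor = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1])
        edges, labels = discretize_times(times, censor)
        assert labels[-1] == 4  # censored at 100 falls past the last edge
        assert np.allclose(edges, np.percentile(times[:-1], [25, 50, 75]))

    def test_edges_use_only_uncensored_times(self):
        times = np.array([10, 20, 30, 40, 50, 60, 70, 80,
                          1000, 2000, 3000.0])
        censor = np.array([0] * 8 + [1] * 3)
        edges, _ = discretize_times(times, censor)
        assert np.allclose(edges, [27.5, 45.0, 62.5])

    def test_too_few_uncensored_rejected(self):
        with pytest.raises(ValueError):
            discretize_times([1.0, 2.0, 3.0], [0, 0, 1])

    def test_assign_bins_matches_training_rule(self):
        edges = np.array([27.5, 45.0, 62.5])
        assert np.array_equal(assign_bins(edges, [5, 27.5, 45.0, 99]),
                              [1, 2, 3, 4])


class TestStratify8:
    def test_corner_strata(self):
        assert stratify_8([1], [0])[0] == 1
        assert stratify_8([4], [1])[0] == 8

    def test_all_combinations_bijective(self):
        labels = np.repeat(np.arange(1, 5), 2)
        censor = np.tile([0, 1], 4)
        strata = stratify_8(labels, censor)
        assert sorted(strata) == list(range(1, 9))

    def test_inverse_frequency_weights_mean_one(self, rng):
        labels = rng.integers(1, 5, size=200)
        censor = rng.integers(0, 2, size=200)
        w = stratum_weights(labels, censor)
        assert np.isclose(w.mean(), 1.0)
        # within a stratum all weights equal, inverse to its count
        strata = stratify_8(labels, censor)
        for s in np.unique(strata):
            assert np.allclose(w[strata == s], w[strata == s][0])


class TestConcordanceIndex:
    def test_perfect_ranking(self):
        assert concordance_index([2, 4, 6], [0, 0, 0], [0.9, 0.5, 0.1]) == 1.0

    def test_all_tied_risks_give_half(self):
        assert concordance_index([1, 2, 3], [0, 0, 0], [1.0, 1.0, 1.0]) == 0.5

    def test_censored_hand_case(self):
        # comparable: (1,2),(1,3),(1,4),(3,4); concordant: 3 of 4
        ci = concordance_index([1, 2, 3, 4], [0, 1, 0, 1], [4, 3, 1, 2])
        assert ci == 0.75

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1, 1], [0.5, 0.3])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadratic_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(5, 101))
            times = rng.exponential(10, size=n).round(1)
            censor = rng.integers(0, 2, size=n)
            if (censor == 0).sum() < 2:
                censor[:2] = 0
            risks = rng.normal(size=n).round(2)
            conc = comp = 0.0
            for i in range(n):
                for j in range(n):
                    if times[i] < times[j] and censor[i] == 0:
                        comp += 1
                        if risks[i] > risks[j]:
                            conc += 1
                        elif risks[i] == risks[j]:
                            conc += 0.5
            assert concordance_index(times, censor, risks) == conc / comp

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        n = 80
        times = rng.exponential(10, size=n) + rng.uniform(0, 1e-6, n)
        censor = rng.integers(0, 2, size=n)
        risks = rng.normal(size=n)
        ours = concordance_index(times, censor, risks)
        theirs = ll_concordance(times, -risks, event_observed=1 - censor)
        assert np.isclose(ours, theirs, atol=1e-12)

    def test_random_scores_average_one_half(self, rng):
        vals = []
        for _ in range(300):
            n = 40
            times = rng.exponential(10, size=n)
            censor = rng.integers(0, 2, size=n)
            vals.append(concordance_index(times, censor, rng.normal(size=n)))
        assert abs(np.mean(vals) - 0.5) < 0.02


class TestKaplanMeier:
    def test_two_events(self):
        curve = km_curve([1.0, 2.0], [0, 0])
        assert np.allclose(curve.survival_probs, [0.5, 0.0])

    def test_all_censored_stays_at_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.event_times.size == 0  # no drops; S stays 1

    def test_hand_case_with_risk_set_bookkeeping(self):
        # times [1,1,2,3], censor [0,1,0,1]: S(1)=3/4, S(2)=3/4*1/2
        curve = km_curve([1.0, 1.0, 2.0, 3.0], [0, 1, 0, 1])
        assert np.allclose(curve.event_times, [1.0, 2.0])
        assert np.allclose(curve.survival_probs, [0.75, 0.375])
        assert np.array_equal(curve.at_risk, [4, 2])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = np.sort(rng.exponential(5, size=40))
        curve = km_curve(times, np.zeros(40, dtype=int))
        n = len(times)
        empirical = 1.0 - np.searchsorted(times, curve.event_times,
                                          side="right") / n
        assert np.allclose(curve.survival_probs, empirical, atol=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0]
        c = [0, 0, 1]
        chi2, p = logrank_test(t, c, t, c)
        assert np.isclose(chi2, 0.0, atol=1e-12)
        assert np.isclose(p, 1.0, atol=1e-12)

    def test_separated_groups_match_hand_tally(self):
        # A: events at 1, 2; B: events at 10, 20
        chi2, p = logrank_test([1.0, 2.0], [0, 0], [10.0, 20.0], [0, 0])
        # hand hypergeometric tally: O_A=2, E_A=1/2+1/3=5/6,
        # V=sum d(n1 n2)(n-d)/(n^2 (n-1)) = 1/4 + 2/9; chi2=(O-E)^2/V
        from scipy.stats import chi2 as chi2_dist
        V = 0.25 + 2.0 / 9.0
        expected = (2 - 5.0 / 6.0) ** 2 / V
        assert np.isclose(chi2, expected, atol=1e-10)
        assert np.isclose(p, chi2_dist.sf(expected, df=1), atol=1e-10)

    def test_invariant_to_group_label_swap(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(10, 25)
        ca, cb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        s1, p1 = logrank_test(ta, ca, tb, cb)
        s2, p2 = logrank_test(tb, cb, ta, ca)
        assert np.isclose(s1, s2) and np.isclose(p1, p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [0])


class TestMedianRiskSplit:
    def test_even_split(self):
        groups = median_risk_split([1.0, 2.0, 3.0, 4.0])
        assert list(groups) == ["low", "low", "high", "high"]

    def test_all_equal_degenerates_to_low_with_warning(self):
        with pytest.warns(UserWarning):
            groups = median_risk_split([2.0, 2.0, 2.0])
        assert (groups == "low").all()

    def test_odd_count_median_element_goes_low(self):
        groups = median_risk_split([1.0, 2.0, 3.0])
        assert list(groups) == ["low", "low", "high"]
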