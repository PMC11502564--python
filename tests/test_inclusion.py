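"""Inclusion probabilities: closed forms against the exhaustive enumeration oracle."""

import numpy as np
import pytest

from nccdesign import (
    at_risk_matrix,
    compute_weights,
    enumerate_design,
    inclusion_probabilities,
    joint_inclusion,
    sample_modified,
    sampling_weights,
)
from nccdesign.inclusion import pairwise_design_weights


class TestFirstOrder:
    def test_worked_modified_realization(self, toy_cohort, toy_modified_realization):
        w = compute_weights(toy_cohort, toy_modified_realization)
        pi = dict(zip(w.subject_ids.tolist(), w.pi.tolist()))
        # r* = (9, 5, 2), m = 2; final pool fully taken => pi = 1 there
        assert pi[7] == pytest.approx(1.0)   # at risk at all three case times
        assert pi[10] == pytest.approx(1.0)
        # subject at risk at t1 and t2 only: 1 - (7/9)(3/5) = 24/45
        ar = at_risk_matrix(toy_cohort, [5], toy_modified_realization.case_times)
        pi5 = inclusion_probabilities(ar, toy_modified_realization.pool_sizes, 2)
        assert pi5[0] == pytest.approx(24 / 45)

    def test_worked_standard_pools(self, toy_cohort):
        # standard design r = (9, 6, 4): subject 10 at risk everywhere
        ar = at_risk_matrix(toy_cohort, [10], [1.0, 2.0, 3.0])
        pi = inclusion_probabilities(ar, [9, 6, 4], 2)
        assert pi[0] == pytest.approx(1 - (7 / 9) * (4 / 6) * (2 / 4))

    def test_cases_get_probability_one_and_weight_one(self, toy_cohort, toy_modified_realization):
        w = compute_weights(toy_cohort, toy_modified_realization)
        for cid in (1, 4, 6):
            i = list(w.subject_ids).index(cid)
            assert w.pi[i] == 1.0 and w.weights[i] == 1.0

    def test_inconsistent_pool_raises(self):
        with pytest.raises(ValueError, match="shortfall"):
            inclusion_probabilities(np.ones((1, 2), bool), [3], 5)


class TestSamplingWeights:
    def test_reciprocal_for_controls(self):
        w = sampling_weights(np.array([24 / 45, 1.0]), np.array([0, 1]))
        assert w[0] == pytest.approx(45 / 24)  # 1.875
        assert w[1] == 1.0

    def test_case_weight_overrides_pi(self):
        assert sampling_weights(np.array([0.4]), np.array([1]))[0] == 1.0

    def test_full_cohort_limit(self):
        w = sampling_weights(np.ones(4), np.zeros(4, int))
        np.testing.assert_array_equal(w, 1.0)

    def test_zero_pi_for_sampled_noncase_rejected(self):
        with pytest.raises(ValueError):
            sampling_weights(np.array([0.0]), np.array([0]))


class TestJointInclusion:
    def test_single_shared_time_closed_form(self):
        # both at risk only at t1 with r*=9, m=2: the only sample containing
        # both picks exactly {i,j} there, probability 1/C(9,2) = 1/36
        ai = np.array([True, False, False])
        aj = np.array([True, False, False])
        pij = joint_inclusion(ai, aj, [9, 5, 2], 2)
        assert pij == pytest.approx(2 / 9 + 2 / 9 - 1 + 21 / 36)
        assert pij == pytest.approx(1 / 36)

    def test_disjoint_at_risk_times_factorize(self):
        ai = np.array([True, True, False, False])
        aj = np.array([False, False, True, True])
        r, m = [10, 8, 6, 4], 2
        pi_i = 1 - (1 - 2 / 10) * (1 - 2 / 8)
        pi_j = 1 - (1 - 2 / 6) * (1 - 2 / 4)
        assert joint_inclusion(ai, aj, r, m) == pytest.approx(pi_i * pi_j)

    def test_certain_inclusion_consistency(self):
        # partner with pi = 1 (zero factor): pi_ij = pi_i
        ai = np.array([True, True, False])
        aj = np.array([True, True, True])
        pij = joint_inclusion(ai, aj, [9, 5, 2], 2)
        assert pij == pytest.approx(24 / 45)

    def test_pairwise_matrix_agrees_with_scalar(self, toy_cohort):
        sample = sample_modified(toy_cohort, 2, seed=12)
        w = compute_weights(toy_cohort, sample)
        nc, M = w.pairwise_design_matrix()
        for a in range(len(nc)):
            for b in range(a, len(nc)):
                i, j = w.subject_ids[nc[a]], w.subject_ids[nc[b]]
                expected = w.pair_weight(i, j) * w.sigma(i, j) / (w.pi[nc[a]] * w.pi[nc[b]])
                assert M[a, b] == pytest.approx(expected, abs=1e-10)


class TestEnumerationOracle:
    def test_probabilities_sum_to_one_and_count(self, toy_cohort):
        dist = enumerate_design(toy_cohort, 2, "standard")
        assert dist.total_probability() == pytest.approx(1.0, abs=1e-12)
        from math import comb

        assert dist.n_outcomes == comb(9, 2) * comb(6, 2) * comb(4, 2)

    def test_m_larger_than_pools_single_outcome(self):
        from nccdesign import Cohort

        coh = Cohort([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0], [1, 0, 0])
        dist = enumerate_design(coh, 5, "modified")
        assert dist.n_outcomes == 1
        assert dist.probabilities[0] == 1.0

    def test_budget_guard(self, toy_cohort):
        with pytest.raises(ValueError, match="budget"):
            enumerate_design(toy_cohort, 2, "standard", budget=10)

    def test_standard_marginals_match_formula(self, toy_cohort):
        dist = enumerate_design(toy_cohort, 2, "standard")
        ar = at_risk_matrix(toy_cohort, toy_cohort.ids, [1.0, 2.0, 3.0])
        pi = inclusion_probabilities(ar, [9, 6, 4], 2)
        for i, sid in enumerate(toy_cohort.ids.tolist()):
            if toy_cohort.event[i] == 0:
                assert dist.pi.get(sid, 0.0) == pytest.approx(pi[i], abs=1e-12)

    def test_modified_marginals_path_independent_pools(self, truncated_cohort):
        # delayed entry arranged so r_k* is the same along every path
        dist = enumerate_design(truncated_cohort, 2, "modified")
        assert dist.total_probability() == pytest.approx(1.0, abs=1e-12)
        times = truncated_cohort.case_times
        ar = at_risk_matrix(truncated_cohort, truncated_cohort.ids, times)
        pi = inclusion_probabilities(ar, [7, 5, 3], 2)
        for i, sid in enumerate(truncated_cohort.ids.tolist()):
            if truncated_cohort.event[i] == 0:
                assert dist.pi.get(sid, 0.0) == pytest.approx(pi[i], abs=1e-12)

    def test_modified_joint_path_independent_pools(self, truncated_cohort):
        dist = enumerate_design(truncated_cohort, 2, "modified")
        times = truncated_cohort.case_times
        ar = at_risk_matrix(truncated_cohort, truncated_cohort.ids, times)
        noncases = [i for i in range(10) if truncated_cohort.event[i] == 0]
        for a in noncases:
            for b in noncases:
                if a >= b:
                    continue
                i, j = truncated_cohort.ids[a], truncated_cohort.ids[b]
                key = (i, j) if str(i) < str(j) else (j, i)
                expected = joint_inclusion(ar[:, a], ar[:, b], [7, 5, 3], 2)
                assert dist.joint.get(key, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_horvitz_thompson_identity(self, truncated_cohort):
        # E(V_i / pi_i) = 1 exactly under the enumerated design distribution
        dist = enumerate_design(truncated_cohort, 2, "modified")
        for sid, pi_i in dist.pi.items():
            assert dist.expected_ht_sum(sid, pi_i) == pytest.approx(1.0, abs=1e-12)

    def test_sigma_negative_for_single_shared_time_pairs(self, toy_cohort):
        # within one time, without-replacement draws are negatively correlated
        dist = enumerate_design(toy_cohort, 2, "modified")
        # ids 2 and 3 are at risk only at t1
        pij = dist.joint.get((2, 3), 0.0)
        assert pij - dist.pi[2] * dist.pi[3] < 0

    def test_weighted_noncase_count_unbiased(self, truncated_cohort):
        # E( sum_{sampled non-cases} 1/pi ) = number of ever-at-risk non-cases
        dist = enumerate_design(truncated_cohort, 2, "modified")
        total = 0.0
        for sample, p in zip(dist.samples, dist.probabilities):
            ever = set().union(*[set(c) for c in sample])
            total += p * sum(1.0 / dist.pi[sid] for sid in ever)
        n_at_risk_noncases = len(dist.pi)
        assert total == pytest.approx(n_at_risk_noncases, abs=1e-9)

    def test_standard_vs_modified_pi_ordering_in_expectation(self, truncated_cohort):
        # exclusion from later pools shrinks them, raising per-time draw odds for
        # those remaining, but the never-sampled product still satisfies
        # pi_std >= ... comparison is made on the enumerated marginals
        std = enumerate_design(truncated_cohort, 2, "standard")
        mod = enumerate_design(truncated_cohort, 2, "modified")
        # every subject's standard inclusion probability is <= modified one here
        for sid in std.pi:
            assert std.pi[sid] <= mod.pi[sid] + 1e-12
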