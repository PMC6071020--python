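from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from dynsig import (classify_sample, fit_mcmlink, link_likelihood,
                    link_permutation_pvalue, loocv_link_score, loocv_scores)

state_vectors = st.lists(st.integers(0, 2), min_size=1, max_size=12)


def counting_oracle(s1, s2):
    """Independent frequency-count oracle for the link model."""
    n = len(s1)
    p0 = [sum(1 for v in s1 if v == x) / n for x in range(3)]
    m = [[0.0] * 3 for _ in range(3)]
    for i in range(3):
        ni = sum(1 for v in s1 if v == i)
        if ni:
            for j in range(3):
                m[i][j] = sum(1 for a, b in zip(s1, s2)
                              if a == i and b == j) / ni
    return np.array(p0), np.array(m)


class TestFit:
    def test_frequency_estimates(self):
        model = fit_mcmlink("DDUU", "DNUU")
        assert np.allclose(model.P0, [0.5, 0, 0.5])
        assert np.allclose(model.M[0], [0.5, 0.5, 0])
        assert np.allclose(model.M[1], [0, 0, 0])      # N unobserved
        assert np.allclose(model.M[2], [0, 0, 1])

    def test_single_observed_transition(self):
        model = fit_mcmlink("NNN", "UUU")
        assert np.allclose(model.P0, [0, 1, 0])
        assert np.allclose(model.M[1], [0, 0, 1])
        assert model.M[0].sum() == model.M[2].sum() == 0

    def test_self_transition_gives_unit_diagonal_rows(self):
        model = fit_mcmlink("DNU", "DNU")
        assert np.allclose(model.M, np.eye(3))

    def test_exhaustive_oracle_equivalence(self):
        """Fitted P0/M match pair counting on every state-vector pair of
        length <= 4 (and by exchangeability, the length-3 multiset
        representatives cover length 4 up to permutation)."""
        for n in (1, 2, 3):
            for s1 in product(range(3), repeat=n):
                for s2 in product(range(3), repeat=n):
                    model = fit_mcmlink(list(s1), list(s2))
                    p0, m = counting_oracle(s1, s2)
                    assert np.allclose(model.P0, p0)
                    assert np.allclose(model.M, m)
        rng = np.random.default_rng(3)
        for _ in range(300):  # length-4 pairs, randomized subset
            s1, s2 = rng.integers(0, 3, (2, 4))
            model = fit_mcmlink(s1, s2)
            p0, m = counting_oracle(list(s1), list(s2))
            assert np.allclose(model.P0, p0) and np.allclose(model.M, m)

    @given(state_vectors, state_vectors)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_conservation(self, s1, s2):
        """P0 sums to 1; every TPM row sums to 1 or is all zero."""
        n = min(len(s1), len(s2))
        model = fit_mcmlink(s1[:n], s2[:n])
        assert abs(model.P0.sum() - 1) < 1e-9
        rows = model.M.sum(axis=1)
        assert np.all((np.abs(rows - 1) < 1e-9) | (rows == 0))

    def test_laplace_smoothing_fills_unseen_rows(self):
        model = fit_mcmlink("DD", "DU", alpha=1.0)
        assert np.allclose(model.M[1], [1 / 3] * 3)    # unseen row uniform
        assert np.allclose(model.M[0], [2 / 5, 1 / 5, 2 / 5])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            fit_mcmlink("DD", "D")


class TestLikelihoodAndClassification:
    def test_joint_likelihood(self):
        model = fit_mcmlink("DDUU", "DNUU")
        assert link_likelihood(model, "DN") == pytest.approx(0.25)
        assert link_likelihood(model, "ND") == 0.0     # unseen source
        det = fit_mcmlink("DD", "DD")
        assert link_likelihood(det, "DD") == 1.0

    def test_classify_by_larger_likelihood(self):
        m1 = fit_mcmlink("DDUU", "DNUU")
        m2 = fit_mcmlink("NNNN", "NNNN")
        assert classify_sample(m1, m2, "DN") == "class1"
        assert classify_sample(m1, m2, "NN") == "class2"
        assert classify_sample(m1, m2, "UD") == "tie"  # 0 vs 0
        assert classify_sample(m1, m1, "DN") == "tie"  # identical models


class TestLoocv:
    def test_perfectly_separated_link(self, separable_states):
        a, d = loocv_link_score(separable_states.states[0],
                                separable_states.states[1],
                                separable_states.labels)
        assert d == 1.0 and a.all()

    def test_identical_classes_are_all_ties(self):
        s = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        labels = ["a", "a", "a", "b", "b", "b"]
        _, d = loocv_link_score(s, s, labels)
        assert d == 0.0

    def test_class_needs_two_samples(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            loocv_link_score([0, 1, 2], [0, 1, 2], ["a", "b", "b"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_batch_matches_reference(self, seed):
        """Vectorized count-identity route equals the literal per-sample
        fit-and-classify route, including unbalanced classes."""
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 3, size=(6, 17)).astype(np.int8)
        labels = np.array(["a"] * 7 + ["b"] * 10, dtype=object)
        links = np.array([[0, 1], [2, 3], [4, 5], [1, 4]])
        a_batch, d_batch = loocv_scores(states, links, labels == "a")
        for j, (r0, r1) in enumerate(links):
            a_ref, d_ref = loocv_link_score(states[r0], states[r1], labels)
            assert np.array_equal(a_ref, a_batch[:, j])
            assert d_ref == pytest.approx(d_batch[j])

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        s1, s2 = rng.integers(0, 3, (2, 20)).astype(np.int8)
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        swapped = np.where(labels == "a", "b", "a").astype(object)
        _, d1 = loocv_link_score(s1, s2, labels)
        _, d2 = loocv_link_score(s1, s2, swapped)
        assert d1 == d2

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        s1, s2 = rng.integers(0, 3, (2, 14)).astype(np.int8)
        labels = np.array(["a", "b"] * 7, dtype=object)
        perm = rng.permutation(14)
        _, d = loocv_link_score(s1, s2, labels)
        _, d_perm = loocv_link_score(s1[perm], s2[perm], labels[perm])
        assert d == d_perm

    def test_null_accuracy_near_half(self):
        """Under exchangeable labels E[d] stays near 1/2; the LOOCV
        training sets are unequal (n-1 vs n), which lends a small
        positive bias at these sample sizes."""
        rng = np.random.default_rng(11)
        labels_mask = np.array([True] * 30 + [False] * 30)
        ds = []
        for _ in range(300):
            states = rng.integers(0, 3, size=(2, 60)).astype(np.int8)
            _, d = loocv_scores(states, np.array([[0, 1]]),
                                rng.permutation(labels_mask))
            ds.append(d[0])
        assert 0.40 < np.mean(ds) < 0.60


class TestPermutationPvalue:
    def test_separable_link_has_zero_pvalue(self, separable_states):
        p = link_permutation_pvalue(separable_states.states[0],
                                    separable_states.states[1],
                                    separable_states.labels, B=100, rng=0)
        assert p == 0.0

    def test_smoothed_estimator_is_positive(self, separable_states):
        p = link_permutation_pvalue(separable_states.states[0],
                                    separable_states.states[1],
                                    separable_states.labels, B=100, rng=0,
                                    smoothed=True)
        assert p == pytest.approx(1 / 101)

    def test_null_pvalues_roughly_uniform(self):
        """On data whose labels carry no signal, link p-values are
        approximately uniform (Kolmogorov-Smirnov on 200 nulls)."""
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(200):
            states = rng.integers(0, 3, size=(2, 24)).astype(np.int8)
            labels = np.array(["a"] * 12 + ["b"] * 12, dtype=object)
            pvals.append(link_permutation_pvalue(states[0], states[1],
                                                 labels, B=49, rng=rng))
        assert kstest(pvals, "uniform").pvalue > 1e-3
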