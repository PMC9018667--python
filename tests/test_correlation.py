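"""Residue clustering, mutual information, AMI matrix and mu."""

import math
from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscorval.correlation import (
    ClusteringVector,
    CorrelationError,
    CorrelationMatrix,
    adjusted_mutual_information,
    analyze,
    cluster_entities,
    correlation_matrix,
    key_residue_and_clustering,
    mutual_information,
    residue_features,
    structural_correlation,
)
from mscorval.synthetic import sample_ensemble

# frozen oracle: direct Fraction-based evaluation of the plug-in mutual
# information of (0,0,1,1) vs (0,1,1,1)
MI_EXAMPLE = 0.3112781244591328


def brute_force_mi(x, y):
    """Direct summation over the joint histogram, in bits."""
    n = len(x)
    cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
    total = 0.0
    for (a, b), c in cxy.items():
        pxy = c / n
        total += pxy * math.log2(pxy / (cx[a] / n * cy[b] / n))
    return total


class TestMutualInformation:
    def test_identical_balanced_binary(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_independent_clusterings(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-15)

    def test_frozen_example(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(MI_EXAMPLE, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(CorrelationError):
            mutual_information([0, 1], [0, 1, 0])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 100))
            x = rng.integers(0, rng.integers(2, 5), size=n)
            y = rng.integers(0, rng.integers(2, 5), size=n)
            assert mutual_information(x, y) == pytest.approx(brute_force_mi(x.tolist(), y.tolist()), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=20)
        y = rng.integers(0, 3, size=20)
        mi = mutual_information(x, y)
        assert mi >= -1e-12
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)


class TestAdjustedMutualInformation:
    def test_identical_nontrivial_is_one(self):
        assert adjusted_mutual_information([0, 1, 0, 1, 2], [0, 1, 0, 1, 2]) == pytest.approx(1.0)

    def test_single_label_convention_is_zero(self):
        assert adjusted_mutual_information([0, 0, 0, 0], [0, 1, 0, 1]) == 0.0
        assert adjusted_mutual_information([0, 1, 0, 1], [2, 2, 2, 2]) == 0.0

    def test_relabeling_invariance(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [2, 2, 0, 0, 1, 1]
        assert adjusted_mutual_information(a, b) == pytest.approx(1.0)

    def test_null_mean_near_zero(self, rng):
        x = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        vals = [adjusted_mutual_information(x, rng.permutation(x)) for _ in range(300)]
        assert abs(np.mean(vals)) < 0.03


def _best_two_partition_loglik(rows):
    """Exhaustive oracle: the 2-partition of the rows maximizing the diagonal
    Gaussian likelihood (variance floored), compared up to label swap."""
    n = len(rows)
    best, best_ll = None, -np.inf
    for labels in product([0, 1], repeat=n - 1):
        lab = np.array((0,) + labels)
        if len(set(lab)) < 2:
            continue
        ll = 0.0
        for k in (0, 1):
            grp = rows[lab == k]
            var = grp.var(axis=0) + 1e-4
            ll += -0.5 * np.sum(np.log(2 * np.pi * var) * len(grp) + ((grp - grp.mean(0)) ** 2 / var).sum(0))
        if ll > best_ll:
            best_ll, best = ll, lab
    return best


class TestClusterEntities:
    def test_well_separated_1d_groups(self):
        feats = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.0]])
        cv = cluster_entities(feats, 2, seed=0)
        assert len(set(cv.labels[:3])) == 1 and len(set(cv.labels[3:])) == 1
        assert cv.labels[0] != cv.labels[3]

    def test_identical_rows_collapse_to_one_cluster(self):
        feats = np.ones((6, 3))
        cv = cluster_entities(feats, 2, seed=0)
        assert adjusted_mutual_information(cv, ClusteringVector([0, 1] * 3)) == 0.0

    def test_empty_features_flagged_uninformative(self):
        cv = cluster_entities(np.empty((5, 0)), 2, seed=0)
        assert cv.degenerate and not cv.informative

    def test_fewer_rows_than_clusters(self):
        with pytest.raises(CorrelationError):
            cluster_entities(np.ones((1, 2)), 2, seed=0)

    def test_two_gaussians_recovered_and_match_exhaustive_oracle(self, rng):
        centers = np.array([0.0, 8.0])  # 8 sigma apart at unit sigma
        truth = np.repeat([0, 1], 20)
        rows = rng.normal(size=(40, 3)) + centers[truth][:, None]
        cv = cluster_entities(rows, 2, seed=0)
        agreement = max(np.mean(cv.labels == truth), np.mean(cv.labels != truth))
        assert agreement >= 0.97
        sub = rows[::4][:10]
        oracle = _best_two_partition_loglik(sub)
        got = cluster_entities(sub, 2, seed=0).labels
        assert np.mean(got == oracle) in (0.0, 1.0)  # equal up to global label swap


class TestResidueFeatures:
    def test_zero_threshold_keeps_all_columns(self, two_state_ensemble):
        feats = residue_features(two_state_ensemble, 0, threshold=0.0)
        assert feats.shape == (40, two_state_ensemble.sequence_length - 1)

    def test_rigid_ensemble_filters_everything(self, rng):
        from mscorval.synthetic import SyntheticModel, _compact_chain

        base = _compact_chain(12, rng)
        model = SyntheticModel(base, np.zeros((2, 12, 3)), np.array([0.5, 0.5]), 0.0, np.arange(0))
        ens = sample_ensemble(model, 5, seed=0)
        feats = residue_features(ens, 3, threshold=0.5)
        assert feats.shape[1] == 0

    def test_filter_matches_brute_force_std(self, two_state_ensemble):
        r = 4
        all_feats = residue_features(two_state_ensemble, r, threshold=0.0)
        kept = residue_features(two_state_ensemble, r, threshold=0.5)
        manual = all_feats[:, all_feats.std(axis=0) >= 0.5]
        np.testing.assert_array_equal(kept, manual)

    def test_out_of_range_residue(self, two_state_ensemble):
        with pytest.raises(CorrelationError):
            residue_features(two_state_ensemble, 99)


class TestCorrelationMatrixAndMu:
    def test_one_state_request_rejected(self, two_state_ensemble):
        with pytest.raises(CorrelationError, match="at least two states"):
            correlation_matrix(two_state_ensemble, 1)

    def test_rigid_ensemble_gives_zero_matrix(self, rng):
        from mscorval.synthetic import SyntheticModel, _compact_chain

        base = _compact_chain(10, rng)
        model = SyntheticModel(base, np.zeros((2, 10, 3)), np.array([0.5, 0.5]), 0.0, np.arange(0))
        ens = sample_ensemble(model, 4, seed=0)
        mat = correlation_matrix(ens, 2, threshold=0.5, seed=0)
        assert np.all(mat.A == 0)
        assert structural_correlation(mat) == 0.0

    def test_matrix_exactly_symmetric(self, two_state_ensemble):
        mat = correlation_matrix(two_state_ensemble, 2, seed=3)
        np.testing.assert_array_equal(mat.A, mat.A.T)
        assert np.all(mat.A <= 1 + 1e-12)

    def test_diagonal_convention_two_residues(self):
        mat = CorrelationMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), 2, 0.5)
        assert structural_correlation(mat, include_diagonal=True) == pytest.approx(0.5)
        assert structural_correlation(mat, include_diagonal=False) == pytest.approx(0.0)

    def test_uniform_matrix_mu_is_one_either_way(self):
        mat = CorrelationMatrix(np.ones((4, 4)), 2, 0.5)
        assert structural_correlation(mat, include_diagonal=True) == pytest.approx(1.0)
        assert structural_correlation(mat, include_diagonal=False) == pytest.approx(1.0)

    def test_negative_mean_clamped(self):
        A = np.full((3, 3), -0.02)
        np.fill_diagonal(A, 1.0)
        mat = CorrelationMatrix(A, 2, 0.5)
        assert structural_correlation(mat) == 0.0
        assert structural_correlation(mat, clamp=False) == pytest.approx(-0.02)

    def test_mu_invariant_under_entity_reordering(self, two_state_model):
        ens = sample_ensemble(two_state_model, 10, seed=4)
        from mscorval.ensemble import Ensemble

        reordered = Ensemble(list(reversed(ens.conformers)))
        mu_a = analyze(ens, 2, seed=9).mu
        mu_b = analyze(reordered, 2, seed=9).mu
        # clustering seeds are positional, so allow small stochastic jitter
        assert mu_a == pytest.approx(mu_b, abs=0.1)


class TestKeyResidue:
    def _clusterings(self, L, n=6):
        return [ClusteringVector(np.tile([0, 1], n // 2), residue_index=i) for i in range(L)]

    def test_dominant_row_wins(self):
        A = np.eye(3)
        A[1, 0] = A[0, 1] = 0.9
        A[1, 2] = A[2, 1] = 0.9
        mat = CorrelationMatrix(A, 2, 0.5)
        idx, cv = key_residue_and_clustering(mat, self._clusterings(3))
        assert idx == 1 and cv.residue_index == 1

    def test_tie_breaks_to_lowest_index(self):
        A = np.ones((3, 3))
        mat = CorrelationMatrix(A, 2, 0.5)
        idx, _ = key_residue_and_clustering(mat, self._clusterings(3))
        assert idx == 0

    def test_all_zero_matrix_warns(self):
        mat = CorrelationMatrix(np.zeros((3, 3)), 2, 0.5)
        with pytest.warns(UserWarning):
            idx, _ = key_residue_and_clustering(mat, self._clusterings(3))
        assert idx == 0

    def test_global_clustering_recovers_states(self, two_state_model):
        ens = sample_ensemble(two_state_model, 20, seed=6)
        res = analyze(ens, 2, seed=8)
        truth = np.tile([0, 1], 20)
        lab = res.global_clustering.labels
        agreement = max(np.mean(lab == truth), np.mean(lab != truth))
        assert agreement >= 0.95
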