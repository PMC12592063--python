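"""Standardization, silhouette k-selection, phase clustering, profiling."""
from __future__ import annotations

import numpy as np
import pytest

from themetrace import clustering as tc
from themetrace.fusion import DocumentVector

from conftest import make_topic_model


def dvs(points, prefix="d"):
    return [DocumentVector(f"{prefix}{i}", np.asarray(p, dtype=float), ())
            for i, p in enumerate(points)]


class TestStandardize:
    def test_population_sd_convention(self):
        Z, mean, sd = tc.standardize(dvs([[1.0], [3.0]]))
        assert np.allclose(Z.ravel(), [-1.0, 1.0])  # sd = 1 under divide-by-n
        assert mean[0] == pytest.approx(2.0) and sd[0] == pytest.approx(1.0)

    def test_constant_dimension_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, _, sd = tc.standardize(dvs([[2.0, 1.0], [2.0, 3.0], [2.0, 5.0]]))
        assert np.allclose(Z[:, 0], 0.0)
        assert sd[0] == 0.0

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        Z1, _, _ = tc.standardize(X)
        Z2, _, _ = tc.standardize(Z1)
        assert np.allclose(Z1, Z2, atol=1e-9)

    def test_too_few_vectors(self):
        with pytest.raises(ValueError):
            tc.standardize(dvs([[1.0]]))


class TestSelectK:
    def test_two_well_separated_pairs(self):
        Z, _, _ = tc.standardize(np.array([[0, 0], [0.01, 0], [5, 5], [5, 5.01]]))
        k, scores = tc.select_k(Z, k_range=range(2, 4), seed=0)
        assert k == 2

    def test_k_at_least_n_skipped(self):
        Z, _, _ = tc.standardize(np.array([[0, 0], [1, 1], [2, 0], [0, 2]], dtype=float))
        with pytest.warns(UserWarning, match="only 4 points"):
            k, scores = tc.select_k(Z, k_range=range(2, 8), seed=0)
        assert set(scores) <= {2, 3}

    def test_blob_recovery_single_seed(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], dtype=float)
        X = np.vstack([rng.normal(c, 0.05, size=(15, 2)) for c in centers])
        Z, _, _ = tc.standardize(X)
        k, _ = tc.select_k(Z, seed=1)
        assert k == 4


class TestClusterPhase:
    def test_coincident_groups(self):
        vectors = dvs([[0, 0]] * 3 + [[9, 9]] * 3)
        pc = tc.cluster_phase(vectors, k=2, seed=0, phase="p")
        groups = {}
        for d, c in pc.assignments.items():
            groups.setdefault(c, set()).add(d)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"d0", "d1", "d2"}), frozenset({"d3", "d4", "d5"})}

    def test_permutation_invariance_as_partition(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        vectors = dvs(pts)
        perm = [vectors[i] for i in rng.permutation(len(vectors))]
        p1 = tc.cluster_phase(vectors, 2, seed=7)
        p2 = tc.cluster_phase(perm, 2, seed=7)

        def partition(pc):
            groups: dict[int, set] = {}
            for d, c in pc.assignments.items():
                groups.setdefault(c, set()).add(d)
            return {frozenset(g) for g in groups.values()}

        assert partition(p1) == partition(p2)

    def test_centroids_raw_are_member_means(self):
        vectors = dvs([[0, 0], [2, 0], [10, 10], [12, 10]])
        pc = tc.cluster_phase(vectors, 2, seed=0)
        for c in range(2):
            members = pc.members(c)
            assert np.allclose(pc.centroids_raw[c],
                               np.mean([vectors[i].vector for i in members], axis=0))

    def test_small_phase_single_cluster(self):
        vectors = dvs([[0, 0], [1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="single cluster"):
            pc = tc.cluster_phase_auto(vectors, phase="tiny", seed=0)
        assert pc.k == 1
        assert set(pc.assignments.values()) == {0}


def _profiled_fixture():
    """Two clusters; member thetas chosen for exact hand computation."""
    theta = np.array([
        [1.0, 0.0],   # d0 cluster 0
        [0.0, 1.0],   # d1 cluster 0
        [0.2, 0.8],   # d2 cluster 1 (singleton)
    ])
    phi = np.array([
        [0.9, 0.1, 0.0],
        [0.0, 0.1, 0.9],
    ])
    model = make_topic_model(phi, theta, ["alpha", "mid", "omega"],
                             doc_ids=["d0", "d1", "d2"])
    vectors = dvs([[0.0, 0.0], [0.2, 0.0], [10.0, 10.0]])
    pc = tc.PhaseClustering(
        phase="p", k=2, doc_ids=("d0", "d1", "d2"),
        labels=np.array([0, 0, 1]),
        centroids_std=np.array([[0.0, 0.0], [10.0, 10.0]]),
        centroids_raw=np.array([[0.1, 0.0], [10.0, 10.0]]),
        silhouette_by_k={}, seed=0,
        std_matrix=np.array([[0.0, 0.0], [0.2, 0.0], [10.0, 10.0]]),
        raw_matrix=np.array([v.vector for v in vectors]),
    )
    return pc, model


class TestProfileCluster:
    def test_singleton_cluster(self):
        pc, model = _profiled_fixture()
        prof = tc.profile_cluster(pc, 1, model)
        assert prof.representative_doc == "d2"
        assert np.allclose(prof.mean_topic_weights, [0.2, 0.8])
        assert prof.dominant_topic == (1, pytest.approx(0.8))

    def test_tie_breaks_to_lowest_topic(self):
        pc, model = _profiled_fixture()
        prof = tc.profile_cluster(pc, 0, model)
        assert np.allclose(prof.mean_topic_weights, [0.5, 0.5])
        assert prof.dominant_topic == (0, pytest.approx(0.5))

    def test_representative_minimizes_distance(self):
        pc, model = _profiled_fixture()
        prof = tc.profile_cluster(pc, 0, model)
        assert prof.representative_doc == "d0"  # distance 0 vs 0.2
        # oracle: exhaustive scan
        members = pc.members(0)
        dists = {pc.doc_ids[i]: np.linalg.norm(pc.std_matrix[i] - pc.centroids_std[0])
                 for i in members}
        assert dists[prof.representative_doc] == min(dists.values())

    def test_keyword_aggregation(self):
        """Members one-hot on a topic whose phi concentrates on one word make
        that word the first keyword."""
        pc, model = _profiled_fixture()
        prof = tc.profile_cluster(pc, 1, model)
        # word dist = 0.2*phi0 + 0.8*phi1 = [0.18, 0.10, 0.72] -> omega first
        assert prof.keywords[0][0] == "omega"
        assert prof.keywords[0][1] == pytest.approx(0.72)

    def test_bad_cluster_id(self):
        pc, model = _profiled_fixture()
        with pytest.raises(IndexError):
            tc.profile_cluster(pc, 5, model)


class TestClusterTopicMatrix:
    def test_rows_sum_to_one(self):
        pc, model = _profiled_fixture()
        profiles = tc.profile_phase(pc, model)
        M = tc.cluster_topic_matrix(profiles)
        assert M.shape == (2, 2)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-6)

    def test_single_one_hot_cluster(self):
        theta = np.array([[1.0, 0.0]])
        phi = np.ones((2, 3)) / 3
        model = make_topic_model(phi, theta, ["a", "b", "c"], doc_ids=["d0"])
        pc = tc.PhaseClustering(
            phase="p", k=1, doc_ids=("d0",), labels=np.array([0]),
            centroids_std=np.zeros((1, 2)), centroids_raw=np.zeros((1, 2)),
            silhouette_by_k={}, seed=0,
            std_matrix=np.zeros((1, 2)), raw_matrix=np.zeros((1, 2)),
        )
        M = tc.cluster_topic_matrix(tc.profile_phase(pc, model))
        assert np.allclose(M, [[1.0, 0.0]])
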