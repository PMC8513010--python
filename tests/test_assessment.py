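"""Overall scoring, node-feature splitting, standard models, fine-grained report."""

import numpy as np
import pytest

from ttstroke.assessment import (
    AssessmentReport,
    UndefinedSimilarityError,
    assess,
    build_standard_model,
    cluster_purity,
    cosine_similarity,
    embed_3d,
    match_clusters,
    overall_score,
    split_node_features,
)
from ttstroke.datamodel import StructuralError


class TestOverallScore:
    def test_uniform_distribution_ties_to_first_class(self):
        s = overall_score(np.full(5, 0.2))
        assert (s.predicted_class, s.score) == (0, pytest.approx(0.2))

    def test_peaked_distribution_selects_its_mode(self):
        s = overall_score(np.array([0.05, 0.1, 0.7, 0.1, 0.05]))
        assert (s.predicted_class, s.score) == (2, pytest.approx(0.7))

    def test_one_hot_scores_unity(self):
        s = overall_score(np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
        assert (s.predicted_class, s.score) == (2, 1.0)

    def test_non_normalized_input_rejected(self):
        with pytest.raises(ValueError):
            overall_score(np.array([0.5, 0.6]))


class TestNodeFeatureSplit:
    def test_45_columns_split_into_five_324_vectors(self):
        m = np.arange(36 * 45.0).reshape(36, 45)
        feats = split_node_features(m, 5)
        assert [f.node_id for f in feats] == list(range(5))
        assert all(f.vector.shape == (324,) for f in feats)
        np.testing.assert_array_equal(feats[2].vector, m[:, 18:27].reshape(-1))

    def test_block_of_ones_isolates_one_node(self):
        m = np.zeros((36, 27))
        m[:, 9:18] = 1.0
        feats = split_node_features(m, 3)
        assert not feats[0].vector.any()
        assert feats[1].vector.all()
        assert not feats[2].vector.any()

    def test_single_node_is_the_whole_map(self):
        m = np.arange(36 * 9.0).reshape(36, 9)
        (f,) = split_node_features(m, 1)
        np.testing.assert_array_equal(f.vector, m.reshape(-1))

    def test_indivisible_columns_rejected(self):
        with pytest.raises(StructuralError):
            split_node_features(np.zeros((36, 10)), 4)


class TestCosineSimilarity:
    def test_identical_vectors_score_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_scale_invariance(self):
        v = np.array([1.0, -2.0, 0.5])
        assert cosine_similarity(v, 2 * v) == pytest.approx(1.0)
        assert cosine_similarity(3 * v, v) == pytest.approx(1.0)

    def test_two_zero_vectors_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity(np.zeros(3), np.zeros(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.zeros(4))


class TestEmbedding:
    def test_output_is_three_dimensional(self):
        rng = np.random.default_rng(0)
        coords = embed_3d(rng.normal(size=(30, 20)), seed=0)
        assert coords.shape == (30, 3)

    def test_duplicated_points_stay_close(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(15, 10))
        coords = embed_3d(np.vstack([base, base]), seed=0)
        paired = np.linalg.norm(coords[:15] - coords[15:], axis=1)
        spread = np.linalg.norm(coords - coords.mean(0), axis=1).mean()
        assert paired.mean() < spread

    def test_separated_blobs_remain_separated(self):
        rng = np.random.default_rng(2)
        blobs = np.concatenate(
            [rng.normal(20 * k, 0.5, size=(20, 8)) for k in range(3)]
        )
        ids = np.repeat(np.arange(3), 20)
        coords = embed_3d(blobs, seed=0)
        cents = np.stack([coords[ids == k].mean(0) for k in range(3)])
        within = np.mean(
            [np.linalg.norm(coords[ids == k] - cents[k], axis=1).mean() for k in range(3)]
        )
        between = min(
            np.linalg.norm(cents[a] - cents[b])
            for a in range(3) for b in range(a + 1, 3)
        )
        assert between > within

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            embed_3d(np.zeros((3, 5)), seed=0)


class TestClusterMatching:
    def test_maximum_agreement_assignment_on_known_table(self):
        # cluster 0 mostly node 2, cluster 1 mostly node 0, cluster 2 node 1
        clusters = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        nodes = np.array([2, 2, 0, 0, 0, 1, 1, 1, 1])
        mapping = match_clusters(clusters, nodes, 3)
        assert mapping == {0: 2, 1: 0, 2: 1}
        assert cluster_purity(clusters, nodes) == pytest.approx(7 / 9)


class TestStandardModel:
    def test_degenerate_node_blocks_recover_exact_centroids(self):
        # tight within node (jitter keeps the embedding non-degenerate:
        # exact duplicates have no local geometry for t-SNE), far apart
        # between nodes
        rng = np.random.default_rng(2)
        windows = rng.normal(0.0, 0.1, size=(12, 36, 27))
        for k in range(3):
            windows[:, :, 9 * k : 9 * (k + 1)] += 10.0 * (k + 1)
        std = build_standard_model(windows, None, d=3, class_id=0, seed=0)
        assert std.purity == 1.0
        assert sorted(std.centroids) == [0, 1, 2]
        for k in range(3):
            np.testing.assert_allclose(std.centroids[k], 10.0 * (k + 1), atol=0.15)
        assert sum(std.member_counts.values()) == 36

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        windows = rng.normal(size=(12, 36, 18))
        windows[:, :, 9:] += 30.0
        a = build_standard_model(windows, None, d=2, class_id=1, seed=5)
        b = build_standard_model(windows, None, d=2, class_id=1, seed=5)
        for k in a.centroids:
            np.testing.assert_array_equal(a.centroids[k], b.centroids[k])
        assert a.cluster_to_node == b.cluster_to_node

    def test_too_few_actions_rejected(self):
        with pytest.raises(ValueError):
            build_standard_model(np.zeros((5, 36, 18)), None, d=2, class_id=0, seed=0)


class _StubModel:
    """Duck-typed classifier: fixed prediction, raw window as abstract map."""

    def __init__(self, probs, scale=1.0):
        self._probs = np.asarray(probs, dtype=float)
        self._scale = scale

    def predict_proba(self, windows):
        return self._probs[None]

    def abstract_map(self, window):
        return self._scale * np.asarray(window)


def _stub_standard(centroid_map, d):
    """Standard model whose centroids are exactly the map's node blocks."""
    from ttstroke.assessment import StandardActionModel, split_node_features

    centroids = {f.node_id: f.vector for f in split_node_features(centroid_map, d)}
    return StandardActionModel(
        class_id=0, d=d, centroids=centroids,
        member_counts={k: 12 for k in range(d)},
        cluster_to_node={k: k for k in range(d)},
        purity=1.0,
    )


class TestAssess:
    def _map(self, d=3, seed=4):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(36, 9 * d)) + 5.0

    def test_target_equal_to_centroids_scores_unity_everywhere(self):
        m = self._map()
        model = _StubModel([1.0, 0.0, 0.0, 0.0, 0.0])
        std = {0: _stub_standard(m, 3)}
        report = assess(m, model, std)
        assert report.overall.predicted_class == 0
        for sim in report.node_similarity.values():
            assert sim == pytest.approx(1.0, abs=1e-9)

    def test_similarity_is_scale_invariant_in_target_features(self):
        m = self._map()
        std = {0: _stub_standard(m, 3)}
        a = assess(m, _StubModel([1, 0, 0, 0, 0], scale=1.0), std)
        b = assess(m, _StubModel([1, 0, 0, 0, 0], scale=7.0), std)
        for k in a.node_similarity:
            assert a.node_similarity[k] == pytest.approx(b.node_similarity[k])

    def test_two_nodes_flags_exactly_both(self):
        m = self._map(d=2)
        report = assess(m, _StubModel([0.6, 0.4, 0, 0, 0]), {0: _stub_standard(m, 2)})
        assert report.flagged_nodes == (0, 1)

    def test_nodes_below_threshold_also_flagged(self):
        m = self._map(d=4)
        target = m.copy()
        target[:, 9:18] *= -1.0  # node 1 anti-aligned
        target[:, 27:36] *= -1.0  # node 3 anti-aligned
        report = assess(target, _StubModel([1, 0, 0, 0, 0]),
                        {0: _stub_standard(m, 4)}, threshold=0.8)
        assert {1, 3} <= set(report.flagged_nodes)
        assert len(report.flagged_nodes) >= 2

    def test_missing_standard_model_names_the_class(self):
        m = self._map()
        with pytest.raises(KeyError, match="class 2"):
            assess(m, _StubModel([0, 0, 1, 0, 0]), {0: _stub_standard(m, 3)})

    def test_report_invariant_requires_two_flags(self):
        with pytest.raises(StructuralError):
            AssessmentReport(
                overall=overall_score(np.array([1.0, 0.0])),
                node_similarity={0: 0.9, 1: 0.8},
                flagged_nodes=(0,),
                threshold=0.8,
            )
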