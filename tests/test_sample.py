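"""Sample-level aggregation: voting, embeddings, pseudo-OTUs, k-mer tables."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import homogeneity_score

from phenoreads import sample

CLASSES3 = ["gut", "skin", "oral"]


class TestMajorityVote:
    def test_two_classes_above_chance_both_gain_a_vote(self):
        # a read scored (0.51, 0.43, 0.06): gut and skin beat 1/3, oral not
        tally = sample.majority_vote([[0.51, 0.43, 0.06]], CLASSES3)
        assert tally.votes.tolist() == [1, 1, 0]
        assert tally.threshold == pytest.approx(1 / 3)

    def test_two_class_threshold_is_half(self):
        tally = sample.majority_vote([[0.9, 0.1]], ["cd", "not_ibd"])
        assert tally.threshold == 0.5

    def test_unanimous_reads(self):
        scores = [[0.9, 0.1]] * 10
        tally = sample.majority_vote(scores, ["cd", "not_ibd"])
        assert tally.votes.tolist() == [10, 0]
        assert tally.predicted_label == "cd"

    def test_uniform_scores_fall_back_to_single_argmax_vote(self):
        tally = sample.majority_vote([[1 / 3, 1 / 3, 1 / 3]], CLASSES3)
        assert tally.votes.sum() == 1
        # tie broken by class-name order: first listed class gets the vote
        assert tally.votes.tolist() == [1, 0, 0]

    def test_vote_conservation_bounds(self):
        # each read casts between 1 and N votes
        rng = np.random.default_rng(0)
        scores = rng.dirichlet(np.ones(3), size=200)
        tally = sample.majority_vote(scores, CLASSES3)
        assert 200 <= tally.votes.sum() <= 3 * 200

    def test_exactly_one_vote_when_one_class_above_chance(self):
        scores = [[0.70, 0.20, 0.10], [0.15, 0.60, 0.25]]
        tally = sample.majority_vote(scores, CLASSES3)
        assert tally.votes.sum() == 2

    def test_empty_read_list_rejected(self):
        with pytest.raises(ValueError, match="at least one read"):
            sample.majority_vote(np.empty((0, 3)), CLASSES3)


class TestAverageEmbedding:
    def test_mean_of_one_is_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(sample.average_embedding([v]), v)

    def test_arithmetic_mean_and_permutation_invariance(self):
        vecs = [np.array([0.0, 2.0]), np.array([2.0, 0.0])]
        np.testing.assert_array_equal(sample.average_embedding(vecs), [1.0, 1.0])
        np.testing.assert_array_equal(
            sample.average_embedding(vecs), sample.average_embedding(vecs[::-1]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sample.average_embedding([])


@pytest.fixture
def blobs():
    rng = np.random.default_rng(1)
    centres = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
    points = np.concatenate(
        [c + rng.normal(scale=0.5, size=(40, 2)) for c in centres])
    labels = np.repeat([0, 1, 2], 40)
    return points, labels


class TestPseudoOtu:
    def test_separated_blobs_are_recovered_perfectly(self, blobs):
        points, labels = blobs
        centroids = sample.pseudo_otu_fit(points, k=3, seed=0)
        assigned = sample.assign_clusters(points, centroids)
        assert homogeneity_score(labels, assigned) == pytest.approx(1.0)

    def test_k_one_gives_global_mean(self, blobs):
        points, _ = blobs
        centroids = sample.pseudo_otu_fit(points, k=1, seed=0)
        np.testing.assert_allclose(centroids[0], points.mean(axis=0), atol=1e-8)

    def test_same_seed_identical_centroids(self, blobs):
        points, _ = blobs
        a = sample.pseudo_otu_fit(points, k=3, seed=5)
        b = sample.pseudo_otu_fit(points, k=3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_fewer_points_than_k_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="lower k"):
            sample.pseudo_otu_fit(np.zeros((5, 2)), k=10)

    def test_assignment_matches_brute_force(self):
        rng = np.random.default_rng(2)
        emb = rng.standard_normal((100, 4))
        centroids = rng.standard_normal((10, 4))
        fast = sample.assign_clusters(emb, centroids)
        brute = np.array([
            int(np.argmin([np.sum((e - c) ** 2) for c in centroids]))
            for e in emb])
        np.testing.assert_array_equal(fast, brute)

    def test_table_counts_and_relative_abundance(self):
        centroids = np.array([[0.0], [10.0], [20.0]])
        table = sample.pseudo_otu_table(
            {"s1": np.array([[9.0], [11.0], [10.0], [9.5]]),
             "s2": np.array([[0.0], [20.0]])},
            centroids)
        assert table.counts.loc["s1"].tolist() == [0, 4, 0]
        assert table.relabund.loc["s1"].tolist() == [0.0, 1.0, 0.0]
        assert table.relabund.loc["s2"].sum() == pytest.approx(1.0)
        assert table.counts.shape[1] == 3

    def test_zero_read_sample_flagged(self):
        centroids = np.zeros((2, 1))
        table = sample.pseudo_otu_table(
            {"empty": np.empty((0, 1)), "ok": np.array([[0.1]])}, centroids)
        assert table.empty_samples == ["empty"]
        assert table.counts.loc["empty"].sum() == 0
        assert np.isnan(table.relabund.loc["empty"]).all()


class TestSampleClassifier:
    def test_separable_features_are_learned(self, blobs):
        points, labels = blobs
        clf = sample.fit_sample_classifier(points, labels.astype(str), seed=0)
        acc = (sample.predict_samples(clf, points) == labels.astype(str)).mean()
        assert acc >= 0.95

    def test_same_seed_identical_predictions(self, blobs):
        points, labels = blobs
        preds = [
            sample.predict_samples(
                sample.fit_sample_classifier(points, labels.astype(str), seed=3),
                points)
            for _ in range(2)]
        np.testing.assert_array_equal(*preds)

    def test_feature_dimension_mismatch_rejected(self, blobs):
        points, labels = blobs
        clf = sample.fit_sample_classifier(points, labels.astype(str), seed=0)
        with pytest.raises(ValueError, match="dimension"):
            sample.predict_samples(clf, np.zeros((2, 5)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            sample.fit_sample_classifier(np.zeros((4, 2)), ["a"] * 4)


class TestKmerTable:
    def test_overlapping_window_count(self):
        table = sample.kmer_table({"s": ["AAAA"]}, k=3)
        assert table.loc["s", "AAA"] == pytest.approx(1.0)
        assert table.loc["s"].sum() == pytest.approx(1.0)

    def test_window_count_identity(self):
        read = "ACGTACGTAC"  # length 10, k=4 -> 7 windows
        table = sample.kmer_table({"s": [read]}, k=4)
        # relative frequencies are counts / (L - k + 1)
        assert table.loc["s"].sum() == pytest.approx(1.0)
        assert table.loc["s", "ACGT"] == pytest.approx(2 / 7)

    def test_matches_brute_force_dictionary_counter(self):
        rng = np.random.default_rng(3)
        reads = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(100)]
        table = sample.kmer_table({"s": reads}, k=4)
        brute: dict[str, int] = {}
        for read in reads:
            for i in range(len(read) - 3):
                kmer = read[i: i + 4]
                brute[kmer] = brute.get(kmer, 0) + 1
        total = sum(brute.values())
        for kmer in ("".join(p) for p in itertools.product("ACGT", repeat=4)):
            assert table.loc["s", kmer] == pytest.approx(
                brute.get(kmer, 0) / total)

    def test_ambiguous_windows_skipped(self):
        table = sample.kmer_table({"s": ["AANAA"]}, k=2)
        # windows AN and NA skipped; AA counted twice
        assert table.loc["s", "AA"] == pytest.approx(1.0)

    def test_reads_shorter_than_k_flagged_zero_row(self):
        with pytest.warns(UserWarning, match="no countable"):
            table = sample.kmer_table({"s": ["ACG"]}, k=5)
        assert table.loc["s"].sum() == 0.0
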