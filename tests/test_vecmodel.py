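"""Embedding spaces, composite likelihoods and Bayes inversion."""

import itertools

import numpy as np
import pytest
from scipy.stats import binomtest

from kgrammar.seqio import Sentence
from kgrammar.vecmodel import (
    EmbeddingSpace,
    _posterior_from_logliks,
    centroid_similarity,
    classify_records,
    classify_sequence,
    nearest_kmers,
    ranklist_dissimilarity,
    sentence_loglik,
    train_embedding,
    vec_profile,
)


def _sentences(pairs, n=60):
    """Corpus of 2-token sentences from explicit co-occurrence pairs."""
    return [Sentence(tokens=p, offset=0) for p in pairs for _ in range(n)]


def test_requested_dimension_honoured():
    space = train_embedding(["ACGTACGTACGTACGT"], k=4, d=16, epochs=2, seed=0)
    assert space.dim == 16
    assert all(space.syn0[i].shape == (16,) for i in range(len(space)))


def test_training_deterministic_under_seed():
    corpus = ["ACGTTGCATTGACGTACGTAACGTAGCA", "TTGACCATGACGTTACGATGCAACGTAC"]
    a = train_embedding(corpus, k=4, d=8, epochs=3, seed=42)
    b = train_embedding(corpus, k=4, d=8, epochs=3, seed=42)
    assert np.array_equal(a.syn0, b.syn0)
    assert np.array_equal(a.syn1, b.syn1)


def test_co_occurring_tokens_closer_than_random():
    """Tokens sharing contexts end up closer in cosine than unrelated ones."""
    rng = np.random.default_rng(3)
    x, y, z, w = "AAAA", "CCCC", "GGGG", "ACAC"
    pairs = [(x, y), (y, x), (z, w), (w, z)]
    corpus = [Sentence(tokens=pairs[rng.integers(0, 4)], offset=0) for _ in range(400)]
    space = train_embedding(corpus, k=4, d=16, epochs=10, seed=1)

    def cos(a, b):
        va, vb = space.vector(a), space.vector(b)
        return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

    assert cos(x, y) > cos(x, z)
    assert cos(x, y) > cos(x, w)


def test_hierarchical_softmax_sums_to_one():
    """For any fixed context the HS probabilities over the whole
    vocabulary sum to 1."""
    corpus = ["ACGTTGCATGCAACGTTGCA", "TTGCAACGTACGTTGCAACG"]
    space = train_embedding(corpus, k=3, d=8, epochs=3, seed=2)
    for ctx in ([space.tokens[0]], [space.tokens[1], space.tokens[2]]):
        total = sum(np.exp(space.log_prob(t, ctx)) for t in space.tokens)
        assert total == pytest.approx(1.0, abs=1e-6)


def test_single_known_token_sentence_flagged_undefined():
    space = train_embedding(["ACGTTGCAACGTGGCA"], k=4, d=8, epochs=2, seed=0)
    assert np.isnan(sentence_loglik(space, [space.tokens[0]]))
    # unknown tokens are dropped before scoring
    assert np.isnan(sentence_loglik(space, [space.tokens[0], "NNNN"]))


def test_repeated_sentence_scores_identically():
    space = train_embedding(["ACGTTGCAACGTGGCAACGT"], k=4, d=8, epochs=2, seed=0)
    sent = Sentence(tokens=(space.tokens[0], space.tokens[1]), offset=0)
    scores = space.sentence_logliks([sent, sent])
    assert scores[0] == scores[1]


def test_posterior_symmetry_and_monotonicity():
    even = _posterior_from_logliks(-10.0, -10.0)
    assert even.p_regulatory == pytest.approx(0.5)
    probs = [
        _posterior_from_logliks(-10.0 + d, -10.0).p_regulatory
        for d in np.linspace(-2, 2, 9)
    ]
    assert np.all(np.diff(probs) > 0)


def test_posterior_matches_naive_bayes_arithmetic():
    """Log-space computation equals the direct Bayes ratio when safe."""
    l_reg, l_rand = -3.0, -4.0
    direct = 0.5 * np.exp(l_reg) / (0.5 * np.exp(l_reg) + 0.5 * np.exp(l_rand))
    assert _posterior_from_logliks(l_reg, l_rand).p_regulatory == pytest.approx(
        direct, abs=1e-12
    )


def test_classify_rejects_short_sequence(embedding_spaces):
    with pytest.raises(Exception):
        classify_sequence(embedding_spaces, "ACGTACGTACGTACG")  # < 2k


def test_classification_beats_chance_significantly(embedding_spaces, study):
    """Binomial test against 0.5 on a 200-sequence balanced holdout."""
    records = study["holdout_reg"] + study["holdout_ctrl"]
    truth = np.array([1] * 100 + [0] * 100)
    probs = classify_records(embedding_spaces, records)
    correct = int(((probs >= 0.5).astype(int) == truth).sum())
    assert binomtest(correct, 200, 0.5, alternative="greater").pvalue < 1e-6


def test_vec_profile_bounded_and_peaked_on_motif_cluster(
    embedding_spaces, motif_set
):
    """The probability track rises over a planted motif cluster."""
    rng = np.random.default_rng(6)
    flank = "".join(rng.choice(list("ACGT"), size=120))
    cluster = "".join(
        motif_set.sample_instance(i % 2, rng) for i in range(4)
    )
    seq = flank + cluster + "".join(rng.choice(list("ACGT"), size=120))
    track = vec_profile(embedding_spaces, seq, group=3)
    valid = ~np.isnan(track)
    assert np.all((track[valid] >= 0) & (track[valid] <= 1))
    inside = track[130: 120 + len(cluster)]
    outside = np.concatenate([track[:90], track[-90:]])
    assert np.nanmean(inside) > np.nanmean(outside)


def test_nearest_kmers_excludes_query_and_breaks_ties():
    vectors = np.array(
        [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.70710678, 0.70710678]]
    )
    space = EmbeddingSpace(
        tokens=["AAAA", "CCCC", "GGGG", "TTTT"][:4],
        counts=np.array([4, 3, 2, 1]),
        syn0=vectors,
        syn1=np.zeros((3, 2)),
        k=4, window=5, epochs=0, seed=0,
    )
    result = nearest_kmers(space, "AAAA", topN=3)
    assert [t for t, _ in result] == ["CCCC", "TTTT", "GGGG"]
    assert result[0][1] == pytest.approx(1.0)
    assert len(nearest_kmers(space, "AAAA", topN=10)) == 3
    with pytest.raises(KeyError):
        nearest_kmers(space, "ACGT")


def test_centroid_similarity_limits():
    vectors = np.array([[1.0, 0.0], [0.0, 1.0]])
    space = EmbeddingSpace(
        tokens=["AAAA", "CCCC"], counts=np.array([2, 1]),
        syn0=vectors, syn1=np.zeros((1, 2)),
        k=4, window=5, epochs=0, seed=0,
    )
    assert centroid_similarity(space, ["AAAA"], np.array([1.0, 0.0])) == (
        pytest.approx(0.0)
    )
    assert centroid_similarity(space, ["AAAA"], np.array([0.0, 1.0])) == (
        pytest.approx(1.0)
    )
    with pytest.raises(ValueError):
        centroid_similarity(space, ["GGGG"], np.array([1.0, 0.0]))


def test_ranklist_dissimilarity_set_arithmetic():
    assert ranklist_dissimilarity(list("ABCD"), list("ABCD"), topN=4) == 0.0
    assert ranklist_dissimilarity(list("ABCD"), list("EFGH"), topN=4) == 1.0
    # overlap 2, union 6 -> 1 - 2/6
    assert ranklist_dissimilarity(list("ABCD"), list("CDEF"), topN=4) == (
        pytest.approx(2 / 3)
    )
    with pytest.raises(ValueError):
        ranklist_dissimilarity([], list("ABC"), topN=3)


def test_planted_spaces_more_differentiated_than_background_split(
    embedding_spaces, study
):
    """Top-5 neighbour lists differ between V_regulatory and V_random for
    more tokens than between two halves of the same background corpus."""
    ctrl = [r for r in study["train"] if r.region.label == "control"]
    half_a = train_embedding(ctrl[:250], k=8, d=32, epochs=3, seed=1)
    half_b = train_embedding(ctrl[250:500], k=8, d=32, epochs=3, seed=1)

    def mean_dissimilarity(s1, s2, n_tokens=100):
        shared = [t for t in s1.tokens if t in s2][:n_tokens]
        return np.mean([
            ranklist_dissimilarity(
                [x for x, _ in nearest_kmers(s1, t, topN=5)],
                [x for x, _ in nearest_kmers(s2, t, topN=5)],
                topN=5,
            )
            for t in shared
        ])

    planted = mean_dissimilarity(
        embedding_spaces["regulatory"], embedding_spaces["random"]
    )
    null = mean_dissimilarity(half_a, half_b)
    # the null split uses half-sized corpora (noisier neighbourhoods), yet
    # the planted contrast still dominates
    assert planted > null


def test_space_save_load_and_text_export(tmp_path, embedding_spaces):
    space = embedding_spaces["regulatory"]
    path = tmp_path / "space.npz"
    space.save(path)
    back = EmbeddingSpace.load(path)
    assert np.array_equal(space.syn0, back.syn0)
    sent = Sentence(tokens=tuple(space.tokens[:5]), offset=0)
    assert space.sentence_logliks([sent])[0] == back.sentence_logliks([sent])[0]

    txt = tmp_path / "vectors.txt"
    space.export_word_vectors(txt)
    header = txt.read_text().splitlines()[0].split()
    assert header == [str(len(space)), str(space.dim)]
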