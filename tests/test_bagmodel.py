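"""TF*IDF transform and the bag-of-k-mers classifier."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from kgrammar.bagmodel import (
    BagModel,
    VocabularyIndex,
    bag_profile,
    build_vocabulary,
    fit_bag_classifier,
    tfidf_transform,
)
from kgrammar.complexity import filter_vocabulary
from kgrammar.fixtures import simulate_dataset, split_by_label
from kgrammar.seqio import GenomicRegion, SequenceRecord, tokenize_bag

# abstract 1-char "tokens" exercise the transform independent of DNA
TOY_CORPUS = [["A", "A", "B"], ["B", "C"]]
TOY_VOCAB = VocabularyIndex(["A", "B", "C"], k=1)


def test_tfidf_raw_matches_printed_formula():
    """weights(s, t) = f(t) * ln((1+|S|)/(df+1)); A occurs twice in s1,
    df(A)=1, |S|=2 -> 2*ln(3/2)."""
    X, df, n_docs = tfidf_transform(TOY_CORPUS, TOY_VOCAB, convention="raw")
    assert X[0, TOY_VOCAB.index["A"]] == pytest.approx(2 * math.log(1.5), abs=1e-9)
    assert n_docs == 2


def test_tfidf_raw_saturated_token_weight_zero():
    X, _, _ = tfidf_transform(TOY_CORPUS, TOY_VOCAB, convention="raw")
    # B occurs in every sequence: idf = ln(3/3) = 0
    assert X[0, TOY_VOCAB.index["B"]] == pytest.approx(0.0, abs=1e-12)
    assert X[1, TOY_VOCAB.index["B"]] == pytest.approx(0.0, abs=1e-12)


def test_tfidf_sklearn_convention_rows_unit_norm():
    X, _, _ = tfidf_transform(TOY_CORPUS, TOY_VOCAB, convention="sklearn")
    norms = sp.linalg.norm(X, axis=1)
    assert np.allclose(norms, 1.0)
    empty, _, _ = tfidf_transform([["A"], []], TOY_VOCAB, convention="sklearn")
    assert sp.linalg.norm(empty, axis=1)[1] == 0.0


def _brute_force_tfidf(token_lists, vocab, convention):
    n = len(token_lists)
    out = np.zeros((n, len(vocab)))
    for j, tok in enumerate(vocab.tokens):
        df = sum(1 for toks in token_lists if tok in toks)
        idf = math.log((1 + n) / (df + 1)) + (1.0 if convention == "sklearn" else 0.0)
        for i, toks in enumerate(token_lists):
            out[i, j] = toks.count(tok) * idf
    if convention == "sklearn":
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        out = out / norms
    return out


@pytest.mark.parametrize("convention", ["raw", "sklearn"])
def test_tfidf_matches_brute_force_oracle(convention):
    rng = np.random.default_rng(8)
    alphabet = list("ABCDEFG")
    corpora = [
        [list(rng.choice(alphabet, size=int(rng.integers(1, 12))))
         for _ in range(int(rng.integers(2, 9)))]
        for _ in range(5)
    ]
    for token_lists in corpora:
        vocab = VocabularyIndex(alphabet, k=1)
        X, _, _ = tfidf_transform(token_lists, vocab, convention=convention)
        expected = _brute_force_tfidf(token_lists, vocab, convention)
        assert np.allclose(X.toarray(), expected, atol=1e-9)


def test_tfidf_sklearn_convention_matches_library_transformer():
    """Dual route: in-package transform equals sklearn's TfidfTransformer."""
    from sklearn.feature_extraction.text import TfidfTransformer

    rng = np.random.default_rng(15)
    counts = rng.integers(0, 5, size=(10, 6)).astype(float)
    token_lists = [
        [tok for j, tok in enumerate("ABCDEF") for _ in range(int(row[j]))]
        for row in counts
    ]
    vocab = VocabularyIndex(list("ABCDEF"), k=1)
    X, _, _ = tfidf_transform(token_lists, vocab, convention="sklearn")
    ref = TfidfTransformer(smooth_idf=True, norm="l2").fit_transform(counts)
    assert np.allclose(X.toarray(), ref.toarray(), atol=1e-9)


def test_frozen_df_reproduces_fit_transform():
    X_fit, df, n_docs = tfidf_transform(TOY_CORPUS, TOY_VOCAB)
    X_frozen, _, _ = tfidf_transform(
        TOY_CORPUS, TOY_VOCAB, frozen_df=df, frozen_n_docs=n_docs
    )
    assert np.allclose(X_fit.toarray(), X_frozen.toarray())


def _record(seq, label, name="r"):
    region = GenomicRegion(name, 0, len(seq), ".", label)
    return SequenceRecord(region=region, seq=seq)


def test_separable_token_gets_positive_coefficient():
    rng = np.random.default_rng(12)
    marker = "AAATTTGG"
    recs, labels = [], []
    for i in range(30):
        bg = "".join(rng.choice(list("ACGT"), size=40))
        recs.append(_record(bg[:16] + marker + bg[16:], "regulatory", f"p{i}"))
        labels.append(1)
        bg2 = "".join(rng.choice(list("ACGT"), size=48))
        recs.append(_record(bg2, "control", f"n{i}"))
        labels.append(0)
    model = fit_bag_classifier(recs, labels=labels, k=8, seed=0)
    assert model.beta[model.vocab.index[marker]] > 0


def test_single_class_input_rejected():
    recs = [_record("ACGTACGTACGT", "regulatory", f"r{i}") for i in range(10)]
    with pytest.raises(ValueError):
        fit_bag_classifier(recs, labels=[1] * 10, k=4)


def test_identical_features_give_null_coefficients():
    """The same sequences under both labels carry no signal."""
    rng = np.random.default_rng(13)
    seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(20)]
    recs = [_record(s, "regulatory", f"a{i}") for i, s in enumerate(seqs)]
    recs += [_record(s, "control", f"b{i}") for i, s in enumerate(seqs)]
    labels = [1] * 20 + [0] * 20
    model = fit_bag_classifier(recs, labels=labels, k=6, seed=0)
    assert np.max(np.abs(model.beta)) < 0.1


def test_zero_feature_row_predicts_sigmoid_intercept():
    rng = np.random.default_rng(14)
    seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(20)]
    recs = [_record(s, "regulatory" if i < 10 else "control", f"s{i}")
            for i, s in enumerate(seqs)]
    allowed = {t for s in seqs[:5] for t in tokenize_bag(s, 8)}
    model = fit_bag_classifier(recs, k=8, allowed_vocab=allowed, seed=0)
    # a sequence sharing no 8-mers with the vocabulary: poly-dA is only in
    # the vocabulary if it occurred; drop it explicitly to be sure
    model.vocab.index.pop("AAAAAAAA", None)
    prob = model.predict_proba(["A" * 40])[0]
    assert prob == pytest.approx(1 / (1 + math.exp(-model.intercept)), abs=1e-12)


def test_predictions_monotone_in_decision_score(bag_model, study):
    records = study["holdout_reg"][:20] + study["holdout_ctrl"][:20]
    z = bag_model.decision_function(records)
    p = bag_model.predict_proba(records)
    order = np.argsort(z)
    assert np.all(np.diff(p[order]) >= -1e-12)
    assert np.all((p >= 0) & (p <= 1))


def test_planted_motif_tokens_rank_top_percent(bag_model, motif_set):
    """Canonical 8-mers of the planted consensus land in the top 1%."""
    from kgrammar.seqio import canonical_token

    table = bag_model.kmer_score_table()
    n_top = math.ceil(0.01 * len(table))
    top = set(table.head(n_top)["token"])
    motif_tokens = {
        canonical_token(c[i: i + 8])
        for c in motif_set.consensus
        for i in range(len(c) - 7)
    }
    assert motif_tokens & top, "no planted k-mer in the top tail"


def test_score_table_sorted_and_complete(bag_model):
    table = bag_model.kmer_score_table()
    assert len(table) == len(bag_model.vocab)
    assert (table["beta"].values[:-1] >= table["beta"].values[1:]).all()
    assert {"token", "beta", "entropy", "gc"} <= set(table.columns)


def test_save_load_predictions_bit_identical(tmp_path, bag_model, study):
    path = tmp_path / "bag.npz"
    bag_model.save(path)
    back = BagModel.load(path)
    records = study["holdout_reg"][:10]
    assert np.array_equal(bag_model.predict_proba(records), back.predict_proba(records))
    assert back.C == bag_model.C


def test_bag_profile_constant_on_single_token_sequence(bag_model):
    token = bag_model.vocab.tokens[0]
    if token == token[0] * 8:  # avoid accidental homopolymer
        token = bag_model.vocab.tokens[1]
    seq = "A" * 20
    track = bag_profile(bag_model, seq)
    assert len(track) == 20
    beta = bag_model.beta[bag_model.vocab.index["AAAAAAAA"]] if (
        "AAAAAAAA" in bag_model.vocab
    ) else 0.0
    assert np.allclose(track, beta)


def test_bag_profile_filtered_model_silent_on_low_complexity_tract():
    """A poly(dA:dT) tract scores 0 under the filtered vocabulary but not
    necessarily under the full one."""
    motifs_recs = simulate_dataset(
        n_per_class=150, at_tract=(40, 30), seed=33
    )
    reg, ctrl = split_by_label(motifs_recs)
    train = reg + ctrl
    full = fit_bag_classifier(train, k=8, seed=0)
    all_tokens = set(full.vocab.tokens)
    filtered_vocab = filter_vocabulary(all_tokens, 1.3)
    filt = fit_bag_classifier(train, k=8, allowed_vocab=filtered_vocab, seed=0)
    tract = "A" * 40
    assert np.allclose(bag_profile(filt, tract), 0.0)
    assert np.abs(bag_profile(full, tract)).max() > 0


def test_build_vocabulary_respects_allowed_set():
    lists = [tokenize_bag("ACGTACGTACGT", 4), tokenize_bag("AAAATTTT", 4)]
    allowed = {"ACGT"}
    vocab = build_vocabulary(lists, k=4, allowed=allowed)
    assert vocab.tokens == ("ACGT",)
    assert vocab.filtered
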