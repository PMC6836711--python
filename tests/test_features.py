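import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from screenrank.features import (
    BLOCKS,
    FeatureSpace,
    FeatureSpaceError,
    extract_ngrams,
    fit_feature_space,
    record_text,
    tokenize,
    transform,
)
from conftest import make_record


# -- tokenization ----------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Core outcome sets!", ["core", "outcome", "sets"]),
        ("", []),
        ("COS-2019 update", ["cos", "2019", "update"]),
        ("  spaced\t\nout  ", ["spaced", "out"]),
    ],
)
def test_tokenize_rule(text, expected):
    assert tokenize(text) == expected


# -- n-gram extraction -----------------------------------------------------


def test_extract_ngrams_enumeration():
    got = extract_ngrams(["core", "outcome", "sets"], n_max=2)
    assert sorted(got) == sorted(
        ["core", "outcome", "sets", "core outcome", "outcome sets"]
    )


def test_single_token_yields_unigram_only():
    assert extract_ngrams(["alpha"], n_max=5) == ["alpha"]


@given(st.integers(min_value=0, max_value=30), st.integers(min_value=1, max_value=5))
def test_ngram_count_formula(length, n_max):
    tokens = [f"t{i}" for i in range(length)]
    expected = sum(length - n + 1 for n in range(1, min(n_max, length) + 1))
    assert len(extract_ngrams(tokens, n_max)) == expected


# -- fitting ---------------------------------------------------------------


def test_fit_two_one_word_docs():
    recs = [
        make_record("a", "alpha", None),
        make_record("b", "beta", None),
    ]
    space = fit_feature_space(recs, n_max=1)
    assert len(space.vocabulary_unstemmed) == 2
    assert len(space.vocabulary_stemmed) == 2
    assert space.width == 8  # four blocks of two columns


def test_idf_ordering():
    recs = [
        make_record("a", "common rare1", None),
        make_record("b", "common rare2", None),
        make_record("c", "common rare3", None),
    ]
    space = fit_feature_space(recs, n_max=1)
    vocab, idf = space.vocabulary_unstemmed, space.idf_unstemmed
    common = idf[vocab["common"]]
    assert all(
        common < idf[vocab[t]] for t in ("rare1", "rare2", "rare3")
    )
    # smoothed formula: term in all N docs -> ln((1+N)/(1+N)) + 1 = 1
    assert common == pytest.approx(1.0)
    assert idf[vocab["rare1"]] == pytest.approx(math.log(4 / 2) + 1)


def test_fit_is_deterministic():
    recs = [make_record(f"r{i}", f"one two three doc{i}", "shared abstract text")
            for i in range(5)]
    s1, s2 = fit_feature_space(recs), fit_feature_space(recs)
    assert s1.vocabulary_unstemmed == s2.vocabulary_unstemmed
    assert np.array_equal(s1.idf_stemmed, s2.idf_stemmed)


def test_all_empty_text_is_an_error():
    recs = [make_record("a", "...", None), make_record("b", "!!!", None)]
    with pytest.raises(FeatureSpaceError):
        fit_feature_space(recs)


# -- transform -------------------------------------------------------------


def test_binary_block_ignores_repetition():
    train = [make_record("a", "word word word", None),
             make_record("b", "other text", None)]
    space = fit_feature_space(train, n_max=1)
    X = transform([make_record("q", "word word", None)], space)
    col = space.vocabulary_unstemmed["word"] + space.block_slices["binary_unstemmed"].start
    assert X[0, col] == 1.0


def test_out_of_vocabulary_row_is_zero():
    train = [make_record("a", "alpha beta", None), make_record("b", "beta", None)]
    space = fit_feature_space(train)
    X = transform([make_record("q", "gamma delta", None)], space)
    assert X[0].nnz == 0


def test_tfidf_matches_hand_computation():
    """3-document toy corpus against the documented smoothed-idf formula."""
    train = [
        make_record("d1", "alpha beta", None),
        make_record("d2", "alpha", None),
        make_record("d3", "gamma", None),
    ]
    space = fit_feature_space(train, n_max=1)
    X = transform(train, space).toarray()
    idf_a = math.log(4 / 3) + 1  # df=2, N=3
    idf_b = math.log(4 / 2) + 1
    idf_g = math.log(4 / 2) + 1
    sl = space.block_slices["tfidf_unstemmed"]
    vocab = space.vocabulary_unstemmed
    # n_max=1 and two tokens: doc d1 row = (idf_a, idf_b, 0) L2-normalized
    norm = math.hypot(idf_a, idf_b)
    assert X[0, sl.start + vocab["alpha"]] == pytest.approx(idf_a / norm)
    assert X[0, sl.start + vocab["beta"]] == pytest.approx(idf_b / norm)
    assert X[1, sl.start + vocab["alpha"]] == pytest.approx(1.0)
    assert X[2, sl.start + vocab["gamma"]] == pytest.approx(1.0)
    # binary blocks carry plain presence
    slb = space.block_slices["binary_unstemmed"]
    assert X[0, slb.start + vocab["alpha"]] == 1.0


def test_tfidf_rows_unit_norm_and_no_zero_training_rows():
    train = [make_record(f"r{i}", f"token{i} shared words here", "body text {i}")
             for i in range(6)]
    space = fit_feature_space(train)
    X = transform(train, space)
    sl = space.block_slices["tfidf_unstemmed"]
    norms = np.sqrt(np.asarray(X[:, sl].multiply(X[:, sl]).sum(axis=1)).ravel())
    assert np.allclose(norms, 1.0)
    assert all(X[i].nnz > 0 for i in range(X.shape[0]))


def test_no_ngram_spans_title_abstract_boundary():
    train = [make_record("a", "one two", "three four")]
    space = fit_feature_space(train)
    assert "two three" not in space.vocabulary_unstemmed
    assert "one two" in space.vocabulary_unstemmed
    assert "three four" in space.vocabulary_unstemmed


def test_title_only_mode_ignores_abstracts():
    with_abs = [make_record("a", "some title", "an abstract"),
                make_record("b", "other title", "more text")]
    without = [make_record("a", "some title", None),
               make_record("b", "other title", None)]
    s1 = fit_feature_space(with_abs, text_mode="title_only")
    s2 = fit_feature_space(without, text_mode="title_only")
    assert s1.vocabulary_unstemmed == s2.vocabulary_unstemmed
    assert (transform(with_abs, s1) != transform(without, s1)).nnz == 0


def test_stemmed_block_conflates_variants():
    train = [make_record("a", "outcomes", None), make_record("b", "outcome", None)]
    space = fit_feature_space(train, n_max=1)
    assert len(space.vocabulary_unstemmed) == 2
    assert list(space.vocabulary_stemmed) == ["outcom"]


def test_json_roundtrip(tmp_path):
    train = [make_record("a", "alpha beta gamma", "delta epsilon"),
             make_record("b", "beta beta zeta", None)]
    space = fit_feature_space(train)
    path = tmp_path / "space.json"
    space.to_json(path)
    loaded = FeatureSpace.from_json(path)
    assert loaded.fingerprint() == space.fingerprint()
    assert (transform(train, loaded) != transform(train, space)).nnz == 0


def test_block_order_fixed():
    assert BLOCKS == (
        "tfidf_unstemmed", "tfidf_stemmed", "binary_unstemmed", "binary_stemmed"
    )


def test_record_text_modes():
    rec = make_record("a", "the title", "the abstract")
    assert record_text(rec, "title_only") == "the title"
    assert record_text(rec, "title_and_abstract") == "the title\nthe abstract"
    rec2 = make_record("b", "only title", None)
    assert record_text(rec2, "title_and_abstract") == "only title"
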