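import numpy as np
import pytest

from adrin.embedding import (
    EmbeddingConfig,
    VectorStore,
    calibrate_threshold,
    cosine_similarity,
    matches_above_threshold,
    most_similar,
    train_bigram,
    train_unigram,
)
from adrin.lexicon import SearchTerm
from conftest import planted_store
from reference import brute_force_threshold_curve


def term(t, thr=0.6, category="medication"):
    return SearchTerm(term=t, category=category, threshold=thr)


# -- cosine ------------------------------------------------------------

@pytest.mark.parametrize(
    "v, w, expected",
    [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 2, 2), (2, 1, 2), 8 / 9),
        ((1, 1), (-1, -1), -1.0),
    ],
)
def test_cosine_similarity(v, w, expected):
    assert cosine_similarity(v, w) == pytest.approx(expected)
    assert cosine_similarity(w, v) == pytest.approx(expected)


def test_cosine_zero_vector_rejected():
    with pytest.raises(ValueError, match="zero"):
        cosine_similarity((0, 0), (1, 0))


def test_store_self_similarity_and_symmetry():
    rng = np.random.default_rng(2)
    store = VectorStore(
        [f"w{i}" for i in range(30)], rng.normal(size=(30, 12))
    )
    for t in store.tokens:
        assert store.similarity(t, t) == 1.0
    for a, b in zip(store.tokens[:10], store.tokens[10:20]):
        assert store.similarity(a, b) == pytest.approx(
            store.similarity(b, a), abs=1e-9
        )


# -- queries -----------------------------------------------------------

def test_most_similar_ranking_echoes_inspection_fixture():
    # similarities arranged like the qualitative neighbour inspection:
    # statine -> simvastatine 0.80 first, then pravastatine 0.76
    store = planted_store(
        {
            ("statine", "simvastatine"): 0.80,
            ("statine", "pravastatine"): 0.76,
            ("statine", "crestor"): 0.75,
            ("betablokker", "metoprolol"): 0.74,
        }
    )
    top = most_similar(store, "statine", 3)
    assert [t for t, _ in top] == ["simvastatine", "pravastatine", "crestor"]
    assert top[0][1] == pytest.approx(0.80, abs=1e-6)
    assert all(t != "statine" for t, _ in top)


def test_most_similar_clamps_k_and_breaks_ties_lexicographically():
    store = planted_store(
        {("a", "bb"): 0.5, ("a", "aa"): 0.5, ("a", "cc"): 0.2}
    )
    full = most_similar(store, "a", 99)
    assert len(full) == len(store) - 1
    assert [t for t, _ in full[:2]] == ["aa", "bb"]  # tie at 0.5


def test_most_similar_unknown_term():
    store = planted_store({("a", "b"): 0.5})
    with pytest.raises(KeyError, match="zzz"):
        most_similar(store, "zzz")


def test_matches_above_threshold():
    store = planted_store(
        {
            ("betablokker", "metoprolol"): 0.74,
            ("statine", "simvastatine"): 0.80,
        }
    )
    hit = matches_above_threshold(
        store, "metoprolol", [term("betablokker", 0.6)]
    )
    assert hit == ("betablokker", pytest.approx(0.74, abs=1e-6))
    # strict inequality at the boundary: a threshold equal to the
    # achieved similarity must not match
    exact = store.similarity("metoprolol", "betablokker")
    assert (
        matches_above_threshold(store, "metoprolol",
                                [term("betablokker", exact)])
        is None
    )
    # argmax across terms, and out-of-vocabulary terms are skipped
    hit = matches_above_threshold(
        store,
        "simvastatine",
        [term("statine", 0.6), term("betablokker", 0.01),
         term("zeldzaam")],
    )
    assert hit[0] == "statine"


# -- threshold calibration --------------------------------------------

def test_calibrate_threshold_bounds_and_brute_force():
    rng = np.random.default_rng(7)
    store = VectorStore(
        [f"w{i:02d}" for i in range(50)], rng.normal(size=(50, 8))
    )
    grid = [-1.0, 0.0, 0.3, 0.6, 0.9, 1.01]
    curve = calibrate_threshold(store, "w00", grid)
    assert curve.match_counts[0] == len(store) - 1  # every word at -1
    assert curve.match_counts[-1] == 0  # nothing above cosine 1
    assert list(curve.match_counts) == sorted(
        curve.match_counts, reverse=True
    )
    assert list(curve.match_counts) == brute_force_threshold_curve(
        store, "w00", grid
    )


# -- training ----------------------------------------------------------

def _toy_corpus(n_repeat=2):
    sent = ["metoprolol", "geeft", "duizelig", "klachten"]
    return [sent] * n_repeat + [["eenmalig", "woord"]]


def test_min_count_boundary():
    cfg = EmbeddingConfig(vector_dim=8, seed=1)
    store = train_unigram(_toy_corpus(), cfg)
    assert "metoprolol" in store  # occurs twice
    assert "eenmalig" not in store  # occurs once


def test_training_is_deterministic():
    cfg = EmbeddingConfig(vector_dim=16, seed=9)
    corpus = [["a", "b", "c", "d"], ["a", "c", "b", "e"]] * 10
    s1 = train_unigram(corpus, cfg)
    s2 = train_unigram(corpus, cfg)
    assert s1.tokens == s2.tokens
    assert np.array_equal(s1.vectors, s2.vectors)


def test_training_rejects_empty_corpus():
    with pytest.raises(ValueError):
        train_unigram([], EmbeddingConfig(vector_dim=8))


def test_bigram_phrase_count_boundary():
    cfg = EmbeddingConfig(vector_dim=8, seed=3)
    corpus = (
        [["pijn", "borst", "vandaag"]] * 6
        + [["druk", "borst", "vandaag"]] * 5
        + [["vandaag", "rustig"]] * 4
    )
    store = train_bigram(corpus, cfg)
    assert "pijn_borst" in store  # pair seen 6 times: merged
    assert "druk_borst" not in store  # pair seen 5 times: kept separate
    assert "druk" in store


def test_bigram_stopword_removal_enables_merge():
    cfg = EmbeddingConfig(vector_dim=8, seed=3)
    corpus = [["pijn", "op", "de", "borst", "links"]] * 6
    store = train_bigram(corpus, cfg, stopwords={"op", "de"})
    assert "pijn_borst" in store


def test_cluster_structure_recovered(trained_small, clusters):
    """Planted co-occurrence clusters separate in the trained space:
    mean within-cluster similarity beats cross-cluster by >= 0.1."""
    content = [c for c in clusters if c.role in ("medication", "adr")]
    within, cross = [], []
    for c in content:
        members = [m for m in c.members if m in trained_small]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                within.append(trained_small.similarity(a, b))
    for i, c1 in enumerate(content):
        for c2 in content[i + 1:]:
            for a in c1.members:
                for b in c2.members:
                    if a in trained_small and b in trained_small:
                        cross.append(trained_small.similarity(a, b))
    assert np.mean(within) > np.mean(cross) + 0.1


def test_domain_specific_neighbours_of_red(trained_small, clusters):
    """In a clinical corpus, 'rood' (red) sits with irritation/symptom
    words, not with the other colours."""
    by_id = {c.cluster_id: c for c in clusters}
    symptoms = set(by_id["demo_symptoms"].members)
    colors = set(by_id["demo_colors"].members)
    top5 = [t for t, _ in most_similar(trained_small, "rood", 5)]
    assert not set(top5) & colors
    assert len(set(top5) & symptoms) >= 3
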