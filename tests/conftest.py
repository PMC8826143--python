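import math

import numpy as np
import pytest

from adrin import default_resources
from adrin.embedding import EmbeddingConfig, VectorStore, train_unigram
from adrin.preprocess import NumberLexicon, preprocess_note
from adrin.synthetic import (
    SyntheticParams,
    default_clusters,
    generate_corpus,
    make_oracle_store,
)


def planted_store(pair_sims: dict[tuple[str, str], float]) -> VectorStore:
    """Small store with planted cosines.

    Every *anchor* (first element of a key) gets its own orthonormal
    axis; every other token ``b`` with planted similarity ``s`` to
    anchor ``a`` becomes ``s * e_a + sqrt(1 - s^2) * e_b`` with a unique
    perpendicular axis, so sim(a, b) = s exactly and tokens attached to
    different anchors are mutually orthogonal (those sharing an anchor
    have sim s1 * s2).
    """
    anchors = sorted({a for a, _ in pair_sims})
    others = sorted({b for _, b in pair_sims})
    overlap = set(anchors) & set(others)
    if overlap:
        raise ValueError(f"tokens cannot be both anchor and other: {overlap}")
    dim = len(anchors) + len(others)
    tokens: list[str] = []
    vectors: list[np.ndarray] = []
    for i, a in enumerate(anchors):
        v = np.zeros(dim)
        v[i] = 1.0
        tokens.append(a)
        vectors.append(v)
    for j, b in enumerate(others):
        sims = {a: s for (a, bb), s in pair_sims.items() if bb == b}
        if len(sims) != 1:
            raise ValueError("each non-anchor token may follow one anchor")
        (a, s), = sims.items()
        v = np.zeros(dim)
        v[anchors.index(a)] = s
        v[len(anchors) + j] = math.sqrt(max(0.0, 1.0 - s * s))
        tokens.append(b)
        vectors.append(v)
    return VectorStore(tokens, np.array(vectors))


@pytest.fixture(scope="session")
def clusters():
    return default_clusters()


@pytest.fixture(scope="session")
def oracle_store(clusters):
    return make_oracle_store(clusters, within_sim=0.81, cross_sim=0.0)


@pytest.fixture(scope="session")
def resources():
    return default_resources(use_dictionary=True)


@pytest.fixture(scope="session")
def resources_no_dict(resources):
    return {k: v for k, v in resources.items() if k != "dictionary"}


@pytest.fixture(scope="session")
def dutch_numbers():
    return NumberLexicon.dutch()


@pytest.fixture(scope="session")
def small_corpus(clusters):
    """1,000 synthetic notes with gold, default study-condition params."""
    params = SyntheticParams(n_notes=1000, seed=101)
    return generate_corpus(clusters, params)


@pytest.fixture(scope="session")
def trained_small(clusters, dutch_numbers):
    """A modest trained model (10k notes, d=100) for embedding sanity
    tests; the full-scale training runs in the acceptance suite."""
    notes, _ = generate_corpus(
        clusters, SyntheticParams(n_notes=10000, seed=202)
    )
    corpus = [
        preprocess_note(n, number_lexicon=dutch_numbers) for n in notes
    ]
    cfg = EmbeddingConfig(vector_dim=100, seed=303)
    return train_unigram(corpus, cfg)
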