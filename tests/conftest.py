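"""Shared fixtures: small seeded corpora and embedding models.

Session-scoped because embedding training, while fast, is the dominant cost
and every module exercises the same handful of corpora.
"""

from __future__ import annotations

import math

import pytest

from medtriage.embedding import embed_document, train_embeddings
from medtriage.preprocess import preprocess_corpus
from medtriage.synthetic import (
    SyntheticConfig,
    generate_corpus,
    guidance_preset,
    recommendation_preset,
)


def _prepared(cfg):
    corpus = generate_corpus(cfg)
    docs = preprocess_corpus(corpus.complaints)
    labels = [c.department for c in corpus.complaints]
    return corpus, docs, labels


@pytest.fixture(scope="session")
def separated_corpus():
    """8-department corpus with fully department-specific vocabulary."""
    cfg = guidance_preset(seed=11, n_patients=600, separation=1.0,
                          length_log_mean=math.log(12), length_log_sigma=0.6)
    return _prepared(cfg)


@pytest.fixture(scope="session")
def separated_model(separated_corpus):
    _, docs, _ = separated_corpus
    return train_embeddings(docs, dim=32, architecture="skip_gram", seed=11, epochs=5)


@pytest.fixture(scope="session")
def unseparated_corpus():
    """Department labels carry no vocabulary signal at all (separation 0)."""
    cfg = guidance_preset(seed=12, n_patients=600, separation=0.0,
                          length_log_mean=math.log(12), length_log_sigma=0.6)
    return _prepared(cfg)


@pytest.fixture(scope="session")
def unseparated_model(unseparated_corpus):
    _, docs, _ = unseparated_corpus
    return train_embeddings(docs, dim=16, architecture="skip_gram", seed=12, epochs=3)


@pytest.fixture(scope="session")
def rec_corpus():
    """Single-department physician pool for the recommendation stack."""
    cfg = recommendation_preset(seed=3, n_patients=150, n_physicians=24)
    return _prepared(cfg)


@pytest.fixture(scope="session")
def rec_model(rec_corpus):
    _, docs, _ = rec_corpus
    return train_embeddings(docs, dim=16, architecture="skip_gram", seed=3, epochs=3)


@pytest.fixture(scope="session")
def rec_doc_vectors(rec_corpus, rec_model):
    _, docs, _ = rec_corpus
    return [embed_document(d, rec_model) for d in docs]
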