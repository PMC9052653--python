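"""Shared fixtures: synthetic bundles and cached trained models."""

from __future__ import annotations

import numpy as np
import pytest

import definition2vec as d2v
from definition2vec.corpus import build_definition_map


def make_bundle(seed: int) -> dict:
    """Standard synthetic fixture, loaded into model-ready objects."""
    bundle = d2v.generate(d2v.SynthSpec(seed=seed))
    vocab = d2v.build_vocabulary(bundle.documents)
    corpus = d2v.encode_corpus(bundle.documents, vocab)
    defs = build_definition_map(bundle.definitions, vocab)
    return {"bundle": bundle, "vocab": vocab, "corpus": corpus, "defs": defs}


@pytest.fixture(scope="session")
def standard_data():
    """Bundle cache keyed by generator seed."""
    cache: dict[int, dict] = {}

    def get(seed: int) -> dict:
        if seed not in cache:
            cache[seed] = make_bundle(seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def trained(standard_data):
    """Trained-run cache keyed by (seed, beta); default hyperparameters."""
    cache: dict[tuple[int, float], dict] = {}

    def get(seed: int, beta: float) -> dict:
        key = (seed, beta)
        if key not in cache:
            data = standard_data(seed)
            cfg = d2v.TrainConfig(seed=seed, beta=beta)
            params, losses = d2v.train(data["corpus"], data["defs"], data["vocab"], cfg)
            table = d2v.finalize_embeddings(
                params, data["vocab"], data["vocab"].freq, data["defs"]
            )
            cache[key] = {
                **data, "cfg": cfg, "params": params,
                "losses": losses, "table": table,
            }
        return cache[key]

    return get


@pytest.fixture()
def tiny_setup():
    """Small hand-checkable training setup (10 terms, 2 docs, defs)."""
    rng = np.random.default_rng(99)
    terms = [f"t{chr(ord('a') + i)}" for i in range(10)]
    docs = [[terms[rng.integers(10)] for _ in range(30)] for _ in range(2)]
    vocab = d2v.build_vocabulary(docs)
    corpus = d2v.encode_corpus(docs, vocab)
    def_words = ["alpha", "bravo", "charlie", "delta", "echo"]
    raw = {t: " ".join(rng.choice(def_words, size=3)) for t in terms[:6]}
    defs = build_definition_map(raw, vocab, stopwords=frozenset(), min_def_word_count=1)
    return vocab, corpus, defs
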