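"""Synthetic corpora with planted semantic clusters.

The generator emulates the regime the model is designed for: a modest
corpus of documents, each about a single topic ("cluster"), in which a
term's co-occurrence neighbourhood and its dictionary definition both
encode the same cluster identity.  Each cluster contributes frequent
terms (geometric frequency skew, so the sqrt-frequency weighting is
exercised across a range), rare terms planted with exact corpus counts
of 1-2, and held-out terms that never appear in the corpus but carry
definitions — the out-of-vocabulary regime.  Definitions draw at least
80% of their words from a cluster-private definition vocabulary and the
rest from a shared pool; a shared noise vocabulary is sprinkled across
all documents.

Everything is deterministic given the seed and is emitted in the exact
file dialects the loaders consume, so the whole pipeline is testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SynthSpec:
    """Generator parameters; the defaults define the standard fixture."""

    n_clusters: int = 5
    terms_per_cluster: int = 20
    n_docs: int = 400
    doc_len: int = 50
    rare_fraction: float = 0.2
    oov_per_cluster: int = 2
    def_len: int = 8
    def_vocab_per_cluster: int = 12
    noise_word_prob: float = 0.05
    seed: int = 0
    n_noise_words: int = 20
    n_shared_def_words: int = 10
    geometric_ratio: float = 0.7
    n_similarity_pairs: int = 40  # per kind (within / cross)

    def __post_init__(self):
        for name in (
            "n_clusters", "terms_per_cluster", "n_docs", "doc_len",
            "def_len", "def_vocab_per_cluster",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.oov_per_cluster < 0:
            raise ValueError("oov_per_cluster must be >= 0")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")
        if not 0.0 <= self.noise_word_prob <= 1.0:
            raise ValueError("noise_word_prob must be in [0, 1]")


@dataclass
class SynthBundle:
    """Generated corpus, definitions, gold structure and file paths."""

    documents: list[list[str]]
    definitions: dict[str, str]  # term -> definition text (space-joined)
    labels: dict[str, str]  # in-corpus term -> cluster label
    similarity: list[tuple[str, str, float]]
    oov_terms: dict[str, str]  # held-out term -> cluster label
    rare_terms: dict[str, str]  # planted rare term -> cluster label
    paths: dict[str, Path] = field(default_factory=dict)


def _alpha(i: int) -> str:
    """Two-letter base-26 tag; generated names stay purely alphabetic so
    they survive the digit-stripping text cleaner."""
    if not 0 <= i < 26 * 26:
        raise ValueError("index out of range for two-letter tag")
    return chr(ord("a") + i // 26) + chr(ord("a") + i % 26)


def _cluster_label(c: int) -> str:
    return f"cluster{_alpha(c)}"


def generate(spec: SynthSpec, out_dir: str | Path | None = None) -> SynthBundle:
    """Generate a clustered corpus bundle; optionally write it to disk.

    Raises ValueError when the rare-term occurrence budget cannot fit
    in the corpus.  With ``out_dir`` set, writes corpus.txt,
    definitions.tsv, labels.tsv, similarity.tsv and oov.tsv.
    """
    rng = np.random.default_rng(spec.seed)
    n_rare = round(spec.rare_fraction * spec.terms_per_cluster)
    n_freq = spec.terms_per_cluster - n_rare
    if n_freq < 1:
        raise ValueError("rare_fraction leaves no frequent terms")

    noise_words = [f"noise{_alpha(i)}" for i in range(spec.n_noise_words)]
    shared_def = [f"shareddef{_alpha(i)}" for i in range(spec.n_shared_def_words)]

    freq_terms, rare_terms, oov_terms, cluster_def_vocab = [], [], [], []
    for c in range(spec.n_clusters):
        tag = _alpha(c)
        freq_terms.append([f"c{tag}term{_alpha(i)}" for i in range(n_freq)])
        rare_terms.append([f"c{tag}rare{_alpha(i)}" for i in range(n_rare)])
        oov_terms.append([f"c{tag}oov{_alpha(i)}" for i in range(spec.oov_per_cluster)])
        cluster_def_vocab.append(
            [f"c{tag}def{_alpha(i)}" for i in range(spec.def_vocab_per_cluster)]
        )

    # geometric skew over a cluster's frequent terms
    weights = spec.geometric_ratio ** np.arange(n_freq)
    weights /= weights.sum()

    # documents: round-robin cluster assignment, then per-position draw
    doc_cluster = [d % spec.n_clusters for d in range(spec.n_docs)]
    documents: list[list[str]] = []
    for d in range(spec.n_docs):
        c = doc_cluster[d]
        doc = []
        for _ in range(spec.doc_len):
            if rng.random() < spec.noise_word_prob:
                doc.append(noise_words[rng.integers(len(noise_words))])
            else:
                doc.append(freq_terms[c][rng.choice(n_freq, p=weights)])
        documents.append(doc)

    # plant rare terms with exact 1-2 occurrence budgets
    rare_budget: dict[str, int] = {}
    for c in range(spec.n_clusters):
        slots = [
            (d, p)
            for d in range(spec.n_docs)
            if doc_cluster[d] == c
            for p in range(spec.doc_len)
        ]
        counts = [int(rng.integers(1, 3)) for _ in rare_terms[c]]
        need = sum(counts)
        if need > len(slots):
            raise ValueError(
                f"rare-term budget ({need}) exceeds cluster corpus size "
                f"({len(slots)})"
            )
        chosen = rng.choice(len(slots), size=need, replace=False)
        i = 0
        for term, cnt in zip(rare_terms[c], counts):
            rare_budget[term] = cnt
            for _ in range(cnt):
                d, p = slots[chosen[i]]
                documents[d][p] = term
                i += 1

    # definitions: >=80% cluster-private words, remainder shared
    n_shared_in_def = int(0.2 * spec.def_len)
    n_own_in_def = spec.def_len - n_shared_in_def
    definitions: dict[str, str] = {}
    for c in range(spec.n_clusters):
        for term in freq_terms[c] + rare_terms[c] + oov_terms[c]:
            own = rng.choice(
                spec.def_vocab_per_cluster,
                size=min(n_own_in_def, spec.def_vocab_per_cluster),
                replace=n_own_in_def > spec.def_vocab_per_cluster,
            )
            words = [cluster_def_vocab[c][i] for i in own]
            words += [
                shared_def[rng.integers(len(shared_def))]
                for _ in range(n_shared_in_def)
            ]
            definitions[term] = " ".join(words)

    labels = {
        t: _cluster_label(c)
        for c in range(spec.n_clusters)
        for t in freq_terms[c] + rare_terms[c]
    }
    oov_labels = {
        t: _cluster_label(c) for c in range(spec.n_clusters) for t in oov_terms[c]
    }
    rare_labels = {
        t: _cluster_label(c) for c in range(spec.n_clusters) for t in rare_terms[c]
    }

    # similarity pairs: within-cluster scored high, cross-cluster low
    in_corpus = [t for c in range(spec.n_clusters) for t in freq_terms[c]]
    by_cluster = {c: freq_terms[c] for c in range(spec.n_clusters)}
    similarity: list[tuple[str, str, float]] = []
    seen: set[frozenset] = set()
    def _add_pair(t1: str, t2: str, lo: float, hi: float):
        key = frozenset((t1, t2))
        if t1 != t2 and key not in seen:
            seen.add(key)
            similarity.append((t1, t2, round(float(rng.uniform(lo, hi)), 3)))
    tries = 0
    while len(similarity) < spec.n_similarity_pairs and tries < 10000:
        c = int(rng.integers(spec.n_clusters))
        t1, t2 = rng.choice(len(by_cluster[c]), size=2, replace=False)
        _add_pair(by_cluster[c][t1], by_cluster[c][t2], 7.0, 9.0)
        tries += 1
    target = 2 * spec.n_similarity_pairs
    tries = 0
    while len(similarity) < target and tries < 10000:
        t1, t2 = rng.choice(len(in_corpus), size=2, replace=False)
        if labels[in_corpus[t1]] != labels[in_corpus[t2]]:
            _add_pair(in_corpus[t1], in_corpus[t2], 1.0, 3.0)
        tries += 1

    bundle = SynthBundle(
        documents=documents,
        definitions=definitions,
        labels=labels,
        similarity=similarity,
        oov_terms=oov_labels,
        rare_terms=rare_labels,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SynthBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out_dir / "corpus.txt",
        "definitions": out_dir / "definitions.tsv",
        "labels": out_dir / "labels.tsv",
        "similarity": out_dir / "similarity.tsv",
        "oov": out_dir / "oov.tsv",
    }
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for doc in bundle.documents:
            fh.write(" ".join(doc) + "\n")
    with open(paths["definitions"], "w", encoding="utf-8") as fh:
        for term in sorted(bundle.definitions):
            fh.write(f"{term}\t{bundle.definitions[term]}\n")
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        for term in sorted(bundle.labels):
            fh.write(f"{term}\t{bundle.labels[term]}\n")
    with open(paths["similarity"], "w", encoding="utf-8") as fh:
        for t1, t2, score in bundle.similarity:
            fh.write(f"{t1}\t{t2}\t{score}\n")
    with open(paths["oov"], "w", encoding="utf-8") as fh:
        for term in sorted(bundle.oov_terms):
            fh.write(
                f"{term}\t{bundle.oov_terms[term]}\t{bundle.definitions[term]}\n"
            )
    bundle.paths = paths
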