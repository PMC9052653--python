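"""Intrinsic evaluation of embeddings.

Three probes: cosine nearest neighbours of a query term, Pearson
correlation between model cosine similarity and human similarity
judgements over term pairs, and purity of a k-means clustering of the
embeddings against gold category labels, scored by normalized mutual
information (NMI).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .sgns import EmbeddingTable


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def nearest_to_vector(
    vec: np.ndarray, table: EmbeddingTable, k: int = 10,
    exclude: str | None = None,
) -> list[tuple[str, float]]:
    """Top-k terms by cosine similarity to an arbitrary query vector.

    Ties are broken lexicographically so results are deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    norms = np.linalg.norm(table.vectors, axis=1)
    qn = np.linalg.norm(vec)
    if qn == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    safe = np.where(norms == 0.0, np.inf, norms)
    sims = (table.vectors @ vec) / (safe * qn)
    order = sorted(
        (i for i in range(len(table.terms)) if table.terms[i] != exclude),
        key=lambda i: (-sims[i], table.terms[i]),
    )
    return [(table.terms[i], float(sims[i])) for i in order[:k]]


def nearest_neighbors(
    term: str, table: EmbeddingTable, k: int = 10
) -> list[tuple[str, float]]:
    """Top-k cosine neighbours of a term, the term itself excluded."""
    if term not in table:
        raise KeyError(f"term {term!r} not in embedding table")
    return nearest_to_vector(table[term], table, k, exclude=term)


@dataclass
class SimilarityDataset:
    """Term pairs with human similarity judgements."""

    pairs: list[tuple[str, str, float]]

    def __post_init__(self):
        seen = set()
        for t1, t2, score in self.pairs:
            if not np.isfinite(score):
                raise ValueError(f"non-finite score for pair ({t1}, {t2})")
            key = frozenset((t1, t2))
            if key in seen:
                raise ValueError(f"duplicate pair ({t1}, {t2})")
            seen.add(key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityDataset":
        """TSV rows: term1 TAB term2 TAB human score.  Multi-word terms
        are underscore-joined to match corpus tokens."""
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 3:
                    raise ValueError(f"line {lineno}: expected 3 TSV fields")
                pairs.append((fields[0], fields[1], float(fields[2])))
        return cls(pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def evaluate_similarity(
    ds: SimilarityDataset, table: EmbeddingTable
) -> tuple[float, int]:
    """Pearson r between model cosine and human score over covered pairs.

    Pairs with either term missing from the table are skipped; the
    number of retained pairs is returned alongside r (coverage varies
    across benchmarks, so it is part of the result).  Raises if fewer
    than two pairs are retained or either series is constant.
    """
    if not ds.pairs:
        raise ValueError("similarity dataset is empty")
    model_scores, human_scores = [], []
    for t1, t2, score in ds.pairs:
        if t1 in table and t2 in table:
            model_scores.append(cosine_similarity(table[t1], table[t2]))
            human_scores.append(score)
    n_used = len(model_scores)
    if n_used < 2:
        raise ValueError(f"only {n_used} pair(s) covered by the embeddings")
    if np.std(human_scores) == 0.0 or np.std(model_scores) == 0.0:
        raise ValueError("Pearson r undefined: a score series is constant")
    r, _p = stats.pearsonr(model_scores, human_scores)
    return float(r), n_used


@dataclass
class LabeledTerms:
    """Gold category (e.g. semantic type) per term."""

    labels: dict[str, str]

    def __post_init__(self):
        if any(not t for t in self.labels):
            raise ValueError("empty term in labels")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledTerms":
        labels = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 2:
                    raise ValueError(f"line {lineno}: expected 2 TSV fields")
                labels[fields[0]] = fields[1]
        return cls(labels)

    def __len__(self) -> int:
        return len(self.labels)


def cluster_nmi(
    table: EmbeddingTable,
    labels: LabeledTerms,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    average_method: str = "arithmetic",
    restrict_terms: set[str] | None = None,
) -> float:
    """k-means the labeled term vectors, score purity against labels by NMI.

    Only terms that have both an embedding and a label are clustered
    (optionally further restricted to ``restrict_terms``, e.g. the rare
    subset).  NMI is normalized by the arithmetic mean of the two
    entropies by default; 'min' and 'geometric' are also accepted.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    terms = [t for t in table.terms if t in labels.labels]
    if restrict_terms is not None:
        terms = [t for t in terms if t in restrict_terms]
    if k > len(terms):
        raise ValueError(f"k={k} exceeds the {len(terms)} labeled terms")
    X = np.stack([table[t] for t in terms])
    y = [labels.labels[t] for t in terms]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(X)
    return float(
        normalized_mutual_info_score(y, assignment, average_method=average_method)
    )


def cosine_margin(
    table: EmbeddingTable, labels: LabeledTerms
) -> tuple[float, float, float]:
    """Mean within-category minus mean between-category cosine.

    A direct measure of how well the embedding geometry reflects the
    gold categories.  Returns (within_mean, between_mean, margin).
    """
    groups: dict[str, list[np.ndarray]] = {}
    for t in table.terms:
        lab = labels.labels.get(t)
        if lab is None:
            continue
        v = table[t]
        n = np.linalg.norm(v)
        if n > 0:
            groups.setdefault(lab, []).append(v / n)
    mats = {lab: np.stack(vs) for lab, vs in groups.items() if len(vs) > 0}
    within, between = [], []
    labs = sorted(mats)
    for i, l1 in enumerate(labs):
        X = mats[l1]
        if len(X) > 1:
            iu = np.triu_indices(len(X), 1)
            within.extend((X @ X.T)[iu])
        for l2 in labs[i + 1 :]:
            between.extend((X @ mats[l2].T).ravel())
    if not within or not between:
        raise ValueError("need at least two categories with two members")
    w, b = float(np.mean(within)), float(np.mean(between))
    return w, b, w - b


def cluster_centroids(
    table: EmbeddingTable, labels: LabeledTerms
) -> dict[str, np.ndarray]:
    """Mean embedding per gold category (unnormalized)."""
    sums: dict[str, list[np.ndarray]] = {}
    for t in table.terms:
        lab = labels.labels.get(t)
        if lab is not None:
            sums.setdefault(lab, []).append(table[t])
    if not sums:
        raise ValueError("no labeled term has an embedding")
    return {lab: np.mean(vs, axis=0) for lab, vs in sums.items()}


def nearest_centroid(vec: np.ndarray, centroids: dict[str, np.ndarray]) -> str:
    """Category whose centroid is most cosine-similar to ``vec``;
    ties broken lexicographically."""
    best = sorted(
        centroids, key=lambda lab: (-cosine_similarity(vec, centroids[lab]), lab)
    )
    return best[0]
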