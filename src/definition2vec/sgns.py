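"""Skip-gram with negative sampling, with definition-composed target vectors.

A term's target vector U_w is not a free parameter: it is a blend of a
free vector U'_w and the mean of its definition-word vectors z_d,

    U_w = ( sqrt(f_w) * U'_w  +  beta * mean_d z_d ) / ( sqrt(f_w) + beta )

where f_w is the term's corpus frequency and beta >= 0 controls how
strongly the definition pulls on the embedding.  Frequent terms are
dominated by their corpus context (sqrt(f_w) large), rare terms by
their definition; a term never seen in the corpus (f_w = 0) is embedded
purely as its definition mean, which is what makes out-of-vocabulary
inference possible.  With beta = 0, or for terms with no definition,
the model degenerates to plain skip-gram.

Training minimises the standard negative-sampling loss per
(target, context) pair,

    E = -log sigma(U_t . V_c) - sum_{j in negatives} log sigma(-U_t . V_j),

by SGD.  Gradients flow through the blend: the free vector U'_t is
updated scaled by sqrt(f_t)/(sqrt(f_t)+beta) and each definition-word
vector by beta/(m*(sqrt(f_t)+beta)), m the definition length, once per
occurrence of the word in the definition.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import expit

from .corpus import Corpus, DefinitionMap, Vocabulary

logger = logging.getLogger(__name__)


def sigmoid(x: float) -> float:
    """Logistic function 1/(1+exp(-x)), stable for any finite argument."""
    return float(expit(x))


def pair_loss(u: np.ndarray, v: np.ndarray, label: int) -> float:
    """Negative-sampling loss of one (target, other) pair.

    ``label`` 1 marks a true context pair, 0 a sampled negative.
    Computed as log(1+exp(-s*u.v)) with s = +1/-1, which never
    overflows.
    """
    dot = float(np.dot(u, v))
    if label == 1:
        return float(np.logaddexp(0.0, -dot))
    return float(np.logaddexp(0.0, dot))


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``window`` is the context radius (5 means up to 5 neighbours on
    each side), ``negatives`` the number K of negative samples per
    context pair, ``lr`` the constant SGD learning rate alpha, and
    ``beta`` the definition blending weight; ``beta=0`` disables
    definitions entirely.  ``neg_exponent`` is the power applied to
    unigram frequencies for the negative-sampling distribution (1.0
    samples straight from the corpus distribution).
    """

    window: int = 5
    dim: int = 100
    lr: float = 0.01
    negatives: int = 5
    epochs: int = 10
    beta: float = 10.0
    seed: int = 0
    min_count: int = 1
    neg_exponent: float = 0.75

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class ModelParams:
    """The three learned tables.

    ``U_free`` holds the free (definition-independent) target vectors,
    ``V_ctx`` the context vectors, ``Z`` the definition-word vectors.
    All share the embedding dimension ``dim``.
    """

    dim: int
    U_free: np.ndarray
    V_ctx: np.ndarray
    Z: np.ndarray
    beta: float

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.dim, self.U_free.copy(), self.V_ctx.copy(), self.Z.copy(), self.beta
        )


def init_params(
    n_terms: int, n_def_words: int, cfg: TrainConfig, rng: np.random.Generator
) -> ModelParams:
    """Initialise tables: U' and Z uniform on (-0.5/dim, 0.5/dim), V zero.

    The draw order (U' first, then Z) is part of the contract: any
    trainer sharing the random stream must initialise identically.
    """
    dim = cfg.dim
    U_free = (rng.random((n_terms, dim)) - 0.5) / dim
    Z = (rng.random((n_def_words, dim)) - 0.5) / dim
    V_ctx = np.zeros((n_terms, dim))
    return ModelParams(dim=dim, U_free=U_free, V_ctx=V_ctx, Z=Z, beta=cfg.beta)


def compose_target_vector(
    t: int, params: ModelParams, freq: Sequence[int], defs: DefinitionMap
) -> np.ndarray:
    """Blend the free vector with the definition mean for term ``t``.

    Exact limiting cases: no definition or beta=0 returns U'_t
    verbatim; frequency 0 returns the definition mean verbatim.  The
    doubly-degenerate corner (frequency 0 and beta 0) is defined as
    U'_t.
    """
    d = defs.get(t)
    if not d or params.beta == 0.0:
        return params.U_free[t].copy()
    sf = math.sqrt(freq[t])
    dmean = params.Z[d].mean(axis=0)
    if sf == 0.0:
        return dmean
    return (sf * params.U_free[t] + params.beta * dmean) / (sf + params.beta)


class UnigramTable:
    """Negative-sampling distribution: unigram counts raised to a power."""

    def __init__(self, freq: Sequence[int], exponent: float = 0.75):
        p = np.asarray(freq, dtype=float) ** exponent
        total = p.sum()
        if total <= 0:
            raise ValueError("no sampling mass in frequency table")
        self.probs = p / total
        self.cum = np.cumsum(self.probs)
        self.cum[-1] = 1.0  # guard against rounding


def sample_negatives(
    rng: np.random.Generator,
    k: int,
    dist: UnigramTable,
    exclude: frozenset[int] | set[int],
) -> np.ndarray:
    """Draw ``k`` negative term ids i.i.d. from ``dist``, avoiding ``exclude``.

    Draws are inverse-CDF samples; any draw hitting the excluded set is
    re-drawn.  Raises ValueError if the distribution has no support
    outside ``exclude``.
    """
    if k == 0:
        return np.empty(0, dtype=np.intp)
    cum = dist.cum
    ids = np.searchsorted(cum, rng.random(k), side="right").astype(np.intp)
    rejects = 0
    for i in range(k):
        while ids[i] in exclude:
            rejects += 1
            if rejects >= 200:  # check the rejection is not structural
                mass = sum(dist.probs[j] for j in exclude if 0 <= j < len(dist.probs))
                if mass >= 1.0 - 1e-12:
                    raise ValueError("negative-sampling support is entirely excluded")
                rejects = 0
            ids[i] = np.searchsorted(cum, rng.random(), side="right")
    return ids


def sgd_step(
    t: int,
    ctx: int,
    negs: Sequence[int],
    params: ModelParams,
    freq: Sequence[int],
    defs: DefinitionMap,
    lr: float,
) -> float:
    """One SGD update for a (target, context) pair and its negatives.

    The composed target vector and all gradients are evaluated at the
    pre-step parameter values.  Updates V for the context and each
    negative, U' for the target (scaled by sqrt(f)/(sqrt(f)+beta) when
    a definition is present), and Z for each definition-word occurrence
    of the target.  Returns the summed pair loss of the step, evaluated
    pre-update.
    """
    u_t = compose_target_vector(t, params, freq, defs)
    V = params.V_ctx
    xs = np.empty(1 + len(negs), dtype=np.intp)
    xs[0] = ctx
    xs[1:] = negs
    M = V[xs]  # pre-step copies; xs may repeat ids
    dots = M @ u_t
    g = expit(dots)
    g[0] -= 1.0
    signed = dots.copy()
    signed[0] = -signed[0]
    loss = float(np.logaddexp(0.0, signed).sum())
    G = g @ M
    upd = np.outer(g, u_t)
    upd *= lr
    np.subtract.at(V, xs, upd)  # duplicates accumulate
    d = defs.get(t)
    if d and params.beta > 0.0:
        sf = math.sqrt(freq[t])
        denom = sf + params.beta
        params.U_free[t] -= (lr * sf / denom) * G
        zcoef = lr * params.beta / (len(d) * denom)
        dG = zcoef * G
        for w in d:  # repeated words update once per occurrence
            params.Z[w] -= dG
    else:
        params.U_free[t] -= lr * G
    return loss


def _iter_pairs(doc: Sequence[int], window: int):
    """Yield (position, target, context) over a document; windows do not
    cross document boundaries and are a fixed radius."""
    n = len(doc)
    for tpos in range(n):
        t = doc[tpos]
        lo = 0 if tpos < window else tpos - window
        hi = min(n, tpos + window + 1)
        for cpos in range(lo, hi):
            if cpos != tpos:
                yield tpos, t, doc[cpos]


def _flatten_corpus(corpus: Corpus) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(len(corpus.documents) + 1, dtype=np.int64)
    for i, doc in enumerate(corpus.documents):
        offsets[i + 1] = offsets[i] + len(doc)
    flat = np.empty(offsets[-1], dtype=np.int64)
    for i, doc in enumerate(corpus.documents):
        flat[offsets[i] : offsets[i + 1]] = doc
    return flat, offsets


def _flatten_defs(defs: DefinitionMap, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(n_terms + 1, dtype=np.int64)
    for t in range(n_terms):
        offsets[t + 1] = offsets[t] + len(defs.get(t))
    flat = np.empty(offsets[-1], dtype=np.int64)
    for t in range(n_terms):
        flat[offsets[t] : offsets[t + 1]] = defs.get(t)
    return flat, offsets


@njit(cache=True)
def _epoch_kernel(
    doc_flat, doc_off, U, V, Z, def_flat, def_off, sqrtf, cum,
    window, k, lr, beta, composed, rng,
):  # pragma: no cover - exercised through train()/train_skipgram()
    """One SGD epoch over the flattened corpus.

    ``composed=True`` runs the definition-composed updates (the exact
    per-pair math of ``sgd_step``); ``composed=False`` runs textbook
    skip-gram on the free table.  Both paths draw negatives with the
    same inverse-CDF pattern (a block of k uniforms per pair, scalar
    re-draws on exclusion hits) so they share the random stream.
    Returns the summed pair loss of the epoch.
    """
    dim = U.shape[1]
    u = np.empty(dim)
    G = np.empty(dim)
    xs = np.empty(k + 1, dtype=np.int64)
    gs = np.empty(k + 1)
    total = 0.0
    for di in range(doc_off.size - 1):
        start = doc_off[di]
        n = doc_off[di + 1] - start
        for tp in range(n):
            t = doc_flat[start + tp]
            lo = tp - window if tp >= window else 0
            hi = tp + window + 1
            if hi > n:
                hi = n
            for cp in range(lo, hi):
                if cp == tp:
                    continue
                ctx = doc_flat[start + cp]
                # compose the target vector at current parameter values
                ds, de = def_off[t], def_off[t + 1]
                m = de - ds
                sf = sqrtf[t]
                denom = sf + beta
                if (not composed) or m == 0 or beta == 0.0:
                    blend = False
                    for c in range(dim):
                        u[c] = U[t, c]
                else:
                    blend = True
                    for c in range(dim):
                        acc = 0.0
                        for j in range(ds, de):
                            acc += Z[def_flat[j], c]
                        dmean = acc / m
                        if sf == 0.0:
                            u[c] = dmean
                        else:
                            u[c] = (sf * U[t, c] + beta * dmean) / denom
                # draw negatives: block of k uniforms, re-draw collisions
                xs[0] = ctx
                if k > 0:
                    vals = rng.random(k)
                    for i in range(k):
                        j = np.searchsorted(cum, vals[i], side="right")
                        while j == t or j == ctx:
                            j = np.searchsorted(cum, rng.random(), side="right")
                        xs[i + 1] = j
                # gradients at pre-step values
                for c in range(dim):
                    G[c] = 0.0
                for i in range(k + 1):
                    x = xs[i]
                    dot = 0.0
                    for c in range(dim):
                        dot += u[c] * V[x, c]
                    s = 1.0 / (1.0 + np.exp(-dot))
                    if i == 0:
                        gs[i] = s - 1.0
                        total += np.logaddexp(0.0, -dot)
                    else:
                        gs[i] = s
                        total += np.logaddexp(0.0, dot)
                    for c in range(dim):
                        G[c] += gs[i] * V[x, c]
                for i in range(k + 1):
                    x = xs[i]
                    coef = lr * gs[i]
                    for c in range(dim):
                        V[x, c] -= coef * u[c]
                if blend:
                    cu = lr * sf / denom
                    for c in range(dim):
                        U[t, c] -= cu * G[c]
                    zc = lr * beta / (m * denom)
                    for j in range(ds, de):
                        w = def_flat[j]
                        for c in range(dim):
                            Z[w, c] -= zc * G[c]
                else:
                    for c in range(dim):
                        U[t, c] -= lr * G[c]
    return total


def _run_training(
    corpus: Corpus,
    defs: DefinitionMap,
    vocab: Vocabulary,
    cfg: TrainConfig,
    composed: bool,
) -> tuple[ModelParams, list[float]]:
    if not corpus.documents or corpus.n_tokens() == 0:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(cfg.seed)
    params = init_params(len(vocab), len(defs.def_vocab), cfg, rng)
    table = UnigramTable(vocab.freq, cfg.neg_exponent)
    doc_flat, doc_off = _flatten_corpus(corpus)
    def_flat, def_off = _flatten_defs(defs, len(vocab))
    sqrtf = np.sqrt(np.asarray(vocab.freq, dtype=float))
    # Z may be empty; the kernel indexes it only when definitions exist
    Z = params.Z if params.Z.size else np.zeros((1, cfg.dim))
    epoch_losses: list[float] = []
    n_positions = corpus.n_tokens()
    for epoch in range(cfg.epochs):
        total = _epoch_kernel(
            doc_flat, doc_off, params.U_free, params.V_ctx, Z,
            def_flat, def_off, sqrtf, table.cum,
            cfg.window, cfg.negatives, cfg.lr, cfg.beta, composed, rng,
        )
        epoch_losses.append(total / n_positions)
        logger.info(
            "epoch %d/%d mean loss %.6f", epoch + 1, cfg.epochs, epoch_losses[-1]
        )
    return params, epoch_losses


def train(
    corpus: Corpus,
    defs: DefinitionMap,
    vocab: Vocabulary,
    cfg: TrainConfig,
) -> tuple[ModelParams, list[float]]:
    """Train definition-composed skip-gram by SGD over the corpus.

    Scans each document position in order; every in-window
    (target, context) pair gets ``cfg.negatives`` fresh negative
    samples (excluding the target and the context term) and one
    update with the exact per-pair math of :func:`sgd_step`, executed
    in a compiled kernel.  Returns the trained parameters and the mean
    per-position loss of each epoch.  Fully deterministic given the
    seed.
    """
    return _run_training(corpus, defs, vocab, cfg, composed=True)


def train_skipgram(
    corpus: Corpus,
    defs: DefinitionMap,
    vocab: Vocabulary,
    cfg: TrainConfig,
) -> tuple[ModelParams, list[float]]:
    """Plain skip-gram negative sampling, textbook updates.

    The reference path: it shares the initialisation and random stream
    of :func:`train` (the unused Z table is still drawn, keeping the
    streams aligned) but never composes the target vector — the free
    table is both read and updated directly.  With beta = 0 the two
    trainers produce bit-identical trajectories.
    """
    return _run_training(corpus, defs, vocab, cfg, composed=False)


@dataclass
class EmbeddingTable:
    """Final composed embeddings, one vector per vocabulary term."""

    terms: list[str]
    vectors: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        if len(self.terms) != self.vectors.shape[0]:
            raise ValueError("terms/vectors length mismatch")
        self.index = {t: i for i, t in enumerate(self.terms)}

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def __getitem__(self, term: str) -> np.ndarray:
        return self.vectors[self.index[term]]

    def save_word2vec(self, path: str | Path) -> None:
        """word2vec text format: 'n dim' header, then term + vector per line.

        Floats are written with repr precision so a read-back is exact.
        """
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.terms)} {self.dim}\n")
            for term, vec in zip(self.terms, self.vectors):
                fh.write(term + " " + " ".join(repr(float(x)) for x in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("malformed word2vec header")
            n, dim = int(header[0]), int(header[1])
            terms, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"malformed embedding row for {parts[0]!r}")
                terms.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(terms) != n:
            raise ValueError("header term count does not match rows")
        return cls(terms=terms, vectors=np.array(rows, dtype=float))


def finalize_embeddings(
    params: ModelParams,
    vocab: Vocabulary,
    freq: Sequence[int],
    defs: DefinitionMap,
) -> EmbeddingTable:
    """Compose the final embedding of every vocabulary term."""
    vecs = np.empty((len(vocab), params.dim))
    for i in range(len(vocab)):
        vecs[i] = compose_target_vector(i, params, freq, defs)
    return EmbeddingTable(terms=list(vocab.terms), vectors=vecs)


def embed_oov(
    def_words: Sequence[str], params: ModelParams, defs: DefinitionMap
) -> np.ndarray:
    """Embed an unseen term as the mean of its definition-word vectors.

    Words absent from the definition vocabulary are skipped with a
    warning; raises ValueError if none resolve.  Identical to the
    composed target vector at corpus frequency 0.
    """
    ids = []
    for w in def_words:
        j = defs.def_index.get(w)
        if j is None:
            logger.warning("definition word %r not in definition vocabulary", w)
        else:
            ids.append(j)
    if not ids:
        raise ValueError("no definition word could be resolved")
    return params.Z[ids].mean(axis=0)


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    vocab: Vocabulary,
    defs: DefinitionMap,
    cfg: TrainConfig,
) -> None:
    """Serialize tables + vocabularies + config to a single .npz archive."""
    term_ids = sorted(defs.defs)
    offsets = np.zeros(len(term_ids) + 1, dtype=np.int64)
    flat: list[int] = []
    for i, tid in enumerate(term_ids):
        flat.extend(defs.defs[tid])
        offsets[i + 1] = len(flat)
    np.savez(
        path,
        U_free=params.U_free,
        V_ctx=params.V_ctx,
        Z=params.Z,
        beta=np.array(params.beta),
        terms=np.array(vocab.terms, dtype=object),
        freq=np.array(vocab.freq, dtype=np.int64),
        def_vocab=np.array(defs.def_vocab, dtype=object),
        def_term_ids=np.array(term_ids, dtype=np.int64),
        def_offsets=offsets,
        def_flat=np.array(flat, dtype=np.int64),
        config=np.array(json.dumps(asdict(cfg))),
    )


def load_checkpoint(
    path: str | Path,
) -> tuple[ModelParams, Vocabulary, DefinitionMap, TrainConfig]:
    with np.load(path, allow_pickle=True) as z:
        cfg = TrainConfig(**json.loads(str(z["config"])))
        params = ModelParams(
            dim=int(z["U_free"].shape[1]),
            U_free=z["U_free"],
            V_ctx=z["V_ctx"],
            Z=z["Z"],
            beta=float(z["beta"]),
        )
        vocab = Vocabulary(
            terms=[str(t) for t in z["terms"]], freq=[int(f) for f in z["freq"]]
        )
        flat = z["def_flat"]
        offsets = z["def_offsets"]
        defs = {
            int(tid): [int(w) for w in flat[offsets[i] : offsets[i + 1]]]
            for i, tid in enumerate(z["def_term_ids"])
        }
        dmap = DefinitionMap(
            def_vocab=[str(w) for w in z["def_vocab"]], defs=defs
        )
    return params, vocab, dmap, cfg
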