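"""Model/Results surface over the definition-composed skip-gram trainer.

`Definition2Vec` holds the data (encoded corpus, vocabulary, definition
map) and the training configuration; `fit()` runs SGD and returns a
`Definition2VecResults` with the learned tables, the composed embedding
table, the per-epoch loss curve and convenience evaluation methods.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np

from . import corpus as cio
from . import evaluate as ev
from . import sgns

logger = logging.getLogger(__name__)


class Definition2Vec:
    """Definition-augmented skip-gram embedding model.

    Parameters
    ----------
    corpus : Corpus
        Encoded documents (sequences of vocabulary ids).
    vocab : Vocabulary
        Term index with corpus frequencies.
    definitions : DefinitionMap, optional
        Cleaned term definitions; omit (or pass ``None``) for plain
        skip-gram behaviour.
    config : TrainConfig, optional
        Training hyperparameters; defaults follow the standard recipe
        (window 5, dim 100, lr 0.01, 5 negatives, 10 epochs, beta 10).
    """

    def __init__(
        self,
        corpus: cio.Corpus,
        vocab: cio.Vocabulary,
        definitions: cio.DefinitionMap | None = None,
        config: sgns.TrainConfig | None = None,
    ):
        self.corpus = corpus
        self.vocab = vocab
        self.definitions = definitions or cio.DefinitionMap.empty()
        self.config = config or sgns.TrainConfig()

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        definitions_path: str | Path | None = None,
        config: sgns.TrainConfig | None = None,
        stopwords_path: str | Path | None = None,
        min_def_word_count: int = 2,
    ) -> "Definition2Vec":
        """Build the model from a corpus file and an optional definitions TSV.

        The corpus file has one document per line, space-separated
        tokens, multi-word terms already underscore-joined.
        """
        config = config or sgns.TrainConfig()
        docs = cio.read_corpus_file(corpus_path)
        vocab = cio.build_vocabulary(docs, min_count=config.min_count)
        corpus = cio.encode_corpus(docs, vocab)
        if definitions_path is not None:
            stop = (
                cio.read_stopwords(stopwords_path)
                if stopwords_path
                else cio.DEFAULT_STOPWORDS
            )
            defs = cio.read_definitions_tsv(
                definitions_path, vocab, stop, min_def_word_count
            )
        else:
            defs = cio.DefinitionMap.empty()
        return cls(corpus, vocab, defs, config)

    def fit(self, plain_skipgram: bool = False) -> "Definition2VecResults":
        """Train and return a results object.

        ``plain_skipgram=True`` runs the internal reference skip-gram
        trainer instead (textbook updates, shared random stream), which
        ignores definitions during training.
        """
        t0 = time.perf_counter()
        trainer = sgns.train_skipgram if plain_skipgram else sgns.train
        params, losses = trainer(self.corpus, self.definitions, self.vocab, self.config)
        elapsed = time.perf_counter() - t0
        logger.info("training finished in %.1f s", elapsed)
        if plain_skipgram:
            table = sgns.EmbeddingTable(
                terms=list(self.vocab.terms), vectors=params.U_free.copy()
            )
        else:
            table = sgns.finalize_embeddings(
                params, self.vocab, self.vocab.freq, self.definitions
            )
        return Definition2VecResults(self, params, table, losses, elapsed)


class Definition2VecResults:
    """Trained tables, composed embeddings and diagnostics."""

    def __init__(
        self,
        model: Definition2Vec,
        params: sgns.ModelParams,
        embeddings: sgns.EmbeddingTable,
        epoch_losses: list[float],
        elapsed: float = float("nan"),
    ):
        self.model = model
        self.params = params
        self.embeddings = embeddings
        self.epoch_losses = epoch_losses
        self.elapsed = elapsed

    # -- queries ---------------------------------------------------------
    def __getitem__(self, term: str) -> np.ndarray:
        return self.embeddings[term]

    def embed_oov(self, def_words: Sequence[str]) -> np.ndarray:
        """Embed an unseen term as the mean of its definition-word vectors."""
        return sgns.embed_oov(def_words, self.params, self.model.definitions)

    def nearest(self, term: str, k: int = 10) -> list[tuple[str, float]]:
        return ev.nearest_neighbors(term, self.embeddings, k)

    def nearest_to_vector(self, vec: np.ndarray, k: int = 10) -> list[tuple[str, float]]:
        return ev.nearest_to_vector(vec, self.embeddings, k)

    def evaluate_similarity(self, dataset: ev.SimilarityDataset) -> tuple[float, int]:
        return ev.evaluate_similarity(dataset, self.embeddings)

    def cluster_nmi(self, labels: ev.LabeledTerms, k: int, seed: int = 0) -> float:
        return ev.cluster_nmi(self.embeddings, labels, k, seed)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable overview of the fitted model."""
        cfg = self.model.config
        vocab = self.model.vocab
        defs = self.model.definitions
        n_def = len(defs.defs)
        lines = [
            "definition2vec results",
            "=" * 44,
            f"{'terms':<28}{len(vocab):>16}",
            f"{'terms with definition':<28}{n_def:>16}",
            f"{'definition words':<28}{len(defs.def_vocab):>16}",
            f"{'tokens in corpus':<28}{self.model.corpus.n_tokens():>16}",
            f"{'dimension':<28}{cfg.dim:>16}",
            f"{'window':<28}{cfg.window:>16}",
            f"{'negatives (K)':<28}{cfg.negatives:>16}",
            f"{'beta':<28}{cfg.beta:>16.3g}",
            f"{'learning rate':<28}{cfg.lr:>16.3g}",
            f"{'epochs':<28}{cfg.epochs:>16}",
            f"{'seed':<28}{cfg.seed:>16}",
            f"{'first-epoch mean loss':<28}{self.epoch_losses[0]:>16.6f}",
            f"{'final-epoch mean loss':<28}{self.epoch_losses[-1]:>16.6f}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save_embeddings(self, path: str | Path) -> None:
        self.embeddings.save_word2vec(path)

    def save_checkpoint(self, path: str | Path) -> None:
        sgns.save_checkpoint(
            path, self.params, self.model.vocab, self.model.definitions,
            self.model.config,
        )

    @classmethod
    def from_checkpoint(cls, path: str | Path) -> "Definition2VecResults":
        params, vocab, defs, cfg = sgns.load_checkpoint(path)
        model = Definition2Vec(cio.Corpus(documents=[]), vocab, defs, cfg)
        table = sgns.finalize_embeddings(params, vocab, vocab.freq, defs)
        return cls(model, params, table, epoch_losses=[float("nan")])
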