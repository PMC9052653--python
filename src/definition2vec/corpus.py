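"""Corpus reading, cleaning, concept matching and definition loading.

The training pipeline consumes clinical free text in three stages: raw
text is cleaned into lowercase alphabetic tokens, token runs are matched
against a term dictionary (multi-word concepts become single
underscore-joined tokens, unmatched tokens are dropped), and the matched
corpus is indexed into a dense-id :class:`Vocabulary`.  Term definitions
are loaded either from a two-column TSV or joined out of UMLS-style
pipe-delimited MRCONSO/MRDEF release files, cleaned with the same text
rules, and indexed into a :class:`DefinitionMap` over a separate
definition-word vocabulary.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_NON_ALPHA = re.compile(r"[^a-z_]+")


class EmptyVocabularyError(ValueError):
    """No term survived the frequency cutoff."""


class DefinitionParseError(ValueError):
    """A definitions file row could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def preprocess_text(raw: str) -> list[str]:
    """Clean raw text into lowercase alphabetic tokens.

    Splits on whitespace, lowercases, deletes digits and punctuation
    inside each token, and drops tokens left empty (pure numbers,
    isolated punctuation).  Underscores are preserved so already-joined
    multi-word terms survive a round trip.
    """
    tokens = []
    for tok in raw.lower().split():
        tok = _NON_ALPHA.sub("", tok)
        if tok:
            tokens.append(tok)
    return tokens


@dataclass(frozen=True)
class TermDictionary:
    """Set of known terms; multi-word entries are single-space separated."""

    entries: frozenset[str]
    max_words: int = field(init=False, default=1)

    def __post_init__(self):
        cleaned = frozenset(e.strip().lower() for e in self.entries if e.strip())
        object.__setattr__(self, "entries", cleaned)
        longest = max((e.count(" ") + 1 for e in cleaned), default=1)
        object.__setattr__(self, "max_words", longest)

    @classmethod
    def from_file(cls, path: str | Path) -> "TermDictionary":
        """One term per line; multi-word terms space-separated."""
        with open(path, encoding="utf-8") as fh:
            return cls(frozenset(line.strip() for line in fh if line.strip()))

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def match_terms(
    tokens: Sequence[str], dictionary: TermDictionary, max_len: int = 5
) -> list[str]:
    """Greedy left-to-right longest match of token runs against a dictionary.

    Matched multi-token spans are emitted as a single underscore-joined
    term; tokens matching no dictionary entry are dropped.  ``max_len``
    caps the span length tried (the effective cap is also limited by the
    longest dictionary entry).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    cap = min(max_len, dictionary.max_words)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = 0
        for span in range(min(cap, n - i), 0, -1):
            if " ".join(tokens[i : i + span]) in dictionary:
                matched = span
                break
        if matched:
            out.append("_".join(tokens[i : i + matched]))
            i += matched
        else:
            i += 1
    return out


@dataclass
class Vocabulary:
    """Dense term index with per-term corpus occurrence counts.

    Ids run 0..|V|-1 in descending-frequency order (ties lexicographic),
    so frequent terms get small ids.  ``freq[i]`` is the exact number of
    occurrences of term ``i`` in the corpus the vocabulary was built
    from; it is the f_w entering the composed target vector.
    """

    terms: list[str]
    freq: list[int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("duplicate terms in vocabulary")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


def build_vocabulary(
    documents: Iterable[Sequence[str]], min_count: int = 1
) -> Vocabulary:
    """Count term occurrences and assign dense ids.

    Terms occurring fewer than ``min_count`` times are dropped.  Raises
    :class:`EmptyVocabularyError` if nothing survives.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter()
    for doc in documents:
        counts.update(doc)
    kept = [(t, c) for t, c in counts.items() if c >= min_count]
    if not kept:
        raise EmptyVocabularyError(
            f"no term occurs at least min_count={min_count} times"
        )
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    return Vocabulary(terms=[t for t, _ in kept], freq=[c for _, c in kept])


@dataclass
class Corpus:
    """Documents as sequences of vocabulary ids, original order preserved."""

    documents: list[list[int]]

    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)


def encode_corpus(documents: Iterable[Sequence[str]], vocab: Vocabulary) -> Corpus:
    """Map term documents to id documents, silently dropping OOV terms."""
    idx = vocab.index
    return Corpus([[idx[t] for t in doc if t in idx] for doc in documents])


def read_corpus_file(path: str | Path) -> list[list[str]]:
    """One document per line, space-separated tokens."""
    with open(path, encoding="utf-8") as fh:
        return [line.split() for line in fh if line.strip()]


def write_corpus_file(path: str | Path, documents: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(" ".join(doc) + "\n")


def read_stopwords(path: str | Path) -> frozenset[str]:
    """One word per line."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())


#: Minimal default clinical-text stop list used when no file is supplied.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be but by for from has have in is it its of on or
    that the this to was were which with""".split()
)


@dataclass
class DefinitionMap:
    """Term id -> cleaned definition-word id sequence.

    Definition words live in their own dense vocabulary ``def_vocab``
    (they are not corpus terms and get their own embedding table).
    Terms without definitions are simply absent from ``defs``; the model
    treats them as having an empty definition.
    """

    def_vocab: list[str]
    defs: dict[int, list[int]]
    def_index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.def_index = {w: i for i, w in enumerate(self.def_vocab)}

    def get(self, term_id: int) -> list[int]:
        return self.defs.get(term_id, [])

    def __len__(self) -> int:
        return len(self.defs)

    @classmethod
    def empty(cls) -> "DefinitionMap":
        return cls(def_vocab=[], defs={})


def build_definition_map(
    raw_defs: Mapping[str, str],
    vocab: Vocabulary,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    min_def_word_count: int = 2,
) -> DefinitionMap:
    """Clean raw definition text and index it against a vocabulary.

    ``raw_defs`` maps term strings to (possibly concatenated) definition
    text.  Text is cleaned with :func:`preprocess_text`, stop words are
    removed, and definition words occurring fewer than
    ``min_def_word_count`` times across all retained definitions are
    removed.  Terms absent from ``vocab`` are ignored.
    """
    cleaned: dict[int, list[str]] = {}
    for term, text in raw_defs.items():
        tid = vocab.index.get(term)
        if tid is None:
            continue
        words = [w for w in preprocess_text(text) if w not in stopwords]
        if words:
            cleaned[tid] = words
    word_counts = Counter(w for words in cleaned.values() for w in words)
    kept_words = {w for w, c in word_counts.items() if c >= min_def_word_count}
    # dense ids in descending frequency, ties lexicographic, for determinism
    def_vocab = sorted(kept_words, key=lambda w: (-word_counts[w], w))
    def_index = {w: i for i, w in enumerate(def_vocab)}
    defs = {}
    for tid, words in cleaned.items():
        ids = [def_index[w] for w in words if w in kept_words]
        if ids:
            defs[tid] = ids
    return DefinitionMap(def_vocab=def_vocab, defs=defs)


def read_definitions_tsv(
    path: str | Path,
    vocab: Vocabulary,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    min_def_word_count: int = 2,
) -> DefinitionMap:
    """Load a two-column TSV (term TAB definition text) into a DefinitionMap.

    Multiple rows for the same term are concatenated in file order
    before cleaning.  Raises :class:`DefinitionParseError` on a row with
    no tab separator.
    """
    raw: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if "\t" not in line:
                raise DefinitionParseError("expected 'term<TAB>definition'", lineno)
            term, text = line.rstrip("\n").split("\t", 1)
            term = term.strip()
            if term in raw:
                raw[term] = raw[term] + " " + text
            else:
                raw[term] = text
    return build_definition_map(raw, vocab, stopwords, min_def_word_count)


def parse_umls_rrf(
    mrconso_path: str | Path,
    mrdef_path: str | Path,
    conso_cols: tuple[int, int, int] = (0, 7, 14),
    def_cols: tuple[int, int, int] = (0, 1, 5),
) -> dict[str, str]:
    """Join UMLS-style MRCONSO/MRDEF release files into term -> definition text.

    Both files are pipe-delimited.  ``conso_cols`` gives the (CUI, AUI,
    STR) column positions in MRCONSO and ``def_cols`` the (CUI, AUI,
    DEF) positions in MRDEF; defaults match the standard layouts.
    Definitions attach to atoms (AUIs) but are pooled per concept: every
    term string of a CUI maps to the concatenation, in file order, of
    all definitions of all AUIs of that CUI.  Term strings are
    lowercased with internal spaces preserved; the underscore join
    happens downstream during term matching.  Short rows are skipped
    with a warning, as are definitions whose CUI names no term.
    """
    cui_c, _aui_c, str_c = conso_cols
    cui_d, _aui_d, def_d = def_cols

    cui_terms: dict[str, list[str]] = {}
    with open(mrconso_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("|")
            if len(fields) <= max(conso_cols):
                logger.warning("MRCONSO line %d: too few fields, skipped", lineno)
                continue
            cui, term = fields[cui_c], fields[str_c].strip().lower()
            if term:
                cui_terms.setdefault(cui, []).append(term)

    cui_defs: dict[str, list[str]] = {}
    with open(mrdef_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("|")
            if len(fields) <= max(def_cols):
                logger.warning("MRDEF line %d: too few fields, skipped", lineno)
                continue
            cui, definition = fields[cui_d], fields[def_d].strip()
            if cui not in cui_terms:
                logger.warning(
                    "MRDEF line %d: CUI %s has no MRCONSO term, ignored", lineno, cui
                )
                continue
            if definition:
                cui_defs.setdefault(cui, []).append(definition)

    table: dict[str, str] = {}
    for cui, definitions in cui_defs.items():
        text = " ".join(definitions)
        for term in cui_terms[cui]:
            if term in table:
                table[term] = table[term] + " " + text
            else:
                table[term] = text
    return table
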