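"""Vocabulary scenarios and the document-term representation.

Topic modeling on lay health text is run over a controlled vocabulary: the
MED scenario keeps only medically relevant terms (a MeSH-style list plus drug
and alternative-treatment lists), and the +NN / +V / +A scenarios widen it
with nouns, verbs and adjectives. A small blocklist of over-represented
noise terms (defaults: femme, temps) is always excluded, as are stopwords,
slang and pseudonyms (already removed upstream, re-checked here).

Medical terms may be multi-word ("cancer du sein"); they are matched
longest-first, left-to-right, non-overlapping, and a matched span becomes a
single vocabulary term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LexiconSet
from .preprocess import Token

SCENARIOS = ("MED", "MED+NN", "MED+NN+V", "MED+NN+V+A")
DEFAULT_NOISE_TERMS = frozenset({"femme", "temps"})


@dataclass
class Vocabulary:
    """Ordered distinct terms; the list index is the term id."""

    scenario: str
    terms: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be distinct")
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class DocTermCorpus:
    """Per document: the sequence of retained term ids (length l_d)."""

    docs: list[np.ndarray]
    vocabulary: Vocabulary

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def doc_lengths(self) -> np.ndarray:
        return np.array([len(d) for d in self.docs], dtype=np.int64)

    @property
    def n_tokens(self) -> int:
        return int(self.doc_lengths.sum())

    def term_counts(self) -> np.ndarray:
        """Document-term count matrix (dense, n_docs x |V|)."""
        V = len(self.vocabulary)
        counts = np.zeros((self.n_docs, V), dtype=np.int64)
        for d, ids in enumerate(self.docs):
            np.add.at(counts[d], ids, 1)
        return counts


def _match_spans(lemmas: list[str], medical_terms: set[str]
                 ) -> list[tuple[str, int, int]]:
    """(term, start, length) spans after longest-first multi-word fusion."""
    multi = [t.split() for t in medical_terms if " " in t]
    max_len = max((len(m) for m in multi), default=1)
    multi_set = {tuple(m) for m in multi}

    out: list[tuple[str, int, int]] = []
    i = 0
    n = len(lemmas)
    while i < n:
        matched = False
        if multi_set:
            for span in range(min(max_len, n - i), 1, -1):
                cand = tuple(lemmas[i:i + span])
                if cand in multi_set:
                    out.append((" ".join(cand), i, span))
                    i += span
                    matched = True
                    break
        if not matched:
            out.append((lemmas[i], i, 1))
            i += 1
    return out


def multiword_match(lemmas: list[str], medical_terms: set[str]) -> list[str]:
    """Fuse multi-word medical terms into single terms.

    Longest-match-first, non-overlapping, left to right: on ["a","b","c"]
    with candidates "a b" and "b c", "a b" wins and "c" stays single.
    Single tokens pass through unchanged (fused or not).
    """
    return [term for term, _, _ in _match_spans(lemmas, medical_terms)]


def _excluded_terms(lexicons: LexiconSet) -> set[str]:
    noise = {t.lower() for t in lexicons.noise_terms} | set(DEFAULT_NOISE_TERMS)
    return ({t.lower() for t in lexicons.stopwords}
            | {t.lower() for t in lexicons.slang}
            | {t.lower() for t in lexicons.pseudonyms}
            | noise)


def build_vocabulary(
    tokenized_corpus: list[list[Token]],
    scenario: str = "MED+NN+V+A",
    lexicons: LexiconSet | None = None,
) -> tuple[Vocabulary, DocTermCorpus]:
    """Reduce a tokenized corpus to term-id sequences under a scenario.

    MED keeps tokens whose lemma (or fused multi-word span) is a medical
    term; +NN/+V/+A additionally keep tokens tagged with those POS classes.
    Emits a warning (not an error) if every document empties out.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    lexicons = lexicons or LexiconSet()
    med = {t.lower() for t in lexicons.medical_terms}
    excluded = _excluded_terms(lexicons)
    extra_pos: set[str] = set()
    if scenario != "MED":
        extra_pos.add("NN")
    if scenario in ("MED+NN+V", "MED+NN+V+A"):
        extra_pos.add("V")
    if scenario == "MED+NN+V+A":
        extra_pos.add("A")

    kept_docs: list[list[str]] = []
    for tokens in tokenized_corpus:
        spans = _match_spans([t.lemma for t in tokens], med)
        kept: list[str] = []
        for term, start, length in spans:
            if term in excluded:
                continue
            if term in med or (length == 1 and tokens[start].pos in extra_pos):
                kept.append(term)
        kept_docs.append(kept)

    # term ids in order of first appearance across the corpus
    terms: list[str] = []
    index: dict[str, int] = {}
    for doc in kept_docs:
        for term in doc:
            if term not in index:
                index[term] = len(terms)
                terms.append(term)

    vocab = Vocabulary(scenario=scenario, terms=terms)
    docs = [np.array([index[t] for t in doc], dtype=np.int64) for doc in kept_docs]
    corpus = DocTermCorpus(docs=docs, vocabulary=vocab)
    if tokenized_corpus and corpus.n_tokens == 0:
        warnings.warn("all documents are empty after vocabulary filtering",
                      stacklevel=2)
    return vocab, corpus


class VocabularyBuilder(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`build_vocabulary`.

    ``fit`` freezes the vocabulary on the training corpus; ``transform``
    re-encodes token lists against it (unseen terms dropped), so the same
    vocabulary can encode both messages and questionnaire items.
    """

    def __init__(self, scenario: str = "MED+NN+V+A",
                 lexicons: LexiconSet | None = None):
        self.scenario = scenario
        self.lexicons = lexicons

    def fit(self, X: list[list[Token]], y=None):
        self.vocabulary_, self.corpus_ = build_vocabulary(
            X, self.scenario, self.lexicons)
        return self

    def transform(self, X: list[list[Token]]) -> DocTermCorpus:
        if not hasattr(self, "vocabulary_"):
            raise AttributeError("VocabularyBuilder is not fitted")
        lexicons = self.lexicons or LexiconSet()
        med = {t.lower() for t in lexicons.medical_terms}
        idx = self.vocabulary_.index
        docs = []
        for tokens in X:
            fused = multiword_match([t.lemma for t in tokens], med)
            docs.append(np.array([idx[t] for t in fused if t in idx],
                                 dtype=np.int64))
        return DocTermCorpus(docs=docs, vocabulary=self.vocabulary_)

    def fit_transform(self, X, y=None, **kwargs) -> DocTermCorpus:
        return self.fit(X).corpus_
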