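"""Normalization of noisy patient-authored text.

Social-media text in French health communities is heterogeneous: user tags,
hyperlinks, slang (lol, mdr, xD), lay vocabulary (crabe for cancer),
misspellings and pseudonyms all degrade topic modeling. The pipeline applies
nine ordered steps:

1. user-tag removal (@name)
2. hyperlink -> "link", email -> "mail", emoticon coding (:) -> :smile:)
3. slang removal
4. lemmatization (pluggable; dictionary lookup by default)
5. lowercasing
6. stopword removal
7. lay-term -> medical-term substitution
8. spelling correction (pluggable; dictionary lookup by default)
9. pseudonym removal

The pipeline is deterministic and idempotent: re-applying it to its own
detokenized output changes nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Protocol

from sklearn.base import BaseEstimator, TransformerMixin

from .io import LexiconSet

STEP_ORDER = (
    "user_tags", "links", "slang", "lemmatize", "lowercase",
    "stopwords", "lay_terms", "spelling", "pseudonyms",
)


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str = "OTHER"  # one of NN, V, A, OTHER


@dataclass
class PreprocessConfig:
    """Which steps run, and how links/emails are handled.

    ``steps`` must be a subsequence of the canonical order. ``link_mode``
    selects between replacing hyperlinks/emails with marker tokens
    ("replace", the default) and dropping them outright ("delete").
    """

    steps: tuple[str, ...] = STEP_ORDER
    link_mode: str = "replace"  # or "delete"
    link_token: str = "link"
    mail_token: str = "mail"
    emoticon_coding: bool = True

    def __post_init__(self) -> None:
        it = iter(STEP_ORDER)
        if not all(s in it for s in self.steps):
            raise ValueError(
                f"steps must be a subsequence of {STEP_ORDER}, got {self.steps}")
        if self.link_mode not in ("replace", "delete"):
            raise ValueError(f"link_mode must be 'replace' or 'delete'")


class Lemmatizer(Protocol):
    def __call__(self, surface: str) -> tuple[str, str]:
        """Return (lemma, pos) for a surface form."""


class DictionaryLemmatizer:
    """Lemma/POS lookup tables; identity lemma and POS OTHER when absent.

    Stands in for a full morphological analyzer: adequate whenever the lemma
    table covers the corpus (always true for synthetic corpora).
    """

    def __init__(self, lemmas: dict[str, str] | None = None,
                 pos: dict[str, str] | None = None):
        self.lemmas = lemmas or {}
        self.pos = pos or {}

    def __call__(self, surface: str) -> tuple[str, str]:
        key = surface.lower()
        lemma = self.lemmas.get(key, surface)
        return lemma, self.pos.get(lemma.lower(), self.pos.get(key, "OTHER"))


class DictionarySpeller:
    """Misspelling->correction lookup; identity when absent."""

    def __init__(self, corrections: dict[str, str] | None = None):
        self.corrections = corrections or {}

    def __call__(self, token: str) -> str:
        return self.corrections.get(token, token)


EMOTICON_TABLE = {
    ":)": ":smile:", ":-)": ":smile:", ":(": ":sad:", ":-(": ":sad:",
    ":D": ":laugh:", ";)": ":wink:",
}

_USER_TAG_RE = re.compile(r"(?<!\w)@\w+")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.-]+\b")
# tokens: emoticon codes (:smile:), words incl. accents/hyphens; apostrophes split
_TOKEN_RE = re.compile(r":[a-z]+:|[^\W\d_][\w-]*|\d+[\w-]*", re.UNICODE)
_ELISION_RE = re.compile(r"^([cdjlmnst]|qu|jusqu|lorsqu|puisqu|quoiqu)['’](.+)$",
                         re.IGNORECASE)


def tokenize(text: str) -> list[str]:
    """Unicode word tokenizer with French elision splitting (l'onco -> l, onco).

    Emoticon codes of the form ``:word:`` survive as single tokens so the
    pipeline is idempotent.
    """
    pieces: list[str] = []
    for chunk in text.split():
        m = _ELISION_RE.match(chunk)
        if m:
            pieces.append(m.group(1))
            chunk = m.group(2)
        pieces.extend(_TOKEN_RE.findall(chunk))
    return pieces


def detokenize(tokens: list[Token] | list[str]) -> str:
    parts = [t.lemma if isinstance(t, Token) else t for t in tokens]
    return " ".join(parts)


def preprocess_document(
    text: str,
    config: PreprocessConfig | None = None,
    lexicons: LexiconSet | None = None,
    lemmatizer: Lemmatizer | None = None,
    speller: Callable[[str], str] | None = None,
) -> list[Token]:
    """Apply the nine-step normalization to one message; empty input -> []."""
    config = config or PreprocessConfig()
    lexicons = lexicons or LexiconSet()
    lemmatizer = lemmatizer or DictionaryLemmatizer()
    if speller is None:
        speller = DictionarySpeller(lexicons.spelling_dictionary)
    enabled = set(config.steps)

    # -- character-level steps on the raw string ---------------------------
    if "user_tags" in enabled:
        text = _USER_TAG_RE.sub(" ", text)
    if "links" in enabled:
        link = f" {config.link_token} " if config.link_mode == "replace" else " "
        mail = f" {config.mail_token} " if config.link_mode == "replace" else " "
        text = _URL_RE.sub(link, text)
        text = _EMAIL_RE.sub(mail, text)
        if config.emoticon_coding:
            for emo, code in EMOTICON_TABLE.items():
                text = text.replace(emo, f" {code} ")

    surfaces = tokenize(text)

    # -- token-level steps -------------------------------------------------
    if "slang" in enabled:
        slang = {s.lower() for s in lexicons.slang}
        surfaces = [s for s in surfaces if s.lower() not in slang]

    if "lemmatize" in enabled:
        tokens = [Token(s, *lemmatizer(s)) for s in surfaces]
    else:
        tokens = [Token(s, s) for s in surfaces]

    if "lowercase" in enabled:
        tokens = [Token(t.surface, t.lemma.lower(), t.pos) for t in tokens]

    if "stopwords" in enabled:
        stop = {s.lower() for s in lexicons.stopwords}
        tokens = [t for t in tokens if t.lemma not in stop]

    if "lay_terms" in enabled:
        lay = lexicons.lay_to_medical
        tokens = [Token(t.surface, lay.get(t.lemma, t.lemma), t.pos) for t in tokens]

    if "spelling" in enabled:
        tokens = [Token(t.surface, speller(t.lemma), t.pos) for t in tokens]

    if "pseudonyms" in enabled:
        pseud = {p.lower() for p in lexicons.pseudonyms}
        tokens = [t for t in tokens if t.lemma not in pseud]

    return tokens


class TextPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`preprocess_document`.

    ``transform`` maps an iterable of raw strings to a list of lemma-token
    lists, so the preprocessor slots into sklearn pipelines ahead of
    :class:`~qoltopics.vocabulary.VocabularyBuilder`.
    """

    def __init__(self, config: PreprocessConfig | None = None,
                 lexicons: LexiconSet | None = None,
                 lemmatizer: Lemmatizer | None = None,
                 speller: Callable[[str], str] | None = None):
        self.config = config
        self.lexicons = lexicons
        self.lemmatizer = lemmatizer
        self.speller = speller

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # raw text in, no feature matrix
        return self

    def transform(self, X) -> list[list[Token]]:
        return [preprocess_document(text, self.config, self.lexicons,
                                    self.lemmatizer, self.speller)
                for text in X]
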