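"""Synthetic data with known ground truth for every pipeline stage.

The corpus generator follows the LDA generative model exactly: topic-word
distributions phi_t ~ Dirichlet(beta_gen), per-document topic weights
theta_d ~ Dirichlet(alpha0/K), then per position a topic and a term.
``beta_gen`` defaults to 0.01 — topics need to be well separated for
recovery experiments to be meaningful — while fitting typically uses the
smoother beta = 0.1. Document lengths are Poisson(mean 30) truncated at 1
(patient messages have no reported length distribution; 30 retained terms
per message is a plausible forum-post scale). Synthetic users and threads
are assigned round-robin so corpus summary statistics are testable.

The questionnaire generator draws each item's few words (questionnaire
items are short, under 5 words) from a chosen topic's top terms, recording
the item -> topic label; excluding topics from the questionnaire creates
ground-truth "emerging" topics.

The noisy-text generator inverts the normalization pipeline: it wraps clean
token lists in user tags, URLs, emails, slang, lay-term swaps, pseudonyms
and random casing such that preprocessing recovers the clean tokens (plus
the "link"/"mail" marker tokens where a URL or email was injected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LexiconSet, Questionnaire, QuestionnaireItem, RawMessage
from .vocabulary import DocTermCorpus, Vocabulary


@dataclass
class GeneratorConfig:
    K: int = 5
    V: int = 200
    D: int = 500
    doc_length: int | None = None      # fixed l_d; None -> Poisson(mean_length)
    mean_length: float = 30.0
    alpha0: float = 10.0
    beta_gen: float = 0.01
    seed: int = 0
    n_users: int | None = None         # round-robin; defaults to max(1, D // 25)
    n_threads: int | None = None       # defaults to max(1, D // 10)

    def __post_init__(self) -> None:
        if self.K < 1 or self.V < 1 or self.D < 0:
            raise ValueError("K, V must be >= 1 and D >= 0")
        if self.alpha0 <= 0 or self.beta_gen <= 0:
            raise ValueError("alpha0 and beta_gen must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def alpha(self) -> float:
        return self.alpha0 / self.K


@dataclass
class SyntheticTruth:
    phi: np.ndarray                    # (K, V)
    theta: np.ndarray                  # (D, K)
    assignments: list[np.ndarray]      # t_dj per document
    item_labels: dict[int, int] = field(default_factory=dict)

    @property
    def dominant_topics(self) -> np.ndarray:
        return np.argmax(self.theta, axis=1)


def _term_name(i: int) -> str:
    return f"med{i:04d}"


def generate_corpus(cfg: GeneratorConfig
                    ) -> tuple[DocTermCorpus, SyntheticTruth]:
    """Sample a corpus from the LDA generative model; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    phi = rng.dirichlet(np.full(cfg.V, cfg.beta_gen), size=cfg.K)
    theta = rng.dirichlet(np.full(cfg.K, cfg.alpha), size=cfg.D) \
        if cfg.D else np.zeros((0, cfg.K))

    docs: list[np.ndarray] = []
    assignments: list[np.ndarray] = []
    for d in range(cfg.D):
        if cfg.doc_length is not None:
            l_d = cfg.doc_length
        else:
            l_d = max(1, int(rng.poisson(cfg.mean_length)))
        z = rng.choice(cfg.K, size=l_d, p=theta[d])
        w = np.empty(l_d, dtype=np.int64)
        for t in range(cfg.K):
            mask = z == t
            if mask.any():
                w[mask] = rng.choice(cfg.V, size=int(mask.sum()), p=phi[t])
        docs.append(w)
        assignments.append(z.astype(np.int64))

    vocab = Vocabulary(scenario="MED", terms=[_term_name(i) for i in range(cfg.V)])
    corpus = DocTermCorpus(docs=docs, vocabulary=vocab)
    return corpus, SyntheticTruth(phi=phi, theta=theta, assignments=assignments)


def corpus_to_messages(corpus: DocTermCorpus, cfg: GeneratorConfig
                       ) -> list[RawMessage]:
    """Render a term-id corpus as raw messages with round-robin users/threads."""
    n_users = cfg.n_users or max(1, cfg.D // 25)
    n_threads = cfg.n_threads or max(1, cfg.D // 10)
    msgs = []
    for d, ids in enumerate(corpus.docs):
        text = " ".join(corpus.vocabulary.terms[int(i)] for i in ids)
        msgs.append(RawMessage(
            message_id=f"m{d:06d}",
            thread_id=f"t{d % n_threads:05d}",
            user_id=f"u{d % n_users:05d}",
            date="",
            text=text,
        ))
    return msgs


def stub_lexicons(vocabulary: Vocabulary) -> LexiconSet:
    """A lexicon set whose MED list is exactly the synthetic vocabulary."""
    return LexiconSet(medical_terms=set(vocabulary.terms))


def generate_questionnaire(
    truth: SyntheticTruth,
    vocabulary: Vocabulary,
    topics: list[int] | None = None,
    items_per_topic: int = 1,
    words_per_item: int = 3,
    noise_word_prob: float = 0.0,
    top_pool: int = 20,
    seed: int = 0,
    instrument_name: str = "SYNTH-QLQ",
) -> tuple[Questionnaire, dict[int, int]]:
    """Build short items from topics' top terms, recording item -> topic labels.

    Each item holds ``words_per_item`` distinct terms (allowed: 2-4, matching
    the short-sentence regime of real questionnaire items) sampled by phi
    weight from its topic's ``top_pool`` highest-probability terms, plus at
    most one uniform noise term with probability ``noise_word_prob``.
    """
    if not 2 <= words_per_item <= 4:
        raise ValueError("words_per_item must be in {2, 3, 4}")
    K, V = truth.phi.shape
    topics = list(range(K)) if topics is None else list(topics)
    if any(t < 0 or t >= K for t in topics):
        raise ValueError("requested topic outside the generated model")
    rng = np.random.default_rng(seed)

    items: list[QuestionnaireItem] = []
    labels: dict[int, int] = {}
    number = 1
    for t in topics:
        pool = np.argsort(-truth.phi[t], kind="stable")[:top_pool]
        if words_per_item > len(pool):
            raise ValueError("words_per_item exceeds the top-word pool")
        pool_w = truth.phi[t][pool]
        pool_w = pool_w / pool_w.sum()
        for _ in range(items_per_topic):
            chosen = rng.choice(pool, size=words_per_item, replace=False,
                                p=pool_w)
            words = [vocabulary.terms[int(i)] for i in chosen]
            if rng.random() < noise_word_prob:
                words.append(vocabulary.terms[int(rng.integers(0, V))])
            items.append(QuestionnaireItem(number, f"scale-{t}", " ".join(words)))
            labels[number] = t
            number += 1
    return Questionnaire(instrument_name, tuple(items)), labels


@dataclass
class NoiseSpec:
    """Which corruptions to inject around a clean token list."""

    user_tags: bool = True
    urls: bool = False          # each injected URL adds a "link" token
    emails: bool = False        # each injected email adds a "mail" token
    slang: bool = True
    lay_swaps: bool = True      # replace canonical terms by lay variants
    pseudonyms: bool = True
    random_case: bool = True
    n_injections: int = 2

    slang_pool: tuple[str, ...] = ("lol", "mdr", "xD")
    pseudonym_pool: tuple[str, ...] = ("rose75", "espoir31")
    tag_pool: tuple[str, ...] = ("@marie", "@paul")


def noise_lexicons(spec: NoiseSpec, lay_to_medical: dict[str, str]
                   ) -> LexiconSet:
    """The lexicon set that undoes a :class:`NoiseSpec`'s corruptions."""
    return LexiconSet(
        slang=set(spec.slang_pool),
        pseudonyms=set(spec.pseudonym_pool),
        lay_to_medical=dict(lay_to_medical),
    )


def generate_noisy_text(
    clean_tokens: list[str],
    spec: NoiseSpec,
    lay_to_medical: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[str, list[str]]:
    """Corrupt a clean token list into raw social-media-style text.

    Returns (raw text, expected tokens): preprocessing the text with
    :func:`noise_lexicons` yields exactly the expected list — the clean
    tokens, with "link"/"mail" markers inserted where a URL or email was
    injected. Tags, slang, pseudonyms and case noise vanish; lay swaps are
    undone by the substitution lexicon.
    """
    rng = np.random.default_rng(seed)
    lay_to_medical = lay_to_medical or {}
    medical_to_lay: dict[str, list[str]] = {}
    for lay, med in lay_to_medical.items():
        medical_to_lay.setdefault(med, []).append(lay)

    pieces: list[str] = []
    for tok in clean_tokens:
        out = tok
        if spec.lay_swaps and tok in medical_to_lay and rng.random() < 0.5:
            out = medical_to_lay[tok][int(rng.integers(0, len(medical_to_lay[tok])))]
        if spec.random_case and rng.random() < 0.3:
            out = out.upper() if rng.random() < 0.5 else out.capitalize()
        pieces.append(out)

    # vanishing injections carry no expected token; link/mail ones do
    injections: list[tuple[str, str | None]] = []
    for _ in range(spec.n_injections):
        kinds = []
        if spec.user_tags:
            kinds.append("tag")
        if spec.slang:
            kinds.append("slang")
        if spec.pseudonyms:
            kinds.append("pseud")
        if spec.urls:
            kinds.append("url")
        if spec.emails:
            kinds.append("mail")
        if not kinds:
            break
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind == "tag":
            injections.append((spec.tag_pool[int(rng.integers(0, len(spec.tag_pool)))], None))
        elif kind == "slang":
            injections.append((spec.slang_pool[int(rng.integers(0, len(spec.slang_pool)))], None))
        elif kind == "pseud":
            injections.append((spec.pseudonym_pool[int(rng.integers(0, len(spec.pseudonym_pool)))], None))
        elif kind == "url":
            injections.append((f"http://ex{int(rng.integers(0, 99))}.fr/page", "link"))
        else:
            injections.append((f"user{int(rng.integers(0, 99))}@mail.fr", "mail"))

    # track survivor markers alongside pieces so expected order stays aligned
    tagged: list[tuple[str, str | None]] = list(zip(pieces, clean_tokens))
    for piece, marker in injections:
        pos = int(rng.integers(0, len(tagged) + 1))
        tagged.insert(pos, (piece, marker))

    text = " ".join(p for p, _ in tagged)
    expected = [m for _, m in tagged if m is not None]
    return text, expected
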