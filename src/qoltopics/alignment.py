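"""Aligning LDA topics with quality-of-life questionnaire items.

Each topic is summarized by its top-n terms (default n = 20, the number of
keywords presented to the expert) with probabilities renormalized to sum 1;
each questionnaire item by a uniform weight vector over its preprocessed
tokens (items are short — typically under 5 words). The similarity between
topic and item is a probability-weighted Jaccard coefficient; the best topic
per item is the argmax, and an expert annotation table turns best-topic
picks into a precision figure and an emerging-topic report (topics that no
item validates — patient concerns the questionnaires do not cover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationTable, LexiconSet, Questionnaire
from .lda import GibbsLDA, dominant_topic_counts, top_words
from .preprocess import PreprocessConfig, preprocess_document


@dataclass(frozen=True)
class TopicProfile:
    """Top-n term weights of one topic, renormalized to sum 1."""

    topic_id: int
    weights: dict[str, float]

    @classmethod
    def from_model(cls, model: GibbsLDA, topic_id: int,
                   top_n: int = 20) -> "TopicProfile":
        n = min(top_n, model.components_.shape[1])
        pairs = top_words(model, topic_id, n=n)
        total = sum(p for _, p in pairs)
        return cls(topic_id, {str(t): p / total for t, p in pairs})


@dataclass(frozen=True)
class ItemProfile:
    """Uniform weights over an item's preprocessed tokens."""

    item_number: int
    weights: dict[str, float]

    @classmethod
    def from_tokens(cls, item_number: int, tokens: list[str]) -> "ItemProfile":
        support = sorted(set(tokens))
        if not support:
            raise ValueError(f"item {item_number}: no tokens after preprocessing")
        w = 1.0 / len(support)
        return cls(item_number, {t: w for t in support})


def weighted_jaccard(x: dict[str, float], y: dict[str, float],
                     variant: str = "minmax") -> float:
    """Probability-weighted Jaccard similarity between two weight vectors.

    ``minmax`` (default): Σ_w min(x_w, y_w) / Σ_w max(x_w, y_w) — symmetric,
    in [0, 1], 1 iff x == y, 0 iff the supports are disjoint; reduces to the
    plain Jaccard of supports when both vectors are uniform on their
    supports. ``overlap``: Σ_{w ∈ X∩Y} x_w / |X ∪ Y| (asymmetric; scores an
    item's coverage by topic probability mass).
    """
    if not x or not y:
        raise ValueError("weighted_jaccard requires nonempty supports")
    if variant == "minmax":
        keys = set(x) | set(y)
        mins = sum(min(x.get(k, 0.0), y.get(k, 0.0)) for k in keys)
        maxs = sum(max(x.get(k, 0.0), y.get(k, 0.0)) for k in keys)
        return mins / maxs
    if variant == "overlap":
        inter = set(x) & set(y)
        union = set(x) | set(y)
        return sum(x[k] for k in inter) / len(union)
    raise ValueError(f"unknown variant {variant!r}; use 'minmax' or 'overlap'")


@dataclass
class AlignmentRow:
    item_number: int
    best_topic_id: int
    score: float
    all_scores: np.ndarray  # length K
    validated: bool | None = None


@dataclass
class AlignmentResult:
    rows: list[AlignmentRow]
    skipped_items: list[int] = field(default_factory=list)

    def best_topic(self, item_number: int) -> int:
        for r in self.rows:
            if r.item_number == item_number:
                return r.best_topic_id
        raise KeyError(item_number)


def align_items(
    model: GibbsLDA,
    questionnaire: Questionnaire,
    config: PreprocessConfig | None = None,
    lexicons: LexiconSet | None = None,
    lemmatizer=None,
    top_n: int = 20,
    variant: str = "minmax",
) -> AlignmentResult:
    """Score every item against every topic; keep the highest-scoring topic.

    Items are preprocessed with the identical pipeline as messages (including
    lay-term substitution) so both sides share one vocabulary. Items that
    preprocess to no tokens are flagged in ``skipped_items``. Ties on the
    best score go to the lowest topic id. The full K-vector of scores is
    retained per item for audit.
    """
    if len(questionnaire) == 0:
        raise ValueError("questionnaire has no items")
    K = model.n_topics
    topics = [TopicProfile.from_model(model, t, top_n=top_n) for t in range(K)]

    rows: list[AlignmentRow] = []
    skipped: list[int] = []
    for item in questionnaire.items:
        tokens = [t.lemma for t in preprocess_document(
            item.text, config, lexicons, lemmatizer)]
        if not tokens:
            skipped.append(item.item_number)
            continue
        profile = ItemProfile.from_tokens(item.item_number, tokens)
        scores = np.array([weighted_jaccard(tp.weights, profile.weights, variant)
                           for tp in topics])
        best = int(np.argmax(scores))  # argmax takes the lowest index on ties
        rows.append(AlignmentRow(item.item_number, best, float(scores[best]),
                                 scores))
    return AlignmentResult(rows=rows, skipped_items=skipped)


def evaluate_precision(alignment: AlignmentResult,
                       annotations: AnnotationTable
                       ) -> tuple[int, int, int]:
    """(n_validated, n_invalidated, precision%) against expert annotations.

    precision = 100 * validated / (validated + invalidated), rounded to the
    nearest whole percent. Every aligned (item, best topic) pair must be
    annotated; missing pairs raise with the offending item numbers.
    """
    missing = [r.item_number for r in alignment.rows
               if annotations.lookup(r.item_number, r.best_topic_id) is None]
    if missing:
        raise ValueError(f"items without an annotation for their best topic: "
                         f"{missing}")
    n_val = sum(bool(annotations.lookup(r.item_number, r.best_topic_id))
                for r in alignment.rows)
    n_inv = len(alignment.rows) - n_val
    total = n_val + n_inv
    precision = int(round(100.0 * n_val / total)) if total else 0
    return n_val, n_inv, precision


@dataclass
class EmergingTopicReport:
    """Topics validated for no item, with their share of the corpus."""

    topics: list[tuple[int, int, float]]  # (topic_id, doc count, percent)

    @property
    def topic_ids(self) -> list[int]:
        return [t for t, _, _ in self.topics]


def emerging_topics(alignment: AlignmentResult,
                    annotations: AnnotationTable,
                    model: GibbsLDA) -> EmergingTopicReport:
    """Topics that are the *validated* best topic of no questionnaire item.

    These are the candidate emerging concerns: discussed by patients
    (non-zero document share) yet absent from the instruments. Reported with
    each topic's dominant-document count and percent of the corpus.
    """
    validated = {r.best_topic_id for r in alignment.rows
                 if annotations.lookup(r.item_number, r.best_topic_id)}
    counts = dominant_topic_counts(model)
    out = [(t, counts[t][0], counts[t][1])
           for t in range(model.n_topics) if t not in validated]
    return EmergingTopicReport(topics=out)


def match_topics_across_corpora(
    model_a: GibbsLDA,
    model_b: GibbsLDA,
    top_n: int = 20,
    threshold: float = 0.3,
    variant: str = "minmax",
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing of topics between two fitted models.

    Profiles live on the union vocabulary (terms absent from one model get
    weight 0). Pairs are taken highest-similarity-first; pairs scoring below
    ``threshold`` are dropped. Returns (topic_a, topic_b, score) triples.
    """
    prof_a = [TopicProfile.from_model(model_a, t, top_n=top_n)
              for t in range(model_a.n_topics)]
    prof_b = [TopicProfile.from_model(model_b, t, top_n=top_n)
              for t in range(model_b.n_topics)]
    scored = []
    for pa in prof_a:
        for pb in prof_b:
            if set(pa.weights) & set(pb.weights):
                s = weighted_jaccard(pa.weights, pb.weights, variant)
            else:
                s = 0.0
            scored.append((s, pa.topic_id, pb.topic_id))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for s, a, b in scored:
        if s < threshold:
            break
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        pairs.append((a, b, s))
    return pairs
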