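"""Latent Dirichlet allocation with collapsed Gibbs sampling.

The model: each of K topics is a distribution phi_t over the vocabulary;
each document d mixes topics with weights theta_d; every token position j in
document d carries a latent topic t_dj ~ Categorical(theta_d) and a term
w_dj ~ Categorical(phi_{t_dj}). Priors are symmetric Dirichlets with
concentration alpha = alpha0 / K on theta (so the effective prior mass is
held constant across K) and beta on phi. Defaults alpha0 = 10, beta = 0.1,
K = 20 — the regime in which per-message topic distributions stay peaked
enough to index messages by a small number of topics.

Inference is the collapsed Gibbs sampler (phi and theta integrated out):
each position is resampled from

    P(z = t | rest) ∝ (n_dt + alpha) (n_tw + beta) / (n_t + V beta)

with n_* the count tables excluding the current position. Point estimates
average the count tables over post-burn-in sweeps:

    phi_tw  = (<n_tw> + beta) / (<n_t> + V beta)
    theta_dt = (<n_dt> + alpha) / (l_d + K alpha)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._sampler import gibbs_run
from .vocabulary import DocTermCorpus


@dataclass(frozen=True)
class Hyperparameters:
    """Bundle of sampler settings; ``alpha`` is derived, never set directly."""

    K: int = 20
    alpha0: float = 10.0
    beta: float = 0.1
    n_iterations: int = 1000
    burn_in: int = 200
    seed: int = 0

    @property
    def alpha(self) -> float:
        return self.alpha0 / self.K

    def __post_init__(self) -> None:
        if self.K <= 1:
            raise ValueError("K must be > 1")
        if self.alpha0 <= 0 or self.beta <= 0:
            raise ValueError("alpha0 and beta must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")


def _flatten(X) -> tuple[np.ndarray, np.ndarray, int, int, list[str] | None]:
    """Accept a DocTermCorpus, a list of term-id sequences, or a count matrix.

    Returns (words, doc_of, n_docs, n_terms, vocabulary). A count matrix is
    expanded to positions in term-id order within each document, which is the
    canonical order under the bag-of-words assumption.
    """
    vocabulary = None
    if isinstance(X, DocTermCorpus):
        vocabulary = list(X.vocabulary.terms)
        docs = X.docs
        V = len(X.vocabulary)
    elif isinstance(X, (list, tuple)) and all(
            np.ndim(d) == 1 or isinstance(d, (list, tuple)) for d in X):
        docs = [np.asarray(d, dtype=np.int64) for d in X]
        V = int(max((d.max() for d in docs if len(d)), default=-1)) + 1
    else:
        M = np.asarray(X)
        if M.ndim != 2:
            raise ValueError("X must be a DocTermCorpus, a list of term-id "
                             "sequences, or a 2D count matrix")
        if M.size and (M < 0).any():
            raise ValueError("count matrix entries must be nonnegative")
        V = M.shape[1]
        docs = [np.repeat(np.arange(V, dtype=np.int64), M[d].astype(np.int64))
                for d in range(M.shape[0])]

    for d, ids in enumerate(docs):
        if len(ids) and (ids.min() < 0 or ids.max() >= V):
            raise ValueError(f"document {d}: term id out of range [0, {V})")
    words = np.concatenate(docs) if docs else np.empty(0, dtype=np.int64)
    doc_of = np.concatenate(
        [np.full(len(ids), d, dtype=np.int64) for d, ids in enumerate(docs)]
    ) if docs else np.empty(0, dtype=np.int64)
    return words.astype(np.int64), doc_of, len(docs), V, vocabulary


class GibbsLDA(BaseEstimator):
    """LDA fitted by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int, default 20
        Number of topics K; must be > 1 (set ``allow_single_topic`` to relax,
        for closed-form checks only).
    alpha0 : float, default 10.0
        Total document-topic prior mass; the per-topic concentration is
        alpha = alpha0 / n_topics.
    beta : float, default 0.1
        Topic-word Dirichlet concentration.
    n_iter, burn_in : int
        Total sweeps and discarded initial sweeps; estimates average the
        count tables over the remaining ``n_iter - burn_in`` sweeps.
    random_state : int or None
        Seed for the sampler RNG; identical seeds give bitwise-identical
        chains. None draws a seed from numpy's global generator.

    Attributes
    ----------
    components_ : ndarray (n_topics, n_terms)
        Topic-word probabilities phi (rows sum to 1).
    theta_ : ndarray (n_docs, n_topics)
        Document-topic probabilities (rows sum to 1).
    assignments_ : list of int64 arrays
        Final-sweep topic assignment per position, per document.
    vocabulary_ : list of str or None
        Term strings when fitted on a DocTermCorpus.
    """

    def __init__(self, n_topics: int = 20, alpha0: float = 10.0,
                 beta: float = 0.1, n_iter: int = 1000, burn_in: int = 200,
                 random_state: int | None = None,
                 allow_single_topic: bool = False):
        self.n_topics = n_topics
        self.alpha0 = alpha0
        self.beta = beta
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.random_state = random_state
        self.allow_single_topic = allow_single_topic

    @property
    def alpha_(self) -> float:
        return self.alpha0 / self.n_topics

    def fit(self, X, y=None):
        if self.n_topics < 1 or (self.n_topics == 1 and not self.allow_single_topic):
            raise ValueError("n_topics must be > 1")
        if self.alpha0 <= 0 or self.beta <= 0:
            raise ValueError("alpha0 and beta must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")

        words, doc_of, D, V, vocabulary = _flatten(X)
        if D == 0:
            raise ValueError("corpus is empty")
        if V == 0 or len(words) == 0:
            raise ValueError("corpus has no retained tokens (empty vocabulary)")

        seed = self.random_state
        if seed is None:
            seed = int(np.random.default_rng().integers(0, 2**31))
        K = self.n_topics
        alpha = self.alpha_

        z, sum_ndt, sum_ntw, sum_nt, retained = gibbs_run(
            words, doc_of, D, K, V, float(alpha), float(self.beta),
            int(self.n_iter), int(self.burn_in), int(seed))

        avg_ndt = sum_ndt / retained
        avg_ntw = sum_ntw / retained
        avg_nt = sum_nt / retained
        lengths = np.bincount(doc_of, minlength=D).astype(float)

        self.components_ = (avg_ntw + self.beta) / \
            (avg_nt[:, None] + V * self.beta)
        self.theta_ = (avg_ndt + alpha) / (lengths[:, None] + K * alpha)
        splits = np.cumsum(np.bincount(doc_of, minlength=D))[:-1]
        self.assignments_ = np.split(z, splits)
        self.vocabulary_ = vocabulary
        self.n_features_in_ = V
        self.seed_ = seed
        self.n_retained_ = int(retained)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).theta_

    def transform(self, X, n_em_iter: int = 50) -> np.ndarray:
        """Fold in unseen documents: EM for theta under fixed components_.

        q(t | w) ∝ theta_dt phi_tw; theta_dt = (Σ_j q_j(t) + alpha)/(l_d + K alpha).
        Deterministic; matches the training estimator in the l_d -> ∞ limit.
        """
        check_is_fitted(self, "components_")
        words, doc_of, D, V, _ = _flatten(X)
        if V > self.components_.shape[1]:
            raise ValueError("document term ids exceed the fitted vocabulary")
        K = self.n_topics
        alpha = self.alpha_
        theta = np.full((D, K), 1.0 / K)
        phi = self.components_
        lengths = np.bincount(doc_of, minlength=D).astype(float)
        for _ in range(n_em_iter):
            q = theta[doc_of] * phi[:, words].T  # (N, K)
            q /= q.sum(axis=1, keepdims=True)
            acc = np.zeros((D, K))
            np.add.at(acc, doc_of, q)
            theta = (acc + alpha) / (lengths[:, None] + K * alpha)
        return theta


def top_words(model: GibbsLDA, topic_id: int, n: int = 20
              ) -> list[tuple[str | int, float]]:
    """Top-n terms of a topic by phi, ties broken by vocabulary index.

    Terms are the vocabulary strings when available, else the term ids.
    """
    check_is_fitted(model, "components_")
    K, V = model.components_.shape
    if not 0 <= topic_id < K:
        raise ValueError(f"topic_id must be in [0, {K}), got {topic_id}")
    if not 1 <= n <= V:
        raise ValueError(f"n must be in [1, {V}], got {n}")
    row = model.components_[topic_id]
    order = np.argsort(-row, kind="stable")[:n]
    names = model.vocabulary_
    return [(names[i] if names is not None else int(i), float(row[i]))
            for i in order]


def dominant_topic_counts(model: GibbsLDA) -> list[tuple[int, float]]:
    """Per topic: (document count, percent of corpus) by dominant topic.

    A document's dominant topic is argmax_t theta_dt (ties -> lowest topic
    id); percents are 100*count/D rounded to 2 decimals.
    """
    check_is_fitted(model, "theta_")
    D = model.theta_.shape[0]
    dominant = np.argmax(model.theta_, axis=1)
    counts = np.bincount(dominant, minlength=model.n_topics)
    return [(int(c), round(100.0 * c / D, 2)) for c in counts]


def perplexity(model: GibbsLDA, corpus) -> float:
    """exp(- mean per-token log-likelihood) under the point estimates.

    Uses the corpus' own theta when scoring the training corpus is intended;
    here theta is folded in via :meth:`GibbsLDA.transform` unless the corpus
    is exactly the training shape — callers wanting training perplexity
    should pass the training corpus, for which ``theta_`` applies.
    """
    check_is_fitted(model, "components_")
    phi = model.components_
    V = phi.shape[1]

    if isinstance(corpus, DocTermCorpus) and model.vocabulary_ is not None \
            and list(corpus.vocabulary.terms) != list(model.vocabulary_):
        # re-map term ids through the model vocabulary, by term string
        idx = {t: i for i, t in enumerate(model.vocabulary_)}
        docs = []
        for ids in corpus.docs:
            mapped = []
            for i in ids:
                term = corpus.vocabulary.terms[int(i)]
                if term not in idx:
                    raise ValueError(f"out-of-vocabulary term: {term!r}")
                mapped.append(idx[term])
            docs.append(np.asarray(mapped, dtype=np.int64))
        words, doc_of, D, _, _ = _flatten(docs)
    else:
        words, doc_of, D, Vx, _ = _flatten(corpus)
        if len(words) and words.max() >= V:
            raise ValueError(f"out-of-vocabulary term id: {int(words.max())}")

    if len(words) == 0:
        raise ValueError("cannot compute perplexity of an empty corpus")

    if hasattr(model, "theta_") and model.theta_.shape[0] == D:
        theta = model.theta_
    else:
        theta = model.transform([words[doc_of == d] for d in range(D)])

    ll = np.log((theta[doc_of] * phi[:, words].T).sum(axis=1))
    return float(np.exp(-ll.sum() / len(words)))
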