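import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qoltopics import (AnnotationRow, AnnotationTable, GibbsLDA,
                       Questionnaire, QuestionnaireItem, align_items,
                       emerging_topics, evaluate_precision,
                       match_topics_across_corpora, weighted_jaccard)
from qoltopics.alignment import (AlignmentResult, AlignmentRow, ItemProfile,
                                 TopicProfile)


def make_model(phi, theta=None, vocab=None):
    model = GibbsLDA(n_topics=phi.shape[0])
    model.components_ = np.asarray(phi, dtype=float)
    model.theta_ = (np.asarray(theta, dtype=float) if theta is not None
                    else np.full((4, phi.shape[0]), 1.0 / phi.shape[0]))
    model.vocabulary_ = vocab
    model.n_features_in_ = phi.shape[1]
    return model


# ---------------------------------------------------------------------------
# weighted Jaccard
# ---------------------------------------------------------------------------

def test_weighted_jaccard_hand_computed_example():
    x = {"a": 0.5, "b": 0.3, "c": 0.2}
    y = {"a": 0.5, "b": 0.5}
    # min-sum 0.5+0.3+0 = 0.8; max-sum 0.5+0.5+0.2 = 1.2
    assert weighted_jaccard(x, y) == pytest.approx(0.8 / 1.2)


def test_weighted_jaccard_identity_disjoint_and_errors():
    x = {"a": 0.6, "b": 0.4}
    assert weighted_jaccard(x, dict(x)) == pytest.approx(1.0)
    assert weighted_jaccard(x, {"c": 1.0}) == 0.0
    with pytest.raises(ValueError):
        weighted_jaccard({}, x)
    with pytest.raises(ValueError):
        weighted_jaccard(x, x, variant="nope")


def test_overlap_variant():
    x = {"a": 0.5, "b": 0.3, "c": 0.2}
    y = {"a": 1.0, "d": 0.0}
    # mass of {a} over |{a,b,c,d}|
    assert weighted_jaccard(x, y, variant="overlap") == pytest.approx(0.5 / 4)


@st.composite
def profiles(draw):
    keys = draw(st.lists(st.sampled_from("abcdefgh"), min_size=1,
                         max_size=6, unique=True))
    w = [draw(st.floats(0.01, 1.0)) for _ in keys]
    total = sum(w)
    return {k: v / total for k, v in zip(keys, w)}


@settings(max_examples=150, deadline=None, derandomize=True)
@given(profiles(), profiles())
def test_weighted_jaccard_axioms(x, y):
    s = weighted_jaccard(x, y)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(weighted_jaccard(y, x))  # symmetry
    if set(x) == set(y) and all(abs(x[k] - y[k]) < 1e-12 for k in x):
        assert s == pytest.approx(1.0)
    if not set(x) & set(y):
        assert s == 0.0


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=6),
       st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=6))
def test_uniform_weight_limit_is_set_jaccard(s1, s2):
    x = {k: 1.0 / len(s1) for k in s1}
    y = {k: 1.0 / len(s2) for k in s2}
    inter, union = len(s1 & s2), len(s1 | s2)
    # uniform min/max sums collapse to |∩| min(1/|A|,1/|B|) etc. only when
    # |A| == |B|; the general limit check is the equal-size case
    if len(s1) == len(s2):
        assert weighted_jaccard(x, y) == pytest.approx(inter / union)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(profiles(), st.sampled_from("abcdefgh"),
       st.floats(0.05, 0.5))
def test_adding_shared_term_never_decreases_similarity(y, term, mass):
    """Add a term from y's support to x (renormalized): similarity rises."""
    x = {"z1": 0.5, "z2": 0.5}
    if term not in y:
        y = dict(y)
        total = sum(y.values()) + 0.3
        y = {k: v / total for k, v in y.items()}
        y[term] = 0.3 / total
    before = weighted_jaccard(x, y)
    x2 = {k: v * (1 - mass) for k, v in x.items()}
    x2[term] = mass
    after = weighted_jaccard(x2, y)
    assert after >= before - 1e-12


# ---------------------------------------------------------------------------
# item alignment
# ---------------------------------------------------------------------------

def test_single_topic_sharing_word_is_selected():
    phi = np.array([[0.7, 0.2, 0.1], [0.1, 0.1, 0.8]])
    model = make_model(phi, vocab=["cancer", "douleur", "cheveu"])
    q = Questionnaire("Q", (QuestionnaireItem(1, "s", "cancer douleur"),))
    res = align_items(model, q)
    assert res.rows[0].best_topic_id == 0
    assert res.rows[0].score > 0
    assert res.rows[0].all_scores.shape == (2,)


def test_empty_questionnaire_errors():
    model = make_model(np.array([[0.5, 0.5], [0.5, 0.5]]), vocab=["a", "b"])
    with pytest.raises(ValueError):
        align_items(model, Questionnaire("Q", ()))


def test_items_reducing_to_nothing_are_flagged():
    from qoltopics import LexiconSet
    model = make_model(np.array([[1.0, 0.0], [0.0, 1.0]]), vocab=["a", "b"])
    q = Questionnaire("Q", (QuestionnaireItem(1, "s", "le la"),
                            QuestionnaireItem(2, "s", "a")))
    res = align_items(model, q, lexicons=LexiconSet(stopwords={"le", "la"}))
    assert res.skipped_items == [1]
    assert [r.item_number for r in res.rows] == [2]


def test_alignment_invariant_to_topic_relabeling():
    rng = np.random.default_rng(4)
    phi = rng.dirichlet(np.full(12, 0.05), size=4)
    vocab = [f"w{i}" for i in range(12)]
    model = make_model(phi, vocab=vocab)
    q = Questionnaire("Q", tuple(
        QuestionnaireItem(i + 1, "s",
                          " ".join(vocab[j] for j in
                                   np.argsort(-phi[i % 4])[:3]))
        for i in range(6)))
    res = align_items(model, q)

    perm = np.array([2, 0, 3, 1])
    model_p = make_model(phi[perm], vocab=vocab)
    res_p = align_items(model_p, q)
    inv = np.argsort(perm)
    for r, rp in zip(res.rows, res_p.rows):
        assert rp.best_topic_id == inv[r.best_topic_id]
        assert rp.score == pytest.approx(r.score)


# ---------------------------------------------------------------------------
# precision & emerging topics
# ---------------------------------------------------------------------------

def _alignment_of(n_items, topic=0):
    rows = [AlignmentRow(i + 1, topic, 0.5, np.array([0.5]))
            for i in range(n_items)]
    return AlignmentResult(rows=rows)


@pytest.mark.parametrize("n_val,n_inv,expected", [
    (39, 14, 74),   # published forum figure
    (36, 17, 68),   # published Facebook figure
    (0, 53, 0),
])
def test_precision_from_validation_counts(n_val, n_inv, expected):
    n = n_val + n_inv
    alignment = _alignment_of(n)
    table = AnnotationTable([AnnotationRow(i + 1, 0, i < n_val)
                             for i in range(n)])
    assert evaluate_precision(alignment, table) == (n_val, n_inv, expected)


def test_precision_missing_annotation_lists_items():
    alignment = _alignment_of(3)
    table = AnnotationTable([AnnotationRow(1, 0, True)])
    with pytest.raises(ValueError, match=r"\[2, 3\]"):
        evaluate_precision(alignment, table)


def test_emerging_topics_published_share_example():
    """Topic 8 validated for no item and owning 523/16,868 docs -> 3.10%."""
    K, D = 20, 16868
    theta = np.zeros((D, K))
    theta[:523, 7] = 1.0          # topic 8 in 1-based numbering
    theta[523:, 0] = 1.0
    model = make_model(np.full((K, 5), 0.2), theta=theta,
                       vocab=list("abcde"))
    rows = [AlignmentRow(i + 1, i % K, 0.5, np.zeros(K))
            for i in range(53)]
    ann = AnnotationTable([AnnotationRow(r.item_number, r.best_topic_id,
                                         r.best_topic_id != 7)
                           for r in rows])
    report = emerging_topics(AlignmentResult(rows=rows), ann, model)
    assert report.topic_ids == [7]
    assert report.topics[0][1] == 523
    assert report.topics[0][2] == pytest.approx(3.10, abs=0.005)


def test_every_topic_validated_gives_empty_report():
    K = 3
    model = make_model(np.full((K, 4), 0.25),
                       theta=np.full((6, K), 1 / K), vocab=list("abcd"))
    rows = [AlignmentRow(i + 1, i % K, 0.5, np.zeros(K)) for i in range(K)]
    ann = AnnotationTable([AnnotationRow(r.item_number, r.best_topic_id, True)
                           for r in rows])
    assert emerging_topics(AlignmentResult(rows=rows), ann, model).topics == []


# ---------------------------------------------------------------------------
# cross-corpus matching
# ---------------------------------------------------------------------------

def test_model_paired_with_itself_is_identity():
    rng = np.random.default_rng(8)
    phi = rng.dirichlet(np.full(30, 0.02), size=5)
    model = make_model(phi, vocab=[f"w{i}" for i in range(30)])
    pairs = match_topics_across_corpora(model, model)
    assert sorted((a, b) for a, b, _ in pairs) == [(t, t) for t in range(5)]
    assert all(s == pytest.approx(1.0) for _, _, s in pairs)


def test_disjoint_vocabularies_pair_nothing():
    phi = np.array([[0.6, 0.4]])
    a = make_model(np.vstack([phi, phi[::-1]]), vocab=["a", "b"])
    b = make_model(np.vstack([phi, phi[::-1]]), vocab=["c", "d"])
    assert match_topics_across_corpora(a, b) == []


def test_matching_recovers_pairs_across_seeds(small_synthetic):
    """Two fits of corpora drawn from the same phi pair up correctly."""
    from qoltopics import GeneratorConfig, generate_corpus
    cfg_a = GeneratorConfig(K=5, V=120, D=150, seed=21, beta_gen=0.01)
    corpus_a, truth = generate_corpus(cfg_a)
    # same phi, different documents: re-draw with another doc seed
    rng = np.random.default_rng(99)
    docs_b = []
    for d in range(150):
        theta = rng.dirichlet(np.full(5, cfg_a.alpha))
        z = rng.choice(5, size=30, p=theta)
        w = np.array([rng.choice(120, p=truth.phi[t]) for t in z])
        docs_b.append(w)
    from qoltopics.vocabulary import DocTermCorpus
    corpus_b = DocTermCorpus(docs=docs_b, vocabulary=corpus_a.vocabulary)

    fit_a = GibbsLDA(n_topics=5, n_iter=400, burn_in=150,
                     random_state=1).fit(corpus_a)
    fit_b = GibbsLDA(n_topics=5, n_iter=400, burn_in=150,
                     random_state=2).fit(corpus_b)
    pairs = match_topics_across_corpora(fit_a, fit_b)

    # ground-truth identity of each fitted topic by best overlap with true phi
    def truth_map(fit):
        overlap = np.minimum(fit.components_[:, None, :],
                             truth.phi[None, :, :]).sum(axis=2)
        return overlap.argmax(axis=1)
    map_a, map_b = truth_map(fit_a), truth_map(fit_b)
    correct = sum(map_a[a] == map_b[b] for a, b, _ in pairs)
    assert correct >= 4
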