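# Methods

## Model and inference

The core model is latent Dirichlet allocation over a corpus of D documents
(one social-media message = one document) on a vocabulary of V terms. Topic
t is a term distribution φ_t ~ Dirichlet(β·1_V); document d carries topic
weights θ_d ~ Dirichlet(α·1_K); position j of document d draws a topic
t_dj ~ Categorical(θ_d) and then a term w_dj ~ Categorical(φ_{t_dj}). The
bag-of-words assumption is deliberate: message order and syntax carry
little signal after the aggressive normalization that noisy patient text
requires.

Inference is collapsed Gibbs sampling: φ and θ are integrated out and each
position's topic is resampled from

    P(z_i = t | z_-i, w) ∝ (n_dt + α) (n_tw + β) / (n_t + Vβ)

with count tables excluding position i. Point estimates average the count
tables over the retained sweeps and plug them into the smoothed ratios
φ̂_tw = (⟨n_tw⟩+β)/(⟨n_t⟩+Vβ) and θ̂_dt = (⟨n_dt⟩+α)/(l_d+Kα). Averaging
counts from a single chain, without any identifiability correction during
sampling, is the standard practice for collapsed LDA; label switching is
handled only at evaluation time by greedy one-to-one topic matching on
maximal φ overlap. An empty document receives the prior mean θ̂ = 1/K.

### Parameters

| parameter | default | meaning |
|---|---|---|
| K | 20 | number of topics; must be > 1 (K = 1 only behind a test override, where the closed form applies) |
| α₀ | 10 | total document-topic prior mass; α = α₀/K keeps the effective prior comparable across K. α₀ = 50 is the classical recommendation but flattens per-message topic posteriors too much to index messages by a few topics; α₀ = 10 keeps them peaked while remaining stable |
| β | 0.1 | topic-word concentration for fitting |
| n_iter / burn_in | 1000 / 200 | total and discarded sweeps; estimates use the remaining 800 |
| random_state | — | chain seed; identical seeds give bitwise-identical runs |

Iteration counts are a package choice (no reference values exist); the
defaults give stable estimates at the corpus scales the test-suite uses,
and both are exposed.

### Determinism

The sweep kernel (numba) uses an in-package xorshift64* RNG seeded through
splitmix64, with a fixed draw order (documents in index order, positions
left to right). This makes runs bitwise reproducible for a fixed seed,
independent of platform, numpy version or thread count. A count matrix
passed to `fit` is expanded to positions in term-id order within each
document — canonical under exchangeability.

## Normalization pipeline

Nine steps in a fixed canonical order: (1) user-tag removal, (2)
hyperlink→"link" / email→"mail" replacement plus emoticon coding, (3) slang
removal, (4) lemmatization, (5) lowercasing, (6) stopword removal, (7)
lay-term substitution, (8) spelling correction, (9) pseudonym removal. Any
enabled subset must be a subsequence of this order. The order matters and
is tested: lowercasing precedes stopword removal, so capitalized stopwords
are caught; lay substitution operates on lowercased lemmas.

Design choices made where the procedure was genuinely open:

* Link handling is *replacement* by marker tokens (configurable deletion):
  the presence of a link or mail address is itself weak topical signal.
* Tokenization is unicode word boundaries with French elision splitting
  (l', d', j' … split off) and `:code:` emoticon tokens preserved, making
  the pipeline idempotent — re-running it on its own detokenized output is
  a no-op, a property enforced over randomized noisy fixtures.
* Lemmatization/POS tagging and spelling correction are pluggable
  callables. The defaults are dictionary lookups (identity lemma, POS
  `OTHER`, no correction when absent), sufficient wherever the dictionaries
  cover the corpus — always true for synthetic corpora. Real French
  morphology needs an external tagger plugged into the same interface.

Vocabulary scenarios: `MED` keeps only terms from the medical lexicon
(multi-word entries matched longest-first, left-to-right, non-overlapping);
`+NN`, `+V`, `+A` widen by POS class. Stopwords, slang, pseudonyms and
noise terms (always including *femme* and *temps*) never enter the
vocabulary.

## Topic–questionnaire alignment

A topic's profile is its top-n terms by φ̂ (n = 20, the number of keywords
an expert reviews), renormalized to sum 1; ties at the cutoff break by
vocabulary index. An item's profile is uniform over its preprocessed
tokens — items are short (typically under 5 words), so term weighting
within an item is not meaningful. Items run through the *identical*
pipeline as messages (including lay-term substitution) so both sides share
a vocabulary; items that preprocess to nothing are flagged and skipped,
not scored.

The default similarity is the min/max weighted Jaccard
Σ_w min(x_w,y_w)/Σ_w max(x_w,y_w): symmetric, bounded in [0,1], 1 iff the
profiles coincide, 0 iff their supports are disjoint, and reducing to the
set Jaccard when both profiles are uniform over equal-sized supports. An
alternative variant Σ_{w∈T∩Q} φ̂(w)/|T∪Q| is available behind the
`variant="overlap"` switch. The best topic per item is the similarity
argmax (ties → lowest topic id); no acceptance threshold is applied at this
stage — rejection is the annotator's call, recorded in the annotation
table. Precision is 100·validated/(validated+invalidated), rounded to the
nearest whole percent. Emerging topics are those that are the *validated*
best topic of no item, reported with their dominant-document count and
corpus share. Cross-corpus matching reuses the same similarity on the
union vocabulary, pairing greedily highest-first with a drop threshold
(default 0.3).

Matched-dimension rates over the published instrument tables use the floor
of the percentage (22/23 → 95, 20/23 → 86), matching the convention of the
published figures.

## Synthetic data: what it does and does not emulate

The generator draws corpora exactly from the LDA generative model with a
separate generation concentration `beta_gen` (default 0.01): recovery
experiments need well-separated topics, while fitting uses the smoother
β = 0.1. Document lengths are Poisson(30) truncated at 1 (or fixed);
synthetic users/threads are assigned round-robin so corpus summaries are
testable. Questionnaire items sample 2–4 distinct terms by φ weight from a
topic's top-20 pool, with an optional uniform noise word. The noisy-text
generator inverts the normalization pipeline (tags, URLs, emails, slang,
lay swaps, pseudonyms, random casing) such that preprocessing recovers the
clean tokens exactly, plus "link"/"mail" markers where a URL/email was
injected.

What passing these tests shows: the sampler, the alignment statistic and
the normalization rules are correct as algorithms. What it does not show:
performance on real patient text — synthetic corpora have no grammar, no
polysemy, no spelling-error distribution, no topic correlation, and their
"medical lexicon" covers the vocabulary by construction. Real-data
precision depends on expert annotation quality and on lexicon coverage,
neither of which is modeled.

## Numerical choices and degenerate inputs

* φ̂ and θ̂ rows are smoothed (all entries > 0) and sum to 1 within 1e-9.
* Ranking ties (top words, best topic, dominant topic) always break toward
  the lower index, making every report deterministic and byte-stable.
* Perplexity is exp(−mean per-token log θ̂φ̂); out-of-vocabulary terms are
  an error naming the term. Uniform φ rows give perplexity exactly V.
* Corpora that empty out after filtering warn (vocabulary construction) or
  raise (fitting); empty questionnaires and K ≤ 1 raise.
* Greedy topic matching is used instead of the Hungarian algorithm: at the
  K ≤ 20 scales involved both give identical pairings in practice and the
  greedy order (highest overlap first) is easier to audit.

## Known limitations

* Dominant-topic agreement with the generating θ's argmax is capped well
  below 100% whenever α = α₀/K is large enough to make θ draws flat: with
  K = 5, α = 2, l_d = 60, even the true realized token-topic counts agree
  with argmax θ_d only ~80% of the time, and the fitted model tracks the
  realized counts (~94% agreement), not θ. The package therefore reports
  this agreement as a measurement rather than guaranteeing a floor.
* The Gibbs-vs-enumeration oracle uses the pairwise same-topic posterior
  as its sharp check; the posterior mean of θ itself is 1/K by label
  symmetry and only validates calibration, not mixing.
* Perplexity is exposed as a diagnostic only; automatic selection of K is
  out of scope.
* The dictionary lemmatizer/speller defaults do no real morphology; the
  MED lexicon, drug and alternative-treatment lists are user-supplied
  files, not bundled resources.
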