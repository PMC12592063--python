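# Methods

This note documents the models, estimators, and numerical choices behind
`themetrace`, what the synthetic benchmark corpora do and do not emulate,
and the limitations a user should keep in mind.

## Data model and preprocessing

A corpus is a set of records (id, title, abstract, publication year).
Records without an abstract, or with an unparseable year, are excluded and
counted by reason; ingestion never silently drops a row.  Cleaning joins
title and abstract (title first), lowercases, splits on maximal runs of
non-alphanumeric characters, and removes stop words.  Design choices that
change results and are therefore fixed and documented:

- **Tokenizer.** Split on `[^a-z0-9]+`.  Pure-digit tokens are kept by
  default — numerals such as the "19" of "covid 19" carry topical signal —
  and can be dropped via `keep_numbers=False`.
- **Stop words.** A standard 149-word English list ships as package data;
  users can replace or extend it, and the active list is logged with a
  SHA-256 content hash so any run can be tied to the exact list it used.
- **No stemming or lemmatization.** Abstract-scale academic English gains
  little from stemming and loses term identity; there is no flag because
  there is no implementation — adding one would be a contract change.
- **Minimum document length.** Documents with fewer than 5 tokens after
  cleaning are flagged and excluded from model training; a near-empty
  bag-of-words row contributes noise, not signal.  Configurable.
- **Phases.** Four inclusive year ranges, non-overlapping and ordered
  (defaults 1995–2004, 2005–2013, 2014–2019, 2020–2024).  Documents outside
  every phase go to an explicit overflow bucket with a warning, so
  segmentation is always a partition.

## Word embeddings

Skip-gram with negative sampling, implemented in-package (numpy with a
numba-compiled inner loop).  Per (center, context) pair drawn from a
per-center dynamic window (uniform 1…window), the context's output vector
is pulled toward the center's input vector and `negative` noise words —
sampled from the unigram distribution raised to 3/4 — are pushed away;
plain SGD with a linear learning-rate decay from 0.025 to 1e-4.

Defaults: 5 negatives, 50 epochs, minimum word count 2.  Training is
sequential (single worker) and bit-reproducible from the seed; this is a
deliberate contract — the pipeline trades a little wall-clock time for
exact replicability of every downstream artifact.

Hyperparameters (dimension, window) are selected on a grid by **pair
coherence**: the unweighted mean cosine similarity over a user-supplied
list of word pairs that should be semantically related in the domain.
Pairs with an out-of-vocabulary member are skipped and counted, never
zero-scored — zero-scoring would conflate vocabulary coverage with
semantic quality; coverage is reported as its own column.  The shipped
default pair list covers the public-speaking-anxiety domain and is a
convenience only; coherence values are corpus-dependent and the list
should be replaced for any other corpus.  When the default pairs cover
none of the corpus vocabulary (synthetic corpora), the pipeline falls back
to the most frequent within-document co-occurring pairs.

## Topic model

- **Dictionary.** A word is retained iff it occurs in at least 3 documents
  and in at most 50% of them; both boundaries are inclusive ("in exactly
  half the documents" is kept).  Ids are assigned in sorted word order, so
  the dictionary is a pure function of the retained vocabulary.
- **LDA.** Batch variational Bayes (scikit-learn), symmetric priors 1/K on
  both sides, 20 passes by default.  Variational inference lands in local
  optima, so `train_lda` fits `n_init = 3` independent restarts and keeps
  the one with the highest per-word likelihood bound — the k-means restart
  logic applied to LDA.  On planted-signature corpora a single restart
  occasionally splits one true topic and absorbs another; the bound
  separates those fits cleanly (≈ 0.13 nats per word in our benchmarks).
- **Log perplexity** is reported as the per-word variational lower bound on
  log-likelihood (≤ 0; closer to zero is better).
- **Coherence.** Sliding-window NPMI over the cleaned corpus (window 10
  tokens, boolean occurrence per window): a topic scores the mean NPMI of
  its top-10 word pairs, a model the mean over topics.  A UMass
  (document co-occurrence) variant is available; the measure used is
  recorded in the selection report.
- **Topic overlap.** Mean over unordered topic pairs of the shared fraction
  of top-10 words (ties toward the lower word id).  1 means identical
  topics, 0 disjoint.
- **Selection rule.** The three curves are combined automatically: among
  candidate K whose overlap is at or below the median overlap across the
  range, choose the K maximizing coherence (ties toward smaller K).
  Overlap gates out redundant-topic models; coherence then picks the most
  interpretable one.  A forced-K override reproduces manual selection.
- Documents whose bag-of-words is empty after filtering are excluded from
  LDA with a logged count; they have no θ row, no fused vector, and do not
  enter clustering.

## Fusion

Topic vector: the φ-probability-weighted average of the topic's top-10
keywords' embeddings, with weights renormalized over the keywords present
in the embedding vocabulary (out-of-vocabulary keywords are dropped and
recorded; zero-vector substitution would shrink norms unpredictably).
Document vector: the θ-weighted average of the document's top-5 topics'
vectors, weights renormalized over the selected set (when K < 5 all topics
are used).  Renormalization of the top-5 θ weights is an interpretation —
the alternative (unnormalized weights) would scale vectors by the covered
θ mass; renormalization keeps every document vector a convex combination
of topic vectors, which gives two exact identities used in testing: a
one-hot document equals its topic vector, and a single-keyword topic
equals that word's embedding.  Fused vectors are not length-normalized:
the evolution stage's cosine is scale-invariant and the clustering stage
z-scores its own copy.

## Temporal clustering

Per phase: z-score each dimension of the fused vectors with the
*population* standard deviation (divide by n — stated because it changes
values at small n), leaving zero-variance dimensions at 0 with a warning;
run k-means (k-means++ seeding, 10 restarts, tol 1e-6, max 300 iterations)
for k = 2…10; keep the k with maximal mean silhouette (Euclidean, in the
standardized space, consistent with the clustering metric), ties toward
smaller k; candidates with k ≥ n points are skipped.  Phases with fewer
than 10 documents are reported as a single cluster with a warning.

Cluster profiles: the dominant topic is the argmax of the **mean θ over
members** (not the majority of per-document dominant topics — the two can
disagree, and the mean-θ semantics is what the cluster × topic matrix
reports); the representative document minimizes Euclidean distance to the
standardized centroid (ties to the lexicographically smallest id); cluster
keywords come from the member-averaged word distribution mean_d(θ_d φ),
which blends dominant and secondary topical signal.

## Evolution links

Clusters of adjacent phases are compared by cosine similarity of their
**raw-space** centroids (member means of unstandardized fused vectors).
Per-phase z-scores are not comparable across phases, so standardized
centroids would make cross-phase cosines meaningless; the standardized
alternative remains available behind a config switch for sensitivity
checks.  Pairs with similarity ≥ 0.8 (inclusive; configurable) become
links; many-to-many links are allowed.  Links connect only adjacent
phases, so the Sankey structure is a layered graph.  Zero-norm centroids
yield undefined (NaN) similarities with a warning and are never retained.

## Novelty and backtesting

Cluster Novelty `N_C` is the plain mean publication year of a cluster's
members; Topic Novelty `N_{c,t}` is the plain mean year over the cluster-c
members that *include* topic t.  Inclusion defaults to membership in the
document's top-5 θ topics — the same representation the fusion stage uses
— with a θ ≥ 0.1 threshold rule available.  A cell with no qualifying
member is undefined and reported as such, not as 0.  Both scores are
bounded by the member year range and shift by exactly c when every year
shifts by c; these properties are tested.

Prediction strategies are pluggable and recorded in the output: the
default `above_mean` takes the dominant topics of clusters whose `N_C`
strictly exceeds the phase's unweighted mean score; `top_m` and
`year_threshold` are alternatives.  Backtesting compares a phase's
predicted set against the dominant topics of the *next* phase's clusters:
precision = |pred ∩ actual| / |pred|, recall = |pred ∩ actual| / |actual|.
An empty prediction set leaves precision undefined (reported as missing —
fabricating a 0 would invent a score the formula does not define) and
recall 0 when actual topics exist.  Non-adjacent phase pairs are rejected.

## Synthetic benchmark corpora

The generator plants K topics with disjoint signature vocabularies plus a
shared background vocabulary.  Per document: a phase (uniform by default),
a year (uniform within the phase), a topic mixture from Dirichlet(α)
re-weighted by the phase's prevalence column, and 100–250 tokens sampled
topic-first (each token picks a topic from the mixture, then a uniform
signature word; with probability 0.1 a uniform background word instead).
Titles are the first 5 tokens.  Defaults: α = 0.08 (documents concentrate
on one or two topics, as abstracts do), 40 signature words per topic, 120
background words.  Ground truth (signatures, mixtures, argmax labels,
emergent/persistent topic sets) is written beside the corpus.

Presets: **recovery** (5 topics, uniform prevalence, 800 documents) for
topic-count and signature recovery; **emergence** (5 topics; topic 4 has
prevalence only in the final phase, at double weight, with a quadratic
within-phase year ramp — an emerging hotspot concentrates in the newest
years) for novelty forecasting; **persistence** (4 topics; one active in
every phase, one declining, one final-phase-only) for evolution-chain
structure.

What the generator does **not** emulate: English syntax and collocations,
polysemy, vocabulary drift within a topic, citation structure, author
effects, and realistic topic correlations.  Passing tests on these corpora
therefore demonstrate that the estimators recover planted co-occurrence
and recency structure under abstract-scale document statistics — not that
any particular real literature will yield equally clean topics, clusters,
or forecasts.  Real corpora have softer signatures and fuzzier phase
structure; silhouette scores and signature overlaps will be lower.

## Problem sizes used in validation

The test suite and the acceptance script scale the scenarios to keep a
full validation run in the minutes range on one CPU: shared fixtures use a
300-document recovery corpus with 32-dimensional embeddings trained for 5
epochs; statistical checks use the full 800-document recovery preset
(topic scan K = 2…10 at 20 passes), 600-document emergence/persistence
presets at the planted K (15 passes), 20 seeds for the emergence
forecasting rate, 30 seeds for blob k-recovery, and a 250-document
persistence run for the determinism check.  These sizes are the package's
validation conditions, chosen to make the planted effects detectable with
comfortable margins; nothing in the implementation depends on them.

## Known limitations

- The automatic K-selection rule is a reasonable codification of
  three-curve inspection, but no automatic rule reproduces expert judgment
  on every corpus; the forced-K override exists for exactly that reason.
- Pair coherence measures what its pair list measures.  A poorly chosen
  list selects embeddings for the wrong invariances.
- Cosine-thresholded evolution links treat 0.8 as meaningful in the fused
  space; the threshold is configurable, and the link graph should be read
  jointly with cluster sizes and dominant-topic weights.
- Novelty is recency, not importance: a small, young cluster outranks a
  large, established one by construction.
- The backtest's "actual" set is the next phase's dominant topics, so a
  topic that appears there for the first time is unforecastable from the
  previous phase by any dominant-topic strategy; recall against such
  genuinely new themes measures the scenario, not the estimator.
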