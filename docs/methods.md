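# Methods

## Retrieval model

The task is binary relevance classification of abstracts (DDI-relevant vs
not) under pool-stratified active learning. Documents are bags of
lowercase, stop-word-free tokens; title and abstract are concatenated
before tokenisation because titles carry high-signal interaction terms.
Tokenisation splits on whitespace and strips punctuation only at token
edges, preserving hyphenated drug terminology ("co-administration"). The
stop-list is a fixed file shipped with the package; its SHA-256 is logged
by every CLI run so corpora processed with different stop-lists are never
silently mixed.

## Scoring backends

**Linear max-margin.** Features are raw term counts over the vocabulary
that survives the SD filter: a term is kept when the population standard
deviation of its within-document relative frequency (count/length) across
training documents strictly exceeds 0.03. SD is computed on relative
frequencies, not raw counts, so document length does not masquerade as
signal; the population (divide-by-n) form is used for determinism of the
boundary cases. A `LinearSVC` (C = 1, linear kernel — the natural choice
for sparse text) provides the margin; probabilities come from a Platt
sigmoid fitted on the training decision values with Platt's smoothed
targets. The sigmoid's offset is fixed at the margin midpoint and only the
(negative) slope is optimised, which guarantees the probability is a
strictly increasing function of the decision value — rankings, and hence
every sampling scheme, are calibration-invariant.

**fastText-lite.** Each document is the multiset of its word units plus
order-2 character sub-units, hashed by CRC-32 into 2¹⁶ embedding rows
(the hashing-trick dictionary). The document vector is the element-wise
average of the unit embeddings; a single sigmoid unit φ(z) = 1/(1+e⁻ᶻ) on
top is trained end-to-end by SGD on the logistic loss with a linearly
decaying learning rate (0.5, 25 epochs, 32 dimensions by default). Average
pooling makes scores exactly permutation-invariant in the tokens, matching
the bag-of-words semantics of the rest of the pipeline. Training is
deterministic given `random_state` (default 20230530). Pre-trained
embedding initialisation is deliberately not required; the model trains
from random initialisation so the artifact is self-contained.

Hyperparameters of both backends are exposed as estimator parameters and
are not claimed to be optimal; they were chosen as conventional defaults
for short-document text classification.

Documents whose token list is empty after preprocessing receive the 0.5
prior with a warning rather than an arbitrary class.

## Sampling schemes

Uncertainty is least confidence 1−|2p−1| by default; binary margin is
algebraically identical and binary entropy is a monotone transform of it,
so all three rules select the same batches up to ties — they are provided
for interface parity and verified to behave comparably. Composite schemes
follow the protocol's canonical budgets: a 100-document candidate subset per round
(uncertainty only, or 50 least-confident + 50 most-positive when positive
sampling is active — the 50/50 split is configurable via
`positive_fraction`), optionally narrowed to the top 20 by mean cosine
similarity of 30-key-term TF-IDF vectors against the labelled positives.
Key-term vectors use within-document relative frequency as coordinates
(the natural completion of the TF definition; raw counts would only
rescale and cosine is scale-invariant per coordinate set, but the choice
is config-exposed). The TF-IDF reference collection is the current
labelled corpus, and similarity targets the positives only. Out-of-index
terms are assigned df = 1 (maximal IDF) because unscreened-pool documents
routinely contain unseen vocabulary. All top-k selections break ties by a
seeded uniform draw applied after lexicographic id ordering, making every
run exactly reproducible.

Random negatives are drawn once at initialisation (100 for training, 50
for validation); per-round redraws are available behind
`ALConfig.redraw_random_negatives` but default off, since random-negative
sampling belongs to the initialisation step of the protocol. Assumed
negatives re-enter the scoring pool each round as calibration candidates:
if a review batch surfaces one, its label is corrected to the oracle's
answer and its provenance becomes human. Human labels are never
overwritten.

## The loop

Four rounds. Each round re-fits the backend from scratch on the current
training set (no warm start, so results are independent of round history
beyond the data), scores the remaining pool, composes the review batch,
splits the newly labelled documents equally between training and
validation by a seeded draw (odd remainder to training), and evaluates on
the updated validation set. Validation composition therefore drifts across
rounds — this is intrinsic to the protocol and is logged; reviewed
documents are disproportionately near the decision boundary, so per-round
precision is not an i.i.d. estimate of pool-level precision. Validation
documents never migrate into training.

Precision at recall ≥ 0.95 sweeps every distinct score as a threshold and
reports the best precision among thresholds whose recall clears the floor
(the floor interpretation — not "nearest to 0.95" — because a screening
application treats 0.95 as a hard recall guarantee). The all-inclusive
threshold has recall 1, so a feasible threshold always exists.

## Closed-form theory

With N₊ positives, N₋ ≫ N₊ negatives, base error ε and n∓ mislabeled
positives hidden among pseudo-negatives:

- error before calibration: ε + n∓/(N₋+N₊). (The first printed form of
  this relation omits the operator between the two terms; the sum is the
  reading consistent with the after-calibration form and the worked
  example, and is what the package implements.)
- one calibration round multiplies the mislabel term by
  (N₊ + n∓·N₊/(N₋+N₊))/(N₋+N₊); m rounds apply it m times (exact
  geometric decay). At n∓ = N₋/1000 and N₊ = N₋/4 the factor is 0.20016,
  i.e. a ~5.0× reduction per step. Note that at those ratios the initial
  mislabel term is exactly 0.0008 (commonly quoted rounded to 0.001); the
  package returns exact values.
- positive-sampling advantage: (α/ε)·(N₋+N₊)/N₊ — the ratio of the two
  schemes' chances of selecting a given positive. This is a heuristic
  comparison (α is a selection fraction, ε·N₊/(N₋+N₊) a misclassified-
  positive prevalence); the package evaluates the closed form and the test
  suite additionally simulates the underlying selection model at reduced
  scale.

`estimate_pool_positives` scales a spot-check review rate to a pool count
by simple proportion with rounding (142,520 × 25/1000 = 3,563).

## Synthetic corpus generator

The generator emulates the facts the AL design depends on, not language:

- two pools with positive prevalence 0.025 (screened) and 0.001
  (unscreened); pool sizes and labelled stock default to the reference
  corpus layout the protocol is initialised from (150 labelled positives, 799 labelled negatives, 3,169
  unlabeled screened, 9,999 unscreened — ~14k documents per corpus);
- documents are multinomial bags of words, length ~ Poisson(60), over a
  2,000-term Zipf base vocabulary;
- the positive class mixes a log-normally tilted copy of the base with a
  concentrated topic over 30 planted key terms drawn from mid-rank
  vocabulary (frequent within positives, rare corpus-wide — exactly the
  profile that gives them high TF-IDF and makes them survive the SD
  filter, the way "interaction"-type words behave in real abstracts). The
  mixture weight is `key_term_mass × topic_separation` (default 0.3);
- screened negatives carry the same key terms at
  `screened_negative_key_overlap` (default 0.35) of the positive rate,
  because screened negatives matched the keyword query by construction;
  this overlap is what makes the screened pool a hard discrimination task
  and places baseline precision@0.95 in the 0.6–0.9 band with headroom
  for AL improvement, the regime the protocol is designed for;
- unscreened negatives are drawn from the unshifted base; `pool_shift`
  log-normally tilts the screened-negative background away from it,
  reproducing the pool-distinct negative distributions that motivate
  training separate classifiers per pool.

What the generator does *not* emulate: word order, syntax, topic
multimodality within classes, citation metadata, and annotator noise
(the simulated oracle is perfect). Passing properties on this benchmark
therefore demonstrate the mechanics and relative ordering of the sampling
schemes, not absolute precision on real literature.

The benchmark suite is 5 corpora with seeds derived as
`(seed·101 + i) mod 2³¹`; at the default ~14k documents per corpus the
full acceptance property matrix (6 protocol runs × 5 seeds × 4 rounds,
linear backend) completes in well under a minute.

## Numerical and degenerate-input choices

- TF of a term in an empty document is undefined → error; an empty
  document in scoring receives probability 0.5 with a warning.
- `tfidf` is exactly 0 for terms present in every reference document and
  for absent terms.
- Key-term TFIDF ties break lexicographically; all stochastic tie-breaks
  are seeded.
- SD filter requires ≥ 2 documents; an empty post-filter feature set is an
  error that names `sd_threshold` as the remedy.
- `ImbalanceScenario` warns (not errors) when n∓ > N₋/10, where the
  small-contamination approximation behind the decay argument weakens.
- Model archives are versioned joblib payloads carrying backend name,
  parameters and the stop-list hash.

## Known limitations

- The margin backend's Platt slope is fitted on training decision values
  (no held-out fold); with small, separable training sets probabilities
  are optimistic, which is harmless to rank-based sampling but means
  absolute probabilities should not be read as calibrated risks.
- MEDLINE parsing accepts only PMID/TI/AB fields; structured abstracts
  lose their section labels.
- The GENIA interchange format mentioned in some screening pipelines is
  not implemented: nothing downstream consumes it.
- Interactive oracle mode is a minimal stdin prompt; checkpointing
  (`save_checkpoint`/`load_checkpoint`) is provided for resuming
  interrupted interactive runs.
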