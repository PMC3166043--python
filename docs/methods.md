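# Methods

## Problem

Given a sentence with two marked ("focus") proteins, decide whether it
asserts an interaction between them. Supervised learners do well on this
task but waste the sparse tail of the feature distribution: a multi-word
pattern seen twice in a labelled corpus gets a negligible weight, and a
pattern seen only at test time gets none. Feature coupling generalization
(FCG) recovers that tail by measuring, on a large unlabeled corpus, how
strongly each example-specific pattern co-occurs with known interaction
cues, and feeding those real-valued relatedness scores to the classifier
instead of the raw sparse indicators.

## Representation

Sentences are lowercased, XML entities decoded, and split into maximal
letter/digit runs plus single punctuation tokens. The two focus proteins
become `prot1`/`prot2` (in sentence order), other tagged proteins `prot0`.
Pairs whose character spans overlap collapse to the fixed sentence
`prot1 prot2 .`. With `i1`, `i2` the placeholder indices, features are
anchored to:

* **general areas** — left of `prot1`, between the pair, right of `prot2`;
* **surrounding areas** — 4-token windows on each side of each protein;
* **specific positions** — signed final-token offsets within 5 of either
  protein (`-3_From_P1=the results`); every token in range is keyed
  relative to *both* proteins, so offsets beyond the window for the other
  protein (e.g. `-9_From_P2=the`) still appear;
* **conjunct positions** — an n-gram adjacent to each protein joined with
  the discretised pair distance
  (`P1_Left=show that^P2_Left=prot0 and^5`); distance buckets are
  0–5 singletons, then 6~7, 8~10, 11~15, 16~20, 21~30, 31~40, 40~
  (bounds inclusive, so 40 falls in 31~40).

An n-gram's position is the offset of its **final** token. All lexical
features are Boolean with set semantics; n-grams may contain the
placeholder tokens (`0_From_P2=with prot2` is a legitimate and useful
pattern).

## Feature coupling

* **CDFs** (class-distinguishing features): the general/surrounding/
  specific-position n-gram keys of the training data ranked by the
  2×2 chi-square statistic against the label (no continuity correction —
  ranking only; ties broken lexicographically); top `K = 400` kept.
  Selection happens inside each cross-validation fold, on training
  abstracts only.
* **EDFs** (example-distinguishing features), three families with root
  maps: specific-position keys rooted by the general area of their final
  token (protein indices fold rightwards: `i1`→inner, `i2`→right);
  conjunct-position keys rooted by the (P1 side, P2 side) pair;
  discretised-similarity keys `SimWith_<target>_Over_<θ>`,
  θ ∈ {0.1, 0.2, 0.3, 0.5, 0.8} with "over" read as ≥, all sharing a
  single root. The similarity vector uses offset-keyed bigrams/trigrams
  over the whole sentence, no unigrams, surrounding-window terms weighted
  ×3, and is zeroed between examples with different protein distances.
* **Counting**: one pass over the unlabeled corpus records, per example,
  Boolean presence of EDF and CDF keys into (N, cnt(e), cnt(c), co(e,c)).
  Counting is associative, so shards merge exactly — corpus-size ladders
  reuse cumulative prefixes.
* **Coupling measure**: the default is additively smoothed pointwise
  mutual information, `FCD = log((co+b)(N+b) / ((cnt_e+b)(cnt_c+b)))`,
  `b = 1`. A `log_count_pmi` variant applies `x → log(x+b)` to every
  count before the same ratio, compressing the dynamic range of very
  large corpora. Both are separable in the four counts, which the
  vectorizer exploits: per-root baselines plus corrections on the sparse
  co > 0 pairs. An EDF never seen in the unlabeled corpus contributes the
  co = 0 baseline rather than being dropped.
* **Coupling vector**: indexed by (root, CDF, measure); the coordinate sums
  FCD(e, c) over the example's EDFs with that root. L2-normalised per
  example before classification (SVM inputs need bounded scale).

## Classifiers and evaluation

Lexical features go to a linear SVM (C = 1, the solver default). Coupling
vectors are projected onto the top 200 left-singular directions of the
coupling matrix (deterministic full SVD; transductive fit over train+test
rows by default, train-only selectable — labels are never involved) and
classified by an RBF-kernel SVM with C = 3, γ = 20 in the
exp(−γ‖a−b‖²) convention, without rescaling the projected features. Raw
decision values fuse as 0.6·lexical + 0.4·coupling, thresholded at 0.

Evaluation uses abstract-wise 10-fold cross-validation: folds partition
document identifiers, never sentences, so same-abstract leakage is
impossible. CDF selection, counting and model fitting never see test-fold
labels. The unlabeled corpus is scanned once against the union of the
per-fold CDF sets — counting is label-free and each fold reads only its
own CDFs' counts, so this is count-for-count identical to scanning inside
the fold loop. Reported metrics are positive-class precision/recall/F at
threshold 0 and rank-based ROC AUC, pooled over folds (per-fold values
are also emitted). With fixed seeds every stage is bit-reproducible.

The default EDF family for experiments is the specific-position family,
the strongest single family; conjunct-position and similarity families
are selectable. The similarity family costs O(|unlabeled| × |targets|)
cosine evaluations during counting, so it is practical at desk scale only
for small corpora.

## Synthetic corpus

The generator builds the regime FCG is designed for. Sentences follow the
skeleton *left filler / prot1 / inner filler / prot2 / right filler* with
lengths drawn per sentence (left and right may be empty, exercising every
area code path; a `prot0` mention appears in ~10% of sentences). Labels
are decided by *trigger* bigrams planted immediately right of `prot1`:
each of 100 triggers is confined to a single abstract (100 abstracts ×
6 sentences) and occurs about twice in labelled data, so under
abstract-wise folds a supervised learner never sees a test trigger during
training. *Cue* words planted left of `prot2` appear in half the
positives and a tenth of the negatives — frequent enough to be selected
as CDFs. The 100k-example unlabeled corpus carries no labels; triggers
appear ~10³ times each and co-occur with cues (P = 0.9 given a trigger,
0.05 otherwise), so trigger→cue coupling statistics are the only channel
through which unlabeled data can help. Distractor n-grams occur at
matched frequencies in both classes. An optional label-flip noise rate
(default 0) dirties the labels without touching the content.

What the generator does **not** emulate: linguistic word order and
syntax, protein-name morphology, correlated (Zipfian) word frequencies,
multiple interacting pair mentions per sentence, or annotation ambiguity.
Passing tests therefore demonstrate the mechanism — sparse,
fold-disjoint signal recovered through unlabeled co-occurrence — not
performance on real abstracts, which additionally depends on tagging
quality and corpus idiosyncrasies.

## Numerical and design choices

* Chi-square is 0 whenever a table margin is 0; selection is permutation-
  invariant and deterministic.
* Cosine similarity returns 0 (not NaN) for zero vectors.
* SVD components are clipped to the matrix rank with a warning when 200
  exceeds it.
* Fusion weights are fixed constants, not tuned per fold.
* Self-interaction examples (`prot1 prot2 .`) are classified like any
  other example.
* Problem sizes used by the test suite and the acceptance script — 600
  labelled examples, up to 100k unlabeled, 10 folds, K = 400 — are the
  package's default study conditions; the unlabeled-size ladder
  (1k/10k/50k/100k) reuses cumulative counting shards, which the exact
  merge property makes identical to independent passes.

## Known limitations

* The exact algebra of the published coupling measure is not recoverable
  from the available text; the smoothed-PMI default is one member of the
  family the description admits, isolated behind `FcdConfig.measure`.
* Real-corpus headline numbers are not reproducible here: they require
  the original labelled corpus, an unpublished fold assignment and a
  multi-gigabyte tagged unlabeled collection.
* The similarity-EDF route is quadratic in corpus size at counting time.
* Protein named-entity recognition and sentence splitting are out of
  scope; inputs arrive with mention spans already tagged.
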