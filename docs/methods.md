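# Methods

## Problem setting

Curated evidence databases are kept current by periodically re-running broad
bibliographic searches and manually screening the hits. Each annual update
retrieves thousands of candidate references (set A), of which screeners
provisionally include a few percent on title/abstract (set M) and finally
include well under 2% after full-text assessment (set Y, with Y ⊆ M ⊆ A).
Screening prioritization ranks the candidates so that the included
references surface early; the screeners then read the list top-down and stop
at an agreed effort cut-off. Nothing is excluded automatically — the method
changes the *order* of screening, not its rules.

## Ranking model

Each reference contributes its title and, when available, its abstract.
Text is lower-cased and split on non-alphanumeric runs; word n-grams with
n = 1..5 are extracted separately from title and abstract (no n-gram spans
the boundary). The same inventory is encoded four ways — tf-idf and binary
presence, each over raw and Porter-stemmed tokens — and the four sparse
blocks are concatenated in a fixed order (tfidf-unstemmed, tfidf-stemmed,
binary-unstemmed, binary-stemmed). There is no frequency cut-off, feature
selection or dimension reduction: every n-gram observed in training gets a
column, and the regularized trainer is left to discount unhelpful ones.
The tf-idf variant is the smoothed form idf(t) = ln((1+N)/(1+df(t))) + 1
with raw counts as tf and L2 row normalization within each tf-idf block;
binary rows are left unnormalized so presence weights are comparable across
documents. Vocabularies and document frequencies come from training
documents only.

The scorer is linear, s(x) = σ(w·x + b), trained by stochastic gradient
descent on the logistic loss with L2 regularization α = 10⁻⁴ for exactly
50 epochs. The class imbalance is handled by loss weighting alone: every
positive example counts 80× a negative one; there is no under- or
oversampling. By default Y (full-text included) is the positive class and
everything else — including M-not-Y records — is negative; training on M as
the positive signal is available as a configuration switch. Candidates are
ranked by descending score with ties broken by ascending record id, which
makes every ranking a deterministic function of (data, seed).

### Numerical choices

* Training rows are sorted by (iteration, record id) before fitting, so the
  learned model depends on the training *set*, not on how folds or
  iterations were enumerated.
* The SGD learning rate follows an inverse-scaling schedule
  η_t = η₀/√t with η₀ = 0.01. On desk-scale corpora (a few thousand
  documents) aggressive schedules drive |w·x| to several hundred on the
  unnormalized binary blocks (row norms ≈ √(2·n-grams)), saturating σ and
  collapsing distinct candidates onto scores of exactly 0.0/1.0; the small
  initial rate keeps margins at O(10) and training loss monotone while the
  50-epoch budget still converges. The schedule and η₀ are exposed in
  `RankerConfig` for sensitivity analysis.
* Sigmoid scores are used raw for ranking and for merging cross-validation
  folds; no per-fold calibration is applied. Fold scores are therefore only
  approximately comparable — the documented cost of merge-by-score.
* Reported percentages are rounded half-up to one decimal at reporting
  time only; all internal computation is full precision. A screening
  cut-off of x% means the first ⌊x·N⌋ ranks.

## Deduplication

References with dual online/print publication dates can be retrieved by two
consecutive update searches. For simulation this is a leakage hazard;
duplicates are therefore removed from the *training* side only, keeping the
evaluation set — and the reported workload — intact. Matching is exact on a
configurable key: record id, or normalized title (case-folded,
punctuation-stripped, whitespace-collapsed). When prior iterations are
merged into one training pool, a re-screened reference contributes only its
most recent judgement. The protocol layer re-runs duplicate detection after
filtering and fails loudly if any training/test collision survives.

## Simulation protocols

*Prospective*: train on the deduplicated union of all iterations before the
target update, rank the target in one pass. *Retrospective
(cross-validation)*: split the target into k = 10 seeded uniform random
folds; for each fold train on the prior iterations plus the other nine and
score the held-out fold; merge the folds and sort by score, so each target
record is scored exactly once by a model that never saw it. The feature
space is refitted per fold on the training side only. With no prior
iterations the retrospective design degrades to plain k-fold CV, which is
how the original review itself can be evaluated. Folds are not stratified
by label; with very few positives a fold's training set can end up
single-class, which raises an error naming the fold rather than silently
reshuffling.

In abstract mode, records without abstracts are excluded from both training
and evaluation. The title-only variants handle those records: either train
and score on titles (using titles of *all* training records), or train on
full text and score targets from titles alone.

## Evaluation

At cut-off rank r, effort = TP + FP = r (references screened manually) and
recall = TP/(TP+FN). Sweeping r gives the effort-recall curve; screening in
random order yields the diagonal E[recall] = r/N (hypergeometric mean).
Summary statistics: the rank and effort percentage of the last included
reference, and recall at the 20/25/30% cut-offs. Recall denominators follow
the evaluated population (e.g. the deduplicated included records with
abstracts, in abstract mode).

## Synthetic corpora

Real screening labels for this kind of update series are generally not
shareable, so the pipeline is exercised end to end on generated corpora
that reproduce the structure the method assumes: a large original review
(24 000 records) followed by four updates (4 500, 3 800, 4 000, 5 000);
Y-prevalence 1%; an M stratum 7× larger; 8.4% of records without
abstracts; 4% of each update re-screened from the previous iteration
(identical text, fresh id); and 10% of the relevance vocabulary replaced
between iterations (conceptual drift). Tests and the acceptance script use
this shape divided by 10 — (2 400, 450, 380, 400, 500) — so a full
simulated update cycle fits in desk-scale minutes; the generative
conditions are otherwise unchanged.

Text is the simplest model that makes n-gram tf-idf learning non-trivial:
background tokens drawn from a Zipf(1.1) distribution over a 2 000-word
synthetic vocabulary (titles 5–15 tokens, abstracts 50–250), plus 20 signal
terms that a Y record contains with probability 0.6 each, an M-not-Y record
at the midpoint rate 0.31 and a background record at 0.02. A signal term
assigned to an abstract also lands in the title with probability 0.5; for
records without abstracts it goes to the title directly. A ground-truth
manifest records the per-iteration signal terms and every planted
duplicate.

What the generator does *not* emulate: real biomedical language (topical
correlation, synonymy, phrase structure), label noise, reviewer
disagreement, or retrieval-query drift. Passing the synthetic recovery
tests therefore shows the pipeline is correctly wired and can exploit a
lexical signal at realistic prevalence and corpus shape — not that any
particular recall level will be achieved on real screening data.

Because Y records draw their signal terms stochastically, a corpus of this
size pools only ≈ 14 included records across the four updates, and an
occasional Y record carries as few as 7 of the 20 terms — inside the range
typical of the M-not-Y stratum that is trained as negative. Two model
properties compound this. First, with no vocabulary cap the unnormalized
binary blocks give every additional mid-frequency token a slightly negative
weight contribution, so scores drift down with document length (on this
corpus, rank correlates with length at Spearman ρ ≈ 0.85). Second, a
weak-signal Y record is statistically indistinguishable from the upper tail
of the M stratum. An included record that is simultaneously weak-signal and
long therefore ranks deep — the synthetic analogue of the outlier included
references that real screening simulations also report (last included
reference found only after 45–61% of the list in some updates). This is a
property of the weighted logistic objective itself, not of its SGD
optimization: full-batch optimization of the same objective reproduces both
the length bias and the deep-ranked outliers. Small-corpus
recall-at-cut-off numbers are therefore noticeably seed-sensitive, and the
recovery check pools all updates to damp (but not eliminate) this.

## Known limitations

* Merge-by-score across CV folds assumes fold models are on comparable
  scales; with saturation or tiny folds the merged order can depend on
  per-fold calibration that the method deliberately omits.
* Duplicate detection is exact-key matching; fuzzy record linkage (edit
  distance, author/year blocking) is out of scope.
* With no vocabulary cap, the feature space grows to millions of columns on
  corpora of tens of thousands of documents; memory is O(total n-gram
  occurrences).
* Only titles and abstracts are modelled; index terms, journal and author
  metadata are not used.
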