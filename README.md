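# screenrank

Screening prioritization for systematic-review updates.

Evidence databases that are maintained through an annually updated
systematic review force their curators to hand-screen thousands of
retrieved references per update, of which typically under 2% are included
after full-text assessment. `screenrank` ranks the candidate references so
that screeners encounter the relevant ones early: nothing is excluded
automatically, but reading the ranked list top-down lets a review team stop
at an agreed effort cut-off with a quantified, simulated recall. It is
aimed at information specialists and review methodologists who want to
simulate — and then deploy — ranking-assisted screening for a multi-update
review series.

## Method

Records carry cumulative stage labels A ⊇ M ⊇ Y (retrieved; provisionally
included on title/abstract; included on full text). Each record's title and
abstract are turned into bag-of-word-n-grams (n ≤ 5) encoded four ways —
tf-idf and binary presence, over raw and Porter-stemmed tokens — with no
vocabulary cut-off or feature selection. A linear scorer

    s(x) = σ(w·x + b)

is trained by stochastic gradient descent on the logistic loss with L2
regularization (α = 10⁻⁴) for 50 epochs, each positive example weighted 80×
to offset the class imbalance (no under-/oversampling). Candidates are
ranked by descending score (pointwise learning-to-rank).

Evaluation is by effort-recall curves: at cut-off rank r, effort = TP + FP
= r references screened, recall = TP/(TP + FN). Two simulation protocols
reproduce deployment conditions: *prospective* (train on prior review
iterations only, rank the new update) and *retrospective cross-validation*
(additionally split the target update into 10 folds, score each fold by a
model trained on the prior iterations plus the other nine, and merge the
folds into one ranking by score). References re-screened across consecutive
iterations are removed from the training side only, so a model never ranks
a record it was trained on. A synthetic-corpus generator with planted
lexical signal provides fully reproducible test beds shaped like a real
review series (one ~24k-record original review, four ~4–5k updates, ~1%
included, ~8.4% missing abstracts). See `docs/methods.md` for details and
assumptions.

## Worked example

Generate a two-iteration synthetic corpus and simulate prospective
screening of the update:

```sh
cat > gen.yaml <<EOF
n_per_iteration: [1200, 400]
seed: 7
EOF
screenrank generate --out corpus --config gen.yaml --seed 7
screenrank simulate-prospective --records corpus/records.csv \
    --out sim --target 1 --seed 7
```

which prints

```json
{
  "n_candidates": 353,
  "n_relevant": 6,
  "last_relevant_rank": 170,
  "last_relevant_effort_pct": 48.2,
  "recall_at_cutoff_pct": {
    "20": 66.7,
    "25": 66.7,
    "30": 66.7
  }
}
```

Read: the update's abstract-bearing population has 353 candidates, 6 of
them included on full text. Screening the ranked list top-down finds 4 of
the 6 (66.7%) within the first quarter of the list; the last included
reference surfaces only at rank 170 (48.2% effort). Deep-ranked outliers
like this one are expected for included records whose text carries little
of the learned signal — the effort-recall curve (`sim/curve.png`,
`sim/curve.tsv`) shows where each one falls, and the `ranking.tsv` gives
the full ordered list. On the full five-iteration corpus shape the pooled
recall at 25% effort is substantially higher (see below).

The library surface mirrors the CLI: `screenrank.generate_series`,
`fit_feature_space`/`transform`, `train`/`score`/`rank`,
`run_prospective`/`run_retrospective_cv`/`run_title_only`, and
`curve_from_ranked_labels`.

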