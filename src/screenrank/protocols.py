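"""Simulation protocols: prospective and cross-validated retrospective runs.

Prospective
    Train on the deduplicated records of all iterations before the target
    update, rank the target update in one pass.  This mimics deployment:
    the model never sees the update it ranks.

Retrospective (cross-validation)
    Additionally exploit the target update itself: its records are split
    into k random folds; for each fold a model is trained on the prior
    iterations plus the other k-1 folds and scores the held-out fold.  The
    k scored folds are merged and sorted by score into a single ranking, so
    every target record is scored exactly once by a model that never saw it.
    With no prior iterations (target 0) this degrades to plain k-fold CV.

Title-only variants
    Either train and score on titles alone (using titles of *all* training
    records, abstracts or not), or train on titles+abstracts and score the
    targets from their titles — the two ways of handling records that
    arrive without abstracts.

In abstract mode (``title_and_abstract``) records lacking abstracts are
excluded from both the training pool and the evaluation population.  In all
modes, cross-iteration duplicates are removed from the training side only,
and every run asserts that no training/test key collision survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dedup import (
    deduplicate_training,
    deduplicate_within,
    find_cross_iteration_duplicates,
)
from .metrics import EffortRecallCurve, curve_from_ranked_labels
from .ranker import RankedList, RankerConfig, RankerError, rank, score, train
from .features import fit_feature_space, transform
from .records import BibRecord, ReviewSeries

MODES = ("prospective", "retrospective_cv")
EVAL_POPULATIONS = ("abstract_present", "abstract_missing", "all")


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolRun:
    """Configuration of one simulation run."""

    mode: str
    target_iteration: int
    k_folds: int = 10
    text_mode: str = "title_and_abstract"
    eval_population: str = "abstract_present"
    seed: int = 0
    ranker_config: RankerConfig = field(default_factory=RankerConfig)
    dedup_key: str = "normalized_title"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ProtocolError(f"unknown mode {self.mode!r}, expected {MODES}")
        if self.eval_population not in EVAL_POPULATIONS:
            raise ProtocolError(
                f"unknown eval_population {self.eval_population!r}"
            )
        if self.mode == "prospective" and self.target_iteration < 1:
            raise ProtocolError(
                "prospective runs need target_iteration >= 1 (prior training data)"
            )
        if self.target_iteration < 0:
            raise ProtocolError("target_iteration must be >= 0")
        if self.mode == "retrospective_cv" and self.k_folds < 2:
            raise ProtocolError("k_folds must be >= 2")


def _is_positive(record: BibRecord, config: RankerConfig) -> bool:
    if config.positive_label_source == "Y":
        return record.label == "Y"
    return record.label in ("M", "Y")


def _filter_population(
    records: Sequence[BibRecord], population: str
) -> list[BibRecord]:
    if population == "abstract_present":
        return [r for r in records if r.has_abstract]
    if population == "abstract_missing":
        return [r for r in records if not r.has_abstract]
    return list(records)


def _prior_pool(
    series: ReviewSeries, target_iteration: int, require_abstract: bool
) -> list[BibRecord]:
    pool = [
        r
        for it in series.iterations[:target_iteration]
        for r in it
        if r.has_abstract or not require_abstract
    ]
    return pool


def _fit_train_score(
    training: Sequence[BibRecord],
    test: Sequence[BibRecord],
    train_text_mode: str,
    score_text_mode: str,
    config: RankerConfig,
    dedup_key: str,
    context: str,
) -> np.ndarray:
    """Dedup → fit features on training → train → score test.  Returns the
    score vector aligned to ``test`` order."""
    training = deduplicate_within(training, key=dedup_key)
    union = ReviewSeries.from_records(list(training) + list(test))
    report = find_cross_iteration_duplicates(union, key=dedup_key)
    training = deduplicate_training(training, test, report)
    # fixed training order: the model must depend on the training SET, not
    # on how folds or iterations happened to be enumerated
    training = sorted(training, key=lambda r: (r.iteration, r.record_id))
    _assert_no_leakage(training, test, dedup_key, context)
    y = np.array([1 if _is_positive(r, config) else 0 for r in training])
    if not training or y.sum() == 0:
        raise ProtocolError(f"{context}: no positive training records after dedup")
    if y.sum() == len(training):
        raise ProtocolError(f"{context}: no negative training records after dedup")
    space = fit_feature_space(training, text_mode=train_text_mode)
    model = train(transform(training, space), y, config)
    return score(model, transform(test, space, text_mode=score_text_mode))


def _assert_no_leakage(
    training: Sequence[BibRecord],
    test: Sequence[BibRecord],
    dedup_key: str,
    context: str,
) -> None:
    union = ReviewSeries.from_records(list(training) + list(test))
    report = find_cross_iteration_duplicates(union, key=dedup_key)
    test_ids = {(r.record_id, r.iteration) for r in test}
    train_ids = {(r.record_id, r.iteration) for r in training}
    if train_ids & test_ids:
        raise ProtocolError(f"{context}: training and test sets share records")
    for p in report.pairs:
        a = (p.training_record_id, p.iteration_from)
        b = (p.test_record_id, p.iteration_to)
        if (a in train_ids and b in test_ids) or (b in train_ids and a in test_ids):
            raise ProtocolError(
                f"{context}: leakage between training and test under key "
                f"{dedup_key!r}: {p}"
            )


def _finish(
    test: Sequence[BibRecord], scores: np.ndarray, config: RankerConfig
) -> tuple[RankedList, EffortRecallCurve]:
    ranked = rank([r.record_id for r in test], scores)
    label_by_id = {r.record_id: 1 if _is_positive(r, config) else 0 for r in test}
    curve = curve_from_ranked_labels([label_by_id[rid] for rid in ranked.record_ids])
    return ranked, curve


def _check_target(series: ReviewSeries, run: ProtocolRun) -> list[BibRecord]:
    if run.target_iteration >= series.n_iterations:
        raise ProtocolError(
            f"target_iteration {run.target_iteration} out of range "
            f"(series has {series.n_iterations} iterations)"
        )
    population = run.eval_population
    test = _filter_population(series.iterations[run.target_iteration], population)
    if not test:
        raise ProtocolError(
            f"evaluation population {population!r} of iteration "
            f"{run.target_iteration} is empty"
        )
    return test


def run_prospective(
    series: ReviewSeries, run: ProtocolRun
) -> tuple[RankedList, EffortRecallCurve]:
    """Train on prior iterations, rank the target update in one pass."""
    if run.target_iteration < 1:
        raise ProtocolError("prospective runs need target_iteration >= 1")
    test = _check_target(series, run)
    training = _prior_pool(
        series,
        run.target_iteration,
        require_abstract=(run.text_mode == "title_and_abstract"),
    )
    scores = _fit_train_score(
        training,
        test,
        run.text_mode,
        run.text_mode,
        run.ranker_config,
        run.dedup_key,
        context=f"prospective target {run.target_iteration}",
    )
    return _finish(test, scores, run.ranker_config)


def _partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded uniform random partition of range(n) into k near-equal folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def run_retrospective_cv(
    series: ReviewSeries, run: ProtocolRun
) -> tuple[RankedList, EffortRecallCurve]:
    """Prior iterations + k-fold CV over the target, merged into one ranking."""
    test_all = _check_target(series, run)
    if len(test_all) < run.k_folds:
        raise ProtocolError(
            f"target iteration has {len(test_all)} records, fewer than "
            f"k_folds={run.k_folds}"
        )
    prior = _prior_pool(
        series,
        run.target_iteration,
        require_abstract=(run.text_mode == "title_and_abstract"),
    )
    folds = _partition(len(test_all), run.k_folds, run.seed)
    scores = np.empty(len(test_all))
    for i, fold_idx in enumerate(folds):
        held_out = [test_all[j] for j in fold_idx]
        in_folds = [
            test_all[j]
            for other in folds
            if other is not fold_idx
            for j in other
        ]
        try:
            fold_scores = _fit_train_score(
                prior + in_folds,
                held_out,
                run.text_mode,
                run.text_mode,
                run.ranker_config,
                run.dedup_key,
                context=f"retrospective fold {i}",
            )
        except (RankerError, ProtocolError) as exc:
            raise ProtocolError(f"fold {i}: {exc}") from exc
        scores[fold_idx] = fold_scores
    return _finish(test_all, scores, run.ranker_config)


MODEL_SOURCES = ("titles_only", "titles_and_abstracts")


def run_title_only(
    series: ReviewSeries, run: ProtocolRun, model_source: str = "titles_only"
) -> tuple[RankedList, EffortRecallCurve]:
    """Rank target records from their titles alone.

    ``model_source="titles_only"``: the model is trained on title text of
    *all* training records (abstract-bearing ones included).
    ``model_source="titles_and_abstracts"``: the model is trained on full
    text of all training records, but targets are scored from titles only.
    """
    if model_source not in MODEL_SOURCES:
        raise ProtocolError(
            f"unknown model_source {model_source!r}, expected {MODEL_SOURCES}"
        )
    if run.eval_population not in ("abstract_missing", "all"):
        raise ProtocolError(
            "title-only runs evaluate on 'abstract_missing' or 'all' populations"
        )
    train_text_mode = (
        "title_only" if model_source == "titles_only" else "title_and_abstract"
    )
    test = _check_target(series, run)
    prior = _prior_pool(series, run.target_iteration, require_abstract=False)
    if run.mode == "prospective":
        scores = _fit_train_score(
            prior,
            test,
            train_text_mode,
            "title_only",
            run.ranker_config,
            run.dedup_key,
            context=f"title-only prospective target {run.target_iteration}",
        )
        return _finish(test, scores, run.ranker_config)
    # retrospective CV on titles
    if len(test) < run.k_folds:
        raise ProtocolError(
            f"target population has {len(test)} records, fewer than "
            f"k_folds={run.k_folds}"
        )
    folds = _partition(len(test), run.k_folds, run.seed)
    scores = np.empty(len(test))
    for i, fold_idx in enumerate(folds):
        held_out = [test[j] for j in fold_idx]
        in_folds = [
            test[j] for other in folds if other is not fold_idx for j in other
        ]
        try:
            scores[fold_idx] = _fit_train_score(
                prior + in_folds,
                held_out,
                train_text_mode,
                "title_only",
                run.ranker_config,
                run.dedup_key,
                context=f"title-only fold {i}",
            )
        except (RankerError, ProtocolError) as exc:
            raise ProtocolError(f"fold {i}: {exc}") from exc
    return _finish(test, scores, run.ranker_config)


__all__ = [
    "ProtocolRun",
    "ProtocolError",
    "run_prospective",
    "run_retrospective_cv",
    "run_title_only",
    "MODES",
    "EVAL_POPULATIONS",
    "MODEL_SOURCES",
]
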