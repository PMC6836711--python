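"""Cross-iteration duplicate detection and training-side removal.

References with dual (online/print) publication dates can be retrieved by
the searches of two consecutive review updates, so the same article may be
screened twice.  For simulation this is a leakage hazard: a model must never
be trained on a reference it is later asked to rank.  The remedy is to drop
the duplicate from the *training* side only, leaving the evaluation set — and
hence the reported workload — untouched, which mirrors how the manual
screeners handled re-examined references.

Matching keys:

``record_id``
    exact identifier equality (the default),
``normalized_title``
    case-folded, punctuation-stripped, whitespace-collapsed exact title match
    (for corpora where re-retrieved references get fresh identifiers).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .records import BibRecord, ReviewSeries

logger = logging.getLogger(__name__)

DEDUP_KEYS = ("record_id", "normalized_title")

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize_title(title: str) -> str:
    """Case-fold, strip punctuation and collapse whitespace."""
    return " ".join(_NON_ALNUM.sub(" ", title.casefold()).split())


def _key_of(record: BibRecord, key: str) -> str:
    if key == "record_id":
        return record.record_id
    if key == "normalized_title":
        return normalize_title(record.title)
    raise ValueError(f"unknown dedup key {key!r}, expected one of {DEDUP_KEYS}")


@dataclass(frozen=True)
class DuplicatePair:
    """One training-side/test-side duplicate link (iteration_from < iteration_to)."""

    training_record_id: str
    test_record_id: str
    iteration_from: int
    iteration_to: int


@dataclass
class DedupReport:
    """All cross-iteration duplicate links found in a series."""

    key: str
    pairs: list[DuplicatePair] = field(default_factory=list)

    @property
    def n_removed_from_training(self) -> int:
        return len({(p.training_record_id, p.iteration_from) for p in self.pairs})

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("training_record_id\ttest_record_id\titeration_from\titeration_to\n")
            for p in self.pairs:
                fh.write(
                    f"{p.training_record_id}\t{p.test_record_id}"
                    f"\t{p.iteration_from}\t{p.iteration_to}\n"
                )


def find_cross_iteration_duplicates(
    series: ReviewSeries, key: str = "record_id"
) -> DedupReport:
    """Detect records shared between distinct iterations under ``key``.

    Each unordered match is listed once, oriented earlier→later (the earlier
    copy is the training-side member in a chronological simulation).  A
    single-iteration series yields an empty report.
    """
    if key not in DEDUP_KEYS:
        raise ValueError(f"unknown dedup key {key!r}, expected one of {DEDUP_KEYS}")
    by_key: dict[str, list[BibRecord]] = {}
    for rec in series.all_records():
        by_key.setdefault(_key_of(rec, key), []).append(rec)
    pairs = []
    for matches in by_key.values():
        if len(matches) < 2:
            continue
        for i, earlier in enumerate(matches):
            for later in matches[i + 1 :]:
                a, b = earlier, later
                if a.iteration == b.iteration:
                    continue
                if a.iteration > b.iteration:
                    a, b = b, a
                pairs.append(
                    DuplicatePair(a.record_id, b.record_id, a.iteration, b.iteration)
                )
    pairs.sort(
        key=lambda p: (p.iteration_from, p.iteration_to, p.training_record_id)
    )
    return DedupReport(key=key, pairs=pairs)


def deduplicate_training(
    training_records: Sequence[BibRecord],
    test_records: Sequence[BibRecord],
    report: DedupReport,
) -> list[BibRecord]:
    """Drop training records that the report links to a test record.

    The test set is never touched.  Idempotent; an emptied training set is
    logged as a warning, not raised.
    """
    test_ids = {(r.record_id, r.iteration) for r in test_records}
    drop: set[tuple[str, int]] = set()
    for p in report.pairs:
        if (p.test_record_id, p.iteration_to) in test_ids:
            drop.add((p.training_record_id, p.iteration_from))
        # orientation may be reversed when training chronologically follows test
        if (p.training_record_id, p.iteration_from) in test_ids:
            drop.add((p.test_record_id, p.iteration_to))
    kept = [r for r in training_records if (r.record_id, r.iteration) not in drop]
    n_removed = len(training_records) - len(kept)
    if n_removed and not kept:
        logger.warning(
            "deduplication removed all %d training records", len(training_records)
        )
    return kept


def deduplicate_within(
    records: Iterable[BibRecord], key: str = "record_id"
) -> list[BibRecord]:
    """Collapse cross-iteration duplicates inside one pool, keeping the latest copy.

    Used when prior iterations are merged into a single training set: a
    reference screened in two consecutive iterations should contribute one
    training example (the most recent judgement), not two.
    """
    latest: dict[str, BibRecord] = {}
    for rec in records:
        k = _key_of(rec, key)
        if k not in latest or rec.iteration > latest[k].iteration:
            latest[k] = rec
    kept_ids = {(r.record_id, r.iteration) for r in latest.values()}
    return [r for r in records if (r.record_id, r.iteration) in kept_ids]


__all__ = [
    "DedupReport",
    "DuplicatePair",
    "find_cross_iteration_duplicates",
    "deduplicate_training",
    "deduplicate_within",
    "normalize_title",
    "DEDUP_KEYS",
]
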