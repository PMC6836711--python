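"""Bibliographic records, review series and their file formats.

A screening corpus is a series of review iterations: the original systematic
review (iteration 0) followed by successive updates.  Every candidate
reference carries a cumulative stage label:

``A``
    retrieved by the database search only,
``M``
    provisionally included on title/abstract ("maybe"),
``Y``
    included after full-text assessment.

The encoding is cumulative: a ``Y`` record is by definition also a member of
the ``M`` and ``A`` sets, and an ``M`` record of the ``A`` set, so the nested
structure Y ⊆ M ⊆ A cannot be violated by construction.

Two interchange formats are supported: a five-column CSV/TSV with header
``id,title,abstract,iteration,label`` and a minimal RIS dialect using the
``TY``/``TI``/``AB``/``ID`` tags plus ``C1`` (iteration) and ``C2`` (label).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up

STAGE_LABELS = ("A", "M", "Y")

CSV_COLUMNS = ("id", "title", "abstract", "iteration", "label")


class RecordValidationError(ValueError):
    """A record or series violates the data contract."""


@dataclass(frozen=True)
class BibRecord:
    """One candidate reference at one review iteration.

    ``abstract`` is ``None`` when the source record had no abstract (or a
    blank one); it is never coerced to an empty string.
    """

    record_id: str
    title: str
    abstract: str | None
    iteration: int
    label: str

    def __post_init__(self) -> None:
        if not self.record_id:
            raise RecordValidationError("record_id must be non-empty")
        if not self.title or not self.title.strip():
            raise RecordValidationError(
                f"record {self.record_id!r}: title must be non-empty"
            )
        if self.iteration < 0:
            raise RecordValidationError(
                f"record {self.record_id!r}: iteration must be >= 0"
            )
        if self.label not in STAGE_LABELS:
            raise RecordValidationError(
                f"record {self.record_id!r}: unknown label {self.label!r}, "
                f"expected one of {STAGE_LABELS}"
            )
        # blank abstracts count as absent
        if self.abstract is not None and not self.abstract.strip():
            object.__setattr__(self, "abstract", None)

    @property
    def has_abstract(self) -> bool:
        return self.abstract is not None

    @property
    def is_maybe(self) -> bool:
        """Member of set M (provisionally included on title/abstract)."""
        return self.label in ("M", "Y")

    @property
    def is_included(self) -> bool:
        """Member of set Y (included after full-text assessment)."""
        return self.label == "Y"


@dataclass
class ReviewSeries:
    """Ordered collection of review iterations.

    Iterations are indexed contiguously from 0.  ``record_id`` must be unique
    *within* each iteration; the same id may legitimately recur in a later
    iteration (a reference re-screened across updates).
    """

    iterations: list[list[BibRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for idx, records in enumerate(self.iterations):
            seen: set[str] = set()
            for rec in records:
                if rec.iteration != idx:
                    raise RecordValidationError(
                        f"record {rec.record_id!r} has iteration {rec.iteration} "
                        f"but sits in iteration {idx}"
                    )
                if rec.record_id in seen:
                    raise RecordValidationError(
                        f"duplicate record_id {rec.record_id!r} within iteration {idx}"
                    )
                seen.add(rec.record_id)

    @classmethod
    def from_records(cls, records: Iterable[BibRecord]) -> "ReviewSeries":
        """Group a flat record list into contiguous iterations."""
        records = list(records)
        if not records:
            return cls([])
        n_iter = max(r.iteration for r in records) + 1
        buckets: list[list[BibRecord]] = [[] for _ in range(n_iter)]
        for rec in records:
            buckets[rec.iteration].append(rec)
        return cls(buckets)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def all_records(self) -> list[BibRecord]:
        return [rec for it in self.iterations for rec in it]

    def __len__(self) -> int:
        return sum(len(it) for it in self.iterations)


def _normalize_abstract(raw: str | None) -> str | None:
    if raw is None or not raw.strip():
        return None
    return raw


def read_records(path: str | Path, format: str | None = None) -> list[BibRecord]:
    """Read bibliographic records from a CSV/TSV or RIS file.

    ``format`` is ``"csv"``, ``"tsv"`` or ``"ris"``; when omitted it is
    inferred from the file suffix.  Decoding is UTF-8 with replacement of
    undecodable bytes.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".ris": "ris"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    try:
        text = path.read_text(encoding="utf-8", errors="replace")
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    if format in ("csv", "tsv"):
        records = _parse_delimited(text, "\t" if format == "tsv" else ",", path.name)
    elif format == "ris":
        records = _parse_ris(text, path.name)
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_within_iteration_uniqueness(records)
    return records


def _check_within_iteration_uniqueness(records: Sequence[BibRecord]) -> None:
    seen: set[tuple[int, str]] = set()
    for rec in records:
        key = (rec.iteration, rec.record_id)
        if key in seen:
            raise RecordValidationError(
                f"duplicate record_id {rec.record_id!r} within iteration {rec.iteration}"
            )
        seen.add(key)


def _parse_delimited(text: str, delimiter: str, name: str) -> list[BibRecord]:
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != list(
        CSV_COLUMNS
    ):
        raise RecordValidationError(
            f"{name}: expected header {','.join(CSV_COLUMNS)!r}, "
            f"got {reader.fieldnames!r}"
        )
    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            records.append(
                BibRecord(
                    record_id=(row["id"] or "").strip(),
                    title=(row["title"] or "").strip(),
                    abstract=_normalize_abstract(row["abstract"]),
                    iteration=int(row["iteration"]),
                    label=(row["label"] or "").strip(),
                )
            )
        except (RecordValidationError, ValueError, TypeError) as exc:
            raise RecordValidationError(f"{name}, line {lineno}: {exc}") from exc
    return records


_RIS_TYPE = "JOUR"


def _parse_ris(text: str, name: str) -> list[BibRecord]:
    """Parse a minimal RIS dialect: TY/TI/AB/ID plus C1 (iteration), C2 (label)."""
    records = []
    fields: dict[str, str] = {}
    in_record = False
    last_tag: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        tag, sep, value = line[:2], line[2:6], line[6:]
        if len(line) >= 6 and sep == "  - " and tag.strip():
            if tag == "TY":
                in_record = True
                fields = {}
                last_tag = None
                continue
            if tag == "ER":
                if not in_record:
                    raise RecordValidationError(f"{name}, line {lineno}: ER without TY")
                records.append(_ris_record(fields, name, lineno))
                in_record = False
                continue
            if in_record:
                fields[tag] = value.rstrip("\n")
                last_tag = tag
        elif in_record and last_tag is not None:
            # continuation line of the previous tag (long abstracts)
            fields[last_tag] = fields[last_tag] + " " + line.strip()
    if in_record:
        raise RecordValidationError(f"{name}: unterminated RIS record (missing ER)")
    return records


def _ris_record(fields: dict[str, str], name: str, lineno: int) -> BibRecord:
    try:
        return BibRecord(
            record_id=fields.get("ID", "").strip(),
            title=fields.get("TI", "").strip(),
            abstract=_normalize_abstract(fields.get("AB")),
            iteration=int(fields.get("C1", "0")),
            label=fields.get("C2", "").strip(),
        )
    except (RecordValidationError, ValueError) as exc:
        raise RecordValidationError(f"{name}, near line {lineno}: {exc}") from exc


def write_records(
    path: str | Path, records: Sequence[BibRecord], format: str | None = None
) -> None:
    """Write records in the same dialects :func:`read_records` accepts."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".ris": "ris"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    if format in ("csv", "tsv"):
        delim = "\t" if format == "tsv" else ","
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delim)
            writer.writerow(CSV_COLUMNS)
            for rec in records:
                writer.writerow(
                    [
                        rec.record_id,
                        rec.title,
                        rec.abstract or "",
                        rec.iteration,
                        rec.label,
                    ]
                )
    elif format == "ris":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(f"TY  - {_RIS_TYPE}\n")
                fh.write(f"ID  - {rec.record_id}\n")
                fh.write(f"TI  - {rec.title}\n")
                if rec.abstract is not None:
                    fh.write(f"AB  - {rec.abstract}\n")
                fh.write(f"C1  - {rec.iteration}\n")
                fh.write(f"C2  - {rec.label}\n")
                fh.write("ER  - \n")
    else:
        raise ValueError(f"unknown format {format!r}")


def summarize_series(series: ReviewSeries) -> pd.DataFrame:
    """Per-iteration tallies of |A|, |M|, |Y| and missing abstracts.

    Returns one row per iteration with columns ``iteration, n_all, n_maybe,
    n_yes, n_missing_abstract, pct_missing_abstract`` (percentage rounded
    half-up to one decimal).  Counts honour the cumulative stage encoding:
    every Y record counts toward M and A.
    """
    if series.n_iterations == 0:
        raise RecordValidationError("cannot summarize an empty series")
    series.validate()
    rows = []
    for idx, records in enumerate(series.iterations):
        n_all = len(records)
        n_missing = sum(1 for r in records if not r.has_abstract)
        rows.append(
            {
                "iteration": idx,
                "n_all": n_all,
                "n_maybe": sum(1 for r in records if r.is_maybe),
                "n_yes": sum(1 for r in records if r.is_included),
                "n_missing_abstract": n_missing,
                "pct_missing_abstract": round_half_up(100.0 * n_missing / n_all, 1)
                if n_all
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "BibRecord",
    "ReviewSeries",
    "RecordValidationError",
    "read_records",
    "write_records",
    "summarize_series",
    "CSV_COLUMNS",
    "STAGE_LABELS",
]
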