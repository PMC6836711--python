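"""Four-block word n-gram features: {tf-idf, binary} × {unstemmed, stemmed}.

Each document (title, optionally followed by its abstract) is represented by
bag-of-n-grams with n = 1..5.  The same n-gram inventory is encoded twice —
as L2-normalized tf-idf and as binary presence indicators — and the whole
construction is repeated on Porter-stemmed tokens, giving four concatenated
sparse blocks.  No frequency cut-off, feature selection or dimension
reduction is applied: every n-gram observed in the training documents gets a
column, and unhelpful features are left for the regularized trainer to
discount.

Vocabularies and document frequencies come exclusively from the training
documents; at transform time out-of-vocabulary n-grams are ignored.  The
tf-idf variant is the smoothed form

    idf(t) = ln((1 + N) / (1 + df(t))) + 1,

with raw term counts as tf and L2 normalization per row within each tf-idf
block.  Title and abstract are joined with a field barrier so that no n-gram
spans the title/abstract boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import partial
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.preprocessing import normalize

from .records import BibRecord
from .stemming import stem_tokens

N_MAX_DEFAULT = 5

TEXT_MODES = ("title_and_abstract", "title_only")

#: fixed block concatenation order (column layout of FeatureMatrix)
BLOCKS = ("tfidf_unstemmed", "tfidf_stemmed", "binary_unstemmed", "binary_stemmed")

_FIELD_SEP = "\n"
_TOKEN_RE = re.compile(r"[0-9a-z]+")

_FORMAT_VERSION = 1


def tokenize(text: str) -> list[str]:
    """Lower-case and split on any non-alphanumeric run.

    "COS-2019 update" -> ["cos", "2019", "update"]; empty text -> [].
    """
    return _TOKEN_RE.findall(text.casefold())


def extract_ngrams(tokens: Sequence[str], n_max: int = N_MAX_DEFAULT) -> list[str]:
    """All contiguous n-grams for n = 1..n_max, space-joined, in scan order.

    A token list of length L yields sum over n of (L - n + 1) n-grams.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    out: list[str] = []
    L = len(tokens)
    for n in range(1, min(n_max, L) + 1):
        if n == 1:
            out.extend(tokens)
        else:
            out.extend(" ".join(tokens[i : i + n]) for i in range(L - n + 1))
    return out


def record_text(record: BibRecord, text_mode: str) -> str:
    """The raw text a record contributes under the given mode.

    ``title_only`` uses the title alone; ``title_and_abstract`` appends the
    abstract (when present) behind a field barrier so n-grams never span the
    title/abstract boundary.
    """
    if text_mode not in TEXT_MODES:
        raise ValueError(f"unknown text_mode {text_mode!r}, expected {TEXT_MODES}")
    if text_mode == "title_only" or record.abstract is None:
        return record.title
    return record.title + _FIELD_SEP + record.abstract


def _analyze(text: str, stem: bool, n_max: int) -> list[str]:
    """Raw text -> n-gram list, respecting field barriers.  Module-level so
    vectorizers stay picklable."""
    grams: list[str] = []
    for segment in text.split(_FIELD_SEP):
        tokens = tokenize(segment)
        if stem:
            tokens = stem_tokens(tokens)
        grams.extend(extract_ngrams(tokens, n_max))
    return grams


class FeatureSpaceError(ValueError):
    pass


@dataclass
class FeatureSpace:
    """Fitted vocabulary + idf state for the four feature blocks.

    tf-idf and binary blocks share one vocabulary per stem variant, so the
    total width is twice the sum of the two variant vocabulary sizes.
    """

    n_max: int
    text_mode: str
    vocabulary_unstemmed: dict[str, int]
    vocabulary_stemmed: dict[str, int]
    idf_unstemmed: np.ndarray
    idf_stemmed: np.ndarray

    @property
    def width(self) -> int:
        return 2 * (len(self.vocabulary_unstemmed) + len(self.vocabulary_stemmed))

    @property
    def block_slices(self) -> dict[str, slice]:
        """Column ranges of the four blocks in concatenation order."""
        sizes = [
            len(self.vocabulary_unstemmed),
            len(self.vocabulary_stemmed),
            len(self.vocabulary_unstemmed),
            len(self.vocabulary_stemmed),
        ]
        out, start = {}, 0
        for name, size in zip(BLOCKS, sizes):
            out[name] = slice(start, start + size)
            start += size
        return out

    def vocabulary(self, block: str) -> dict[str, int]:
        if block not in BLOCKS:
            raise ValueError(f"unknown block {block!r}")
        return (
            self.vocabulary_stemmed
            if block.endswith("_stemmed")
            else self.vocabulary_unstemmed
        )

    def _vectorizer(self, stem: bool) -> CountVectorizer:
        return CountVectorizer(
            analyzer=partial(_analyze, stem=stem, n_max=self.n_max),
            vocabulary=self.vocabulary_stemmed if stem else self.vocabulary_unstemmed,
        )

    # -- serialization (versioned JSON sidecar) -----------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "n_max": self.n_max,
            "text_mode": self.text_mode,
            "vocabulary_unstemmed": self.vocabulary_unstemmed,
            "vocabulary_stemmed": self.vocabulary_stemmed,
            "idf_unstemmed": self.idf_unstemmed.tolist(),
            "idf_stemmed": self.idf_stemmed.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSpace":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format_version") != _FORMAT_VERSION:
            raise FeatureSpaceError(
                f"unsupported feature-space format {payload.get('format_version')!r}"
            )
        return cls(
            n_max=payload["n_max"],
            text_mode=payload["text_mode"],
            vocabulary_unstemmed=payload["vocabulary_unstemmed"],
            vocabulary_stemmed=payload["vocabulary_stemmed"],
            idf_unstemmed=np.asarray(payload["idf_unstemmed"], dtype=np.float64),
            idf_stemmed=np.asarray(payload["idf_stemmed"], dtype=np.float64),
        )

    def fingerprint(self) -> str:
        """Stable digest identifying this fitted space (for model sidecars)."""
        import hashlib

        h = hashlib.sha256()
        h.update(f"{_FORMAT_VERSION}|{self.n_max}|{self.text_mode}".encode())
        for vocab in (self.vocabulary_unstemmed, self.vocabulary_stemmed):
            for term in sorted(vocab):
                h.update(term.encode())
                h.update(str(vocab[term]).encode())
        return h.hexdigest()[:16]


def _smooth_idf(counts: sp.csr_matrix) -> np.ndarray:
    n_docs = counts.shape[0]
    df = np.asarray((counts > 0).sum(axis=0)).ravel()
    return np.log((1.0 + n_docs) / (1.0 + df)) + 1.0


def fit_feature_space(
    training_records: Sequence[BibRecord],
    text_mode: str = "title_and_abstract",
    n_max: int = N_MAX_DEFAULT,
) -> FeatureSpace:
    """Build vocabularies and idf weights from training documents only."""
    if not training_records:
        raise FeatureSpaceError("no training records")
    texts = [record_text(r, text_mode) for r in training_records]
    space_parts = {}
    for stem in (False, True):
        cv = CountVectorizer(analyzer=partial(_analyze, stem=stem, n_max=n_max))
        try:
            counts = cv.fit_transform(texts)
        except ValueError as exc:  # sklearn: "empty vocabulary"
            raise FeatureSpaceError(
                "training records contain no tokens; cannot fit a feature space"
            ) from exc
        space_parts[stem] = (dict(cv.vocabulary_), _smooth_idf(counts))
    # np.int64 column indices -> int for JSON round-tripping
    vocab_u = {t: int(i) for t, i in space_parts[False][0].items()}
    vocab_s = {t: int(i) for t, i in space_parts[True][0].items()}
    return FeatureSpace(
        n_max=n_max,
        text_mode=text_mode,
        vocabulary_unstemmed=vocab_u,
        vocabulary_stemmed=vocab_s,
        idf_unstemmed=space_parts[False][1],
        idf_stemmed=space_parts[True][1],
    )


def transform(
    records: Sequence[BibRecord],
    space: FeatureSpace,
    text_mode: str | None = None,
) -> sp.csr_matrix:
    """Encode records on a fitted space; rows follow input order.

    ``text_mode`` overrides the space's mode (used when a model trained on
    titles+abstracts must score candidates from their titles alone).
    """
    mode = text_mode if text_mode is not None else space.text_mode
    texts = [record_text(r, mode) for r in records]
    blocks: dict[str, sp.csr_matrix] = {}
    for stem, suffix in ((False, "unstemmed"), (True, "stemmed")):
        cv = space._vectorizer(stem)
        counts = cv.transform(texts).astype(np.float64).tocsr()
        idf = space.idf_stemmed if stem else space.idf_unstemmed
        tfidf = counts.copy()
        tfidf.data = tfidf.data * idf[tfidf.indices]  # O(nnz) column scaling
        tfidf = normalize(tfidf, norm="l2", copy=False)
        binary = counts.copy()
        binary.data = np.ones_like(binary.data)
        blocks[f"tfidf_{suffix}"] = tfidf
        blocks[f"binary_{suffix}"] = binary
    return sp.hstack([blocks[name] for name in BLOCKS], format="csr")


__all__ = [
    "tokenize",
    "extract_ngrams",
    "record_text",
    "fit_feature_space",
    "transform",
    "FeatureSpace",
    "FeatureSpaceError",
    "BLOCKS",
    "TEXT_MODES",
    "N_MAX_DEFAULT",
]
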