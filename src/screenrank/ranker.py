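"""Class-weighted logistic-loss linear ranker trained by SGD.

Relevant references are rare (well under 2% of retrieved records), so the
positive class is up-weighted rather than resampled: each positive example
contributes ``positive_weight`` times as much to the loss.  The model is a
plain linear scorer w·x + b minimizing the weighted, L2-regularized logistic
loss by stochastic gradient descent for a fixed number of epochs; candidate
references are then presented in descending order of the sigmoid score
(pointwise learning-to-rank).

Training stands on :class:`sklearn.linear_model.SGDClassifier`
(``loss="log_loss"``, inverse-scaling "optimal" learning rate, seed-driven
per-epoch shuffling, no early stopping) so that two trainings with identical
inputs and seed produce bitwise-identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.linear_model import SGDClassifier

EPOCHS_DEFAULT = 50
POSITIVE_WEIGHT_DEFAULT = 80.0
L2_ALPHA_DEFAULT = 1e-4

_MODEL_FORMAT_VERSION = 1


class RankerError(ValueError):
    pass


@dataclass(frozen=True)
class RankerConfig:
    """Training hyperparameters.

    positive_weight
        loss weight of each positive example relative to a negative one;
        the default 80 compensates the class imbalance without resampling.
    l2_alpha
        L2 regularization strength (alpha in alpha * ||w||^2).
    positive_label_source
        which stage counts as the positive class: ``"Y"`` (included on full
        text, the default) or ``"M"`` (provisionally included on
        title/abstract, i.e. M and Y records are both positive).
    """

    epochs: int = EPOCHS_DEFAULT
    positive_weight: float = POSITIVE_WEIGHT_DEFAULT
    l2_alpha: float = L2_ALPHA_DEFAULT
    positive_label_source: str = "Y"
    seed: int = 0
    learning_rate: str = "invscaling"
    eta0: float = 0.01
    averaged: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise RankerError("epochs must be >= 1")
        if self.positive_weight <= 0:
            raise RankerError("positive_weight must be > 0")
        if self.l2_alpha < 0:
            raise RankerError("l2_alpha must be >= 0")
        if self.positive_label_source not in ("Y", "M"):
            raise RankerError("positive_label_source must be 'Y' or 'M'")
        if self.learning_rate not in ("invscaling", "optimal"):
            raise RankerError("learning_rate must be 'invscaling' or 'optimal'")
        if self.eta0 <= 0:
            raise RankerError("eta0 must be > 0")


@dataclass
class RankerModel:
    """Fitted linear scorer: weights aligned to the FeatureSpace column order."""

    weights: np.ndarray
    intercept: float
    config: RankerConfig
    training_summary: dict = field(default_factory=dict)
    feature_space_fingerprint: str | None = None

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    def save(self, path: str | Path) -> None:
        """Versioned NPZ sidecar pairing weights with config + space fingerprint."""
        path = Path(path)
        np.savez_compressed(
            path,
            format_version=_MODEL_FORMAT_VERSION,
            weights=self.weights,
            intercept=self.intercept,
            config=json.dumps(self.config.__dict__),
            training_summary=json.dumps(self.training_summary),
            fingerprint=self.feature_space_fingerprint or "",
        )

    @classmethod
    def load(cls, path: str | Path) -> "RankerModel":
        with np.load(path, allow_pickle=False) as data:
            if int(data["format_version"]) != _MODEL_FORMAT_VERSION:
                raise RankerError("unsupported model format version")
            fp = str(data["fingerprint"])
            return cls(
                weights=np.asarray(data["weights"], dtype=np.float64),
                intercept=float(data["intercept"]),
                config=RankerConfig(**json.loads(str(data["config"]))),
                training_summary=json.loads(str(data["training_summary"])),
                feature_space_fingerprint=fp or None,
            )


def training_loss(
    model: "RankerModel", features: sp.spmatrix, labels: np.ndarray
) -> float:
    """Mean weighted logistic loss plus the L2 penalty term."""
    z = features @ model.weights + model.intercept
    y = np.asarray(labels, dtype=np.float64)
    # log(1 + exp(-margin)) computed stably
    margins = np.where(y == 1, z, -z)
    losses = np.logaddexp(0.0, -margins)
    sample_w = np.where(y == 1, model.config.positive_weight, 1.0)
    data_term = float(np.sum(sample_w * losses) / np.sum(sample_w))
    penalty = model.config.l2_alpha * float(model.weights @ model.weights)
    return data_term + penalty


def train(
    features: sp.spmatrix, labels: Sequence[int], config: RankerConfig | None = None
) -> RankerModel:
    """Fit the weighted logistic model for exactly ``config.epochs`` epochs.

    ``labels`` is a 0/1 vector aligned to the feature rows.  Both classes
    must be present.  Deterministic given the config seed.
    """
    config = config or RankerConfig()
    y = np.asarray(labels, dtype=np.int64)
    if features.shape[0] != y.shape[0]:
        raise RankerError(
            f"feature rows ({features.shape[0]}) != labels ({y.shape[0]})"
        )
    for cls_val, name in ((1, "positive"), (0, "negative")):
        if not np.any(y == cls_val):
            raise RankerError(f"training labels contain no {name} examples")
    clf = SGDClassifier(
        loss="log_loss",
        penalty="l2",
        alpha=config.l2_alpha,
        max_iter=config.epochs,
        tol=None,  # run the full epoch budget, no early stopping
        shuffle=True,
        random_state=config.seed,
        learning_rate=config.learning_rate,
        eta0=config.eta0,
        power_t=0.5,
        average=config.averaged,
        class_weight={1: config.positive_weight, 0: 1.0},
        fit_intercept=True,
    )
    clf.fit(features, y)
    model = RankerModel(
        weights=clf.coef_.ravel().astype(np.float64),
        intercept=float(clf.intercept_[0]),
        config=config,
    )
    model.training_summary = {
        "epochs_run": int(clf.n_iter_),
        "final_training_loss": training_loss(model, features, y),
        "n_examples": int(y.shape[0]),
        "n_positive": int(y.sum()),
    }
    return model


def score(model: RankerModel, features: sp.spmatrix) -> np.ndarray:
    """Sigmoid relevance scores in (0, 1), one per feature row."""
    if features.shape[1] != model.width:
        raise RankerError(
            f"feature width {features.shape[1]} != model width {model.width}"
        )
    return expit(features @ model.weights + model.intercept)


@dataclass(frozen=True)
class RankedEntry:
    record_id: str
    score: float
    rank: int  # 1-based


@dataclass
class RankedList:
    """Scores sorted descending; ties broken by ascending record_id."""

    entries: list[RankedEntry]
    tie_break_rule: str = "descending score, ties by ascending record_id"

    @property
    def record_ids(self) -> list[str]:
        return [e.record_id for e in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.entries])

    def to_tsv(self, path: str | Path, labels: dict[str, str] | None = None) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("rank\trecord_id\tscore\tlabel\n")
            for e in self.entries:
                label = labels.get(e.record_id, "") if labels else ""
                fh.write(f"{e.rank}\t{e.record_id}\t{e.score:.10g}\t{label}\n")


def rank(record_ids: Sequence[str], scores: Sequence[float]) -> RankedList:
    """Order records by descending score (deterministic tie-break on id)."""
    ids = list(record_ids)
    s = np.asarray(scores, dtype=np.float64)
    if len(ids) != s.shape[0]:
        raise RankerError("record_ids and scores must have equal length")
    if np.isnan(s).any():
        bad = ids[int(np.flatnonzero(np.isnan(s))[0])]
        raise RankerError(f"NaN score for record {bad!r}")
    order = sorted(range(len(ids)), key=lambda i: (-s[i], ids[i]))
    entries = [
        RankedEntry(record_id=ids[i], score=float(s[i]), rank=pos + 1)
        for pos, i in enumerate(order)
    ]
    return RankedList(entries=entries)


__all__ = [
    "RankerConfig",
    "RankerModel",
    "RankedList",
    "RankedEntry",
    "RankerError",
    "train",
    "score",
    "rank",
    "training_loss",
]
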