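"""Effort-recall evaluation of a ranked, labeled candidate list.

When screeners work through a ranked list top-down and stop at rank r,

    effort(r) = TP(r) + FP(r) = r          (references screened manually)
    recall(r) = TP(r) / (TP(r) + FN(r))    (relevant references identified)

where the confusion counts treat the first r records as predicted-relevant.
Sweeping r from 1 to N traces the effort-recall curve, the screening
analogue of a ROC curve; screening in random order yields the diagonal
E[recall] = r/N as baseline.  Percentages are carried at full precision and
rounded half-up to one decimal only when reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import round_half_up

DEFAULT_CUTOFFS = (0.2, 0.25, 0.3)


class CurveError(ValueError):
    pass


@dataclass
class EffortRecallCurve:
    """Cumulative recall trajectory of a ranked 0/1-labeled list.

    ``tp_cum[r-1]`` is TP(r); ``N`` the number of candidates; ``P`` the
    number of relevant ones.  ``recall_pct`` and ``effort_pct`` are full-
    precision arrays indexed by rank-1.
    """

    tp_cum: np.ndarray
    N: int
    P: int

    @property
    def recall_pct(self) -> np.ndarray:
        return 100.0 * self.tp_cum / self.P

    @property
    def effort_abs(self) -> np.ndarray:
        return np.arange(1, self.N + 1)

    @property
    def effort_pct(self) -> np.ndarray:
        return 100.0 * self.effort_abs / self.N

    # -- summary statistics -------------------------------------------------

    def last_relevant_rank(self) -> tuple[int, float]:
        """Smallest rank reaching 100% recall, with its effort percentage
        (one decimal)."""
        r = int(np.argmax(self.tp_cum == self.P)) + 1
        return r, round_half_up(100.0 * r / self.N, 1)

    def recall_at_effort(self, effort_fraction: float) -> float:
        """Recall (%, one decimal) after screening the first
        floor(effort_fraction * N) records."""
        if not 0.0 < effort_fraction <= 1.0:
            raise CurveError(f"effort_fraction must be in (0, 1], got {effort_fraction}")
        r = math.floor(effort_fraction * self.N + 1e-9)
        if r == 0:
            return 0.0
        return round_half_up(100.0 * float(self.tp_cum[r - 1]) / self.P, 1)

    def tp_at_effort(self, effort_fraction: float) -> float:
        """TP count after screening the first floor(effort_fraction * N)
        records (integer for real curves; used for pooling across updates)."""
        if not 0.0 < effort_fraction <= 1.0:
            raise CurveError(f"effort_fraction must be in (0, 1], got {effort_fraction}")
        r = math.floor(effort_fraction * self.N + 1e-9)
        return float(self.tp_cum[r - 1]) if r else 0.0

    def effort_at_recall(self, target_recall_pct: float) -> tuple[int, float]:
        """Smallest rank achieving >= target recall, with its effort
        percentage (one decimal)."""
        if target_recall_pct > 100.0:
            raise CurveError("target recall cannot exceed 100%")
        target_tp = self.P * target_recall_pct / 100.0
        # first rank whose TP count reaches the (real-valued) target
        r = int(np.argmax(self.tp_cum >= target_tp - 1e-12)) + 1
        return r, round_half_up(100.0 * r / self.N, 1)

    def summary(self, cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> dict:
        rank_last, effort_last = self.last_relevant_rank()
        return {
            "n_candidates": self.N,
            "n_relevant": self.P,
            "last_relevant_rank": rank_last,
            "last_relevant_effort_pct": effort_last,
            "recall_at_cutoff_pct": {
                f"{round_half_up(100 * c, 0):g}": self.recall_at_effort(c)
                for c in cutoffs
            },
        }

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("rank\teffort_pct\trecall_pct\n")
            for r, e, rec in zip(self.effort_abs, self.effort_pct, self.recall_pct):
                fh.write(f"{r}\t{e:.6f}\t{rec:.6f}\n")

    def summary_json(
        self, path: str | Path, cutoffs: Sequence[float] = DEFAULT_CUTOFFS
    ) -> None:
        Path(path).write_text(
            json.dumps(self.summary(cutoffs), indent=2), encoding="utf-8"
        )


def curve_from_ranked_labels(
    labels_in_rank_order: Sequence[int],
) -> EffortRecallCurve:
    """Build the curve from the 0/1 relevance labels in ranked order."""
    labels = np.asarray(labels_in_rank_order, dtype=np.int64)
    if labels.ndim != 1 or labels.size == 0:
        raise CurveError("labels must be a non-empty 1-d sequence")
    if not np.isin(labels, (0, 1)).all():
        raise CurveError("labels must be 0/1")
    P = int(labels.sum())
    if P == 0:
        raise CurveError("no relevant records in the list; recall is undefined")
    return EffortRecallCurve(tp_cum=np.cumsum(labels), N=int(labels.size), P=P)


def random_baseline_curve(N: int, P: int) -> EffortRecallCurve:
    """Expected curve when screening in random order.

    Under a uniformly random permutation the number of relevant records in
    the first r is hypergeometric with mean P*r/N, so expected recall is
    r/N — the dashed diagonal.  Encoded as a curve with fractional expected
    TP counts.
    """
    if not 0 < P <= N:
        raise CurveError("need 0 < P <= N")
    r = np.arange(1, N + 1, dtype=np.float64)
    return EffortRecallCurve(tp_cum=P * r / N, N=N, P=P)


def last_relevant_rank(curve: EffortRecallCurve) -> tuple[int, float]:
    return curve.last_relevant_rank()


def recall_at_effort(curve: EffortRecallCurve, effort_fraction: float) -> float:
    return curve.recall_at_effort(effort_fraction)


def effort_at_recall(
    curve: EffortRecallCurve, target_recall_pct: float
) -> tuple[int, float]:
    return curve.effort_at_recall(target_recall_pct)


def plot_curves(
    curves: dict[str, EffortRecallCurve],
    path: str | Path | None = None,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    title: str | None = None,
):
    """Effort-recall plot: one line per named curve, positions of the
    relevant references marked, the random-order diagonal dashed, vertical
    lines at the screening cut-offs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve.effort_pct, curve.recall_pct, label=name, lw=1.5)
        if np.allclose(np.diff(curve.tp_cum) % 1, 0):  # integer-labeled curve
            hits = np.flatnonzero(np.diff(np.concatenate([[0], curve.tp_cum])) > 0)
            ax.plot(
                curve.effort_pct[hits], curve.recall_pct[hits], "o", ms=3, alpha=0.6
            )
    ax.plot([0, 100], [0, 100], "k--", lw=1, label="random order")
    for c in cutoffs:
        ax.axvline(100 * c, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("effort (% of candidates screened)")
    ax.set_ylabel("recall (% of relevant identified)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 102)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig, ax


__all__ = [
    "EffortRecallCurve",
    "CurveError",
    "curve_from_ranked_labels",
    "random_baseline_curve",
    "last_relevant_rank",
    "recall_at_effort",
    "effort_at_recall",
    "plot_curves",
    "DEFAULT_CUTOFFS",
]
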