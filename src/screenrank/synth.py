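"""Synthetic multi-update screening corpora with planted lexical signal.

Real screening data for review updates is rarely shareable, so the pipeline
is exercised on generated corpora that reproduce its statistical structure:
one large original review followed by smaller annual updates; very low
prevalence of included (Y) records; a larger "maybe" (M) stratum; a fraction
of records lacking abstracts; references re-screened across consecutive
iterations (planted duplicates with identical text but fresh identifiers);
and gradual drift of the relevance-bearing vocabulary between iterations.

The text model is the simplest one that makes n-gram tf-idf learning
non-trivial: background tokens drawn from a Zipf distribution over a fixed
synthetic vocabulary, plus a set of signal terms that included records
contain with high probability, "maybe" records at an intermediate rate and
background records at a low rate.  Titles are 5-15 tokens, abstracts 50-250.
Everything is reproducible from the seed, and a manifest records every
planted property.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .records import BibRecord, ReviewSeries

#: per-iteration corpus sizes shaped like a real original review + 4 updates
FULL_SHAPE = (24000, 4500, 3800, 4000, 5000)

_TITLE_LEN = (5, 15)
_ABSTRACT_LEN = (50, 250)
_TITLE_SIGNAL_PROB = 0.5  # chance a selected signal term also lands in the title
_ZIPF_EXPONENT = 1.1


class GeneratorSpecError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic corpus.

    prevalence_Y
        marginal probability a record is included on full text (~0.5-1.5%
        in real update screening; default 1%).
    maybe_multiplier
        |M| relative to |Y| (default 7: ~7% of records are provisional
        title/abstract inclusions).
    signal_terms / signal_strength / background_signal_rate
        number of relevance-indicative terms and the per-term inclusion
        probability for Y records vs irrelevant ones; M-not-Y records sit
        halfway between the two rates.
    missing_abstract_rate
        fraction of records without an abstract (default 8.4%).
    duplicate_rate
        fraction of an update's records that are re-screens of the previous
        iteration (identical text, fresh id; default 4%).
    drift_rate
        fraction of signal terms replaced between consecutive iterations,
        emulating conceptual drift (default 10%).
    """

    n_per_iteration: tuple[int, ...] = FULL_SHAPE
    prevalence_Y: float = 0.01
    maybe_multiplier: float = 7.0
    signal_terms: int = 20
    signal_strength: float = 0.6
    background_signal_rate: float = 0.02
    vocab_size: int = 2000
    missing_abstract_rate: float = 0.084
    duplicate_rate: float = 0.04
    drift_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_iteration or any(n < 1 for n in self.n_per_iteration):
            raise GeneratorSpecError("n_per_iteration must be positive integers")
        for name in (
            "prevalence_Y",
            "signal_strength",
            "background_signal_rate",
            "missing_abstract_rate",
            "duplicate_rate",
            "drift_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorSpecError(f"{name} must be in [0, 1], got {v}")
        if self.maybe_multiplier < 1.0:
            raise GeneratorSpecError("maybe_multiplier must be >= 1")
        if self.prevalence_Y * self.maybe_multiplier > 1.0:
            raise GeneratorSpecError("prevalence_Y * maybe_multiplier must be <= 1")
        if self.signal_terms < 1 or self.vocab_size < 10:
            raise GeneratorSpecError("signal_terms >= 1 and vocab_size >= 10 required")

    @classmethod
    def test_scale(cls, factor: int = 10, **overrides) -> "GeneratorSpec":
        """The default corpus shape scaled down by ``factor`` (desk-scale runs)."""
        shape = tuple(max(20, n // factor) for n in FULL_SHAPE)
        return cls(n_per_iteration=shape, **overrides)


def _zipf_sampler(vocab_size: int):
    ranks = np.arange(1, vocab_size + 1, dtype=np.float64)
    probs = ranks ** (-_ZIPF_EXPONENT)
    probs /= probs.sum()
    cum = np.cumsum(probs)

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.searchsorted(cum, rng.random(size), side="right")

    return draw


def _signal_rate(label: str, spec: GeneratorSpec) -> float:
    if label == "Y":
        return spec.signal_strength
    if label == "M":
        return spec.background_signal_rate + 0.5 * (
            spec.signal_strength - spec.background_signal_rate
        )
    return spec.background_signal_rate


def generate_series(spec: GeneratorSpec) -> tuple[ReviewSeries, dict]:
    """Generate a labeled multi-iteration corpus plus its ground-truth manifest.

    The manifest records, per iteration, the active signal terms and the
    planted duplicate pairs (source id in the earlier iteration, duplicate
    id in the later one), and echoes the generating spec.
    """
    rng = np.random.default_rng(spec.seed)
    draw_background = _zipf_sampler(spec.vocab_size)
    words = np.array([f"w{i:05d}" for i in range(spec.vocab_size)])

    signal_pool = iter(range(10 ** 6))
    signal = [f"sig{next(signal_pool):03d}" for _ in range(spec.signal_terms)]

    iterations: list[list[BibRecord]] = []
    manifest_iters = []
    serial = 0
    for t, n in enumerate(spec.n_per_iteration):
        if t > 0 and spec.drift_rate > 0:
            n_swap = int(round(spec.drift_rate * len(signal)))
            for j in rng.choice(len(signal), size=n_swap, replace=False):
                signal[int(j)] = f"sig{next(signal_pool):03d}"
        records: list[BibRecord] = []
        dup_pairs = []
        n_dup = 0
        if t > 0 and spec.duplicate_rate > 0:
            n_dup = int(rng.binomial(n, spec.duplicate_rate))
            n_dup = min(n_dup, len(iterations[t - 1]))
            sources = rng.choice(len(iterations[t - 1]), size=n_dup, replace=False)
            for s in sources:
                src = iterations[t - 1][int(s)]
                rec = BibRecord(
                    record_id=f"r{serial:06d}",
                    title=src.title,
                    abstract=src.abstract,
                    iteration=t,
                    label=src.label,
                )
                serial += 1
                records.append(rec)
                dup_pairs.append(
                    {
                        "source_id": src.record_id,
                        "duplicate_id": rec.record_id,
                        "iteration_from": t - 1,
                        "iteration_to": t,
                    }
                )
        for _ in range(n - n_dup):
            u = rng.random()
            if u < spec.prevalence_Y:
                label = "Y"
            elif u < spec.prevalence_Y * spec.maybe_multiplier:
                label = "M"
            else:
                label = "A"
            title_tokens = list(
                words[draw_background(rng, int(rng.integers(*_TITLE_LEN, endpoint=True)))]
            )
            has_abstract = rng.random() >= spec.missing_abstract_rate
            abstract_tokens = (
                list(
                    words[
                        draw_background(
                            rng, int(rng.integers(*_ABSTRACT_LEN, endpoint=True))
                        )
                    ]
                )
                if has_abstract
                else None
            )
            rate = _signal_rate(label, spec)
            for term in signal:
                if rng.random() >= rate:
                    continue
                if abstract_tokens is not None:
                    pos = int(rng.integers(0, len(abstract_tokens) + 1))
                    abstract_tokens.insert(pos, term)
                    if rng.random() < _TITLE_SIGNAL_PROB:
                        pos = int(rng.integers(0, len(title_tokens) + 1))
                        title_tokens.insert(pos, term)
                else:
                    pos = int(rng.integers(0, len(title_tokens) + 1))
                    title_tokens.insert(pos, term)
            records.append(
                BibRecord(
                    record_id=f"r{serial:06d}",
                    title=" ".join(title_tokens),
                    abstract=" ".join(abstract_tokens) if abstract_tokens else None,
                    iteration=t,
                    label=label,
                )
            )
            serial += 1
        iterations.append(records)
        manifest_iters.append(
            {
                "iteration": t,
                "n_records": n,
                "signal_terms": list(signal),
                "duplicates": dup_pairs,
            }
        )
    spec_dict = asdict(spec)
    spec_dict["n_per_iteration"] = list(spec.n_per_iteration)
    manifest = {"spec": spec_dict, "iterations": manifest_iters}
    return ReviewSeries(iterations), manifest


# ---------------------------------------------------------------------------
# hand-sized worked fixtures


def _rec(rid, title, abstract, iteration, label) -> BibRecord:
    return BibRecord(rid, title, abstract, iteration, label)


def _fixture_separable() -> dict:
    """Positives are the only records containing the token "coreset"."""
    recs = []
    fillers = [
        "plasma sodium trial",
        "knee surgery cohort",
        "infant sleep survey",
        "migraine drug study",
        "wound care audit",
        "asthma inhaler comparison",
        "diet score validation",
        "stroke rehab outcomes measure",
    ]
    for i, text in enumerate(fillers):
        recs.append(
            _rec(f"n{i:02d}", text, f"a negative report about {text}", 0, "A")
        )
    for i in range(4):
        recs.append(
            _rec(
                f"p{i:02d}",
                f"coreset development study {i}",
                f"we develop a coreset for condition {i}",
                0,
                "Y",
            )
        )
    return {
        "series": ReviewSeries.from_records(recs),
        "positive_ids": [f"p{i:02d}" for i in range(4)],
    }


def _fixture_tied_scores() -> dict:
    """Identical text everywhere: every score ties, exercising the id tie-break."""
    ids = ["z9", "a1", "m5", "b2", "x7", "c3"]
    recs = [_rec(rid, "identical title text", "identical abstract text", 0, "A")
            for rid in ids]
    recs[1] = _rec("a1", "identical title text", "identical abstract text", 0, "Y")
    return {"series": ReviewSeries.from_records(recs), "expected_order": sorted(ids)}


def _fixture_all_missing_abstracts() -> dict:
    """No abstracts anywhere: the title-only path end to end."""
    recs = []
    for i in range(8):
        recs.append(_rec(f"t0n{i}", f"background title number {i}", None, 0, "A"))
    for i in range(3):
        recs.append(_rec(f"t0p{i}", f"coreset outcome title {i}", None, 0, "Y"))
    for i in range(6):
        recs.append(_rec(f"t1n{i}", f"unrelated followup title {i}", None, 1, "A"))
    recs.append(_rec("t1p0", "new coreset outcome title", None, 1, "Y"))
    return {
        "series": ReviewSeries.from_records(recs),
        "target_positive_ids": ["t1p0"],
    }


_FIXTURES = {
    "separable": _fixture_separable,
    "tied_scores": _fixture_tied_scores,
    "all_missing_abstracts": _fixture_all_missing_abstracts,
}


def generate_worked_fixture(name: str) -> dict:
    """Tiny fixed corpora with hand-verifiable expected outputs.

    Registry: "separable", "tied_scores", "all_missing_abstracts".
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder()


__all__ = [
    "GeneratorSpec",
    "GeneratorSpecError",
    "generate_series",
    "generate_worked_fixture",
    "FULL_SHAPE",
]
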