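"""Probabilistic combination of span-extractor outputs.

Several chemical-entity extractors run over the same corpus; each
candidate span (identified by document, section and character offsets
only) gets a *signature* — the vector of indicator variables saying which
extractors predicted exactly that span. The combiner estimates, for every
realized signature s, the conditional probability that a candidate with
that signature is a true entity:

    P(entity | E_1..E_n = s)  =  precision of the derived extractor
        Y(s) = { x : x in every firing extractor, x not in any silent one }

on an annotated corpus. With n extractors there are 2^n - 1 such
parameters (the all-zero signature never produces a candidate). The
estimated table then scores candidates on new corpora; thresholding the
confidences trades precision against recall, and the full
precision-recall curve over thresholds summarises the ensemble.

The statsmodels-style surface is :class:`EnsembleCombiner` (data in,
``fit()`` out) and :class:`EnsembleResults` (the fitted table plus
scoring, thresholding, curves and a summary table); the module-level
functions expose the same steps individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import EntityMention, EvaluationResult, SpanKey

Signature = tuple[int, ...]

FALLBACK_POLICIES = ("mean-singles", "zero", "error")


@dataclass(frozen=True)
class ExtractorOutput:
    """A named extractor's predicted spans (deduplicated)."""

    extractor_name: str
    spans: frozenset[SpanKey]

    @classmethod
    def from_mentions(
        cls, name: str, mentions: Iterable[EntityMention]
    ) -> "ExtractorOutput":
        return cls(name, frozenset(m.key for m in mentions))


@dataclass
class ConditionalTable:
    """Signature -> (candidate count, gold hits, precision estimate).

    The 2^n - 1 estimable parameters of the combiner; signatures never
    realized on the estimation corpus are absent (probability missing).
    """

    extractor_order: tuple[str, ...]
    cells: dict[Signature, tuple[int, int]] = field(default_factory=dict)
    smoothing: float = 0.0

    @property
    def n(self) -> int:
        return len(self.extractor_order)

    @property
    def n_estimable(self) -> int:
        """Number of estimable signature cells: 2^n - 1."""
        return 2 ** self.n - 1

    def probability(self, sig: Signature) -> float | None:
        cell = self.cells.get(sig)
        if cell is None:
            return None
        count, hits = cell
        a = self.smoothing
        return (hits + a) / (count + 2 * a) if count or a else None

    def single_probability(self, extractor_index: int) -> float | None:
        """Marginal precision P(entity | only extractor i fired)."""
        sig = tuple(
            1 if i == extractor_index else 0 for i in range(self.n)
        )
        return self.probability(sig)

    # -- TSV round-trip (one row per signature: bits, count, hits, prob) --

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(self.extractor_order) + "\tcandidates\thits\tprobability\n")
            for sig in sorted(self.cells):
                count, hits = self.cells[sig]
                prob = self.probability(sig)
                fh.write(
                    "\t".join(str(b) for b in sig)
                    + f"\t{count}\t{hits}\t{prob:.5f}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConditionalTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[-3:] != ["candidates", "hits", "probability"]:
                raise ValueError(f"{path}: not a conditional table file")
            order = tuple(header[:-3])
            cells: dict[Signature, tuple[int, int]] = {}
            for lineno, raw in enumerate(fh, start=2):
                line = raw.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != len(order) + 3:
                    raise ValueError(f"{path}:{lineno}: wrong column count")
                sig = tuple(int(b) for b in parts[: len(order)])
                cells[sig] = (int(parts[-3]), int(parts[-2]))
        return cls(order, cells)


@dataclass(frozen=True)
class ScoredCandidate:
    """A pooled candidate span with its signature and confidence."""

    span: SpanKey
    signature: Signature
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def as_mention(self) -> EntityMention:
        doc_id, section, start, end = self.span
        return EntityMention(doc_id, section, start, end)


# ---------------------------------------------------------------------------
# Core operations

def pool_candidates(
    outputs: Sequence[ExtractorOutput],
) -> list[tuple[SpanKey, Signature]]:
    """Union all extractor outputs into (span, signature) candidates.

    Bit i of the signature is 1 iff extractor i predicted exactly that
    span; distinct spans remain distinct candidates even when they
    overlap — candidate identity is offset-based.
    """
    if not outputs:
        raise ValueError("at least one extractor output is required")
    names = [o.extractor_name for o in outputs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate extractor names: {names}")
    universe: set[SpanKey] = set()
    for o in outputs:
        universe |= o.spans
    return [
        (span, tuple(int(span in o.spans) for o in outputs))
        for span in sorted(universe)
    ]


def estimate_table(
    outputs: Sequence[ExtractorOutput],
    gold: Iterable[SpanKey] | Iterable[EntityMention],
    smoothing: float = 0.0,
) -> ConditionalTable:
    """Estimate the conditional-precision table on an annotated corpus.

    Each realized signature's probability is the precision of the derived
    extractor formed by intersecting the firing extractors' spans and
    subtracting the silent ones'. Unrealized signatures stay missing.
    ``smoothing`` adds an optional add-a correction (default 0: raw
    precisions, as reported).
    """
    candidates = pool_candidates(outputs)
    if not candidates:
        raise ValueError("empty candidate pool: no extractor produced spans")
    gold_keys = _as_span_keys(gold)
    cells: dict[Signature, tuple[int, int]] = {}
    for span, sig in candidates:
        count, hits = cells.get(sig, (0, 0))
        cells[sig] = (count + 1, hits + (1 if span in gold_keys else 0))
    return ConditionalTable(
        tuple(o.extractor_name for o in outputs), cells, smoothing
    )


def score(
    candidates: Sequence[tuple[SpanKey, Signature]],
    table: ConditionalTable,
    fallback: str = "mean-singles",
) -> list[ScoredCandidate]:
    """Assign each candidate the table probability of its signature.

    Signatures missing from the table fall back per policy:
    ``mean-singles`` (default) — unweighted mean of the single-extractor
    probabilities of the firing extractors (available ones only; 0 if
    none); ``zero`` — confidence 0; ``error`` — raise.
    """
    if fallback not in FALLBACK_POLICIES:
        raise ValueError(f"unknown fallback policy {fallback!r}")
    scored: list[ScoredCandidate] = []
    for span, sig in candidates:
        if len(sig) != table.n:
            raise ValueError(
                f"signature length {len(sig)} does not match table n={table.n}"
            )
        prob = table.probability(sig)
        if prob is None:
            if fallback == "error":
                raise KeyError(f"no estimate for signature {sig}")
            if fallback == "zero":
                prob = 0.0
            else:
                singles = [
                    p
                    for i, bit in enumerate(sig)
                    if bit
                    for p in [table.single_probability(i)]
                    if p is not None
                ]
                prob = sum(singles) / len(singles) if singles else 0.0
        scored.append(ScoredCandidate(span, sig, prob))
    return scored


def score_outputs(
    outputs: Sequence[ExtractorOutput],
    table: ConditionalTable,
    fallback: str = "mean-singles",
) -> list[ScoredCandidate]:
    """Pool fresh extractor outputs and score them against a fitted table."""
    if tuple(o.extractor_name for o in outputs) != table.extractor_order:
        raise ValueError(
            "extractor order mismatch: outputs are "
            f"{[o.extractor_name for o in outputs]}, table expects "
            f"{list(table.extractor_order)}"
        )
    return score(pool_candidates(outputs), table, fallback)


def apply_threshold(
    scored: Iterable[ScoredCandidate], tau: float
) -> list[ScoredCandidate]:
    """Retain candidates with confidence >= tau."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"threshold {tau} outside [0, 1]")
    return [c for c in scored if c.confidence >= tau]


def pr_curve(
    scored: Sequence[ScoredCandidate],
    gold: Iterable[SpanKey] | Iterable[EntityMention],
) -> list[tuple[float, float, float, float]]:
    """Precision/recall/F1 at every distinct confidence threshold.

    Rows are (tau, precision, recall, f1) sorted by tau ascending,
    evaluated at each distinct confidence plus the endpoints 0 and 1,
    with exact-span micro-averaged scoring.
    """
    gold_keys = _as_span_keys(gold)
    taus = sorted({c.confidence for c in scored} | {0.0, 1.0})
    rows: list[tuple[float, float, float, float]] = []
    for tau in taus:
        retained = {c.span for c in scored if c.confidence >= tau}
        tp = len(retained & gold_keys)
        res = EvaluationResult(
            true_positives=tp,
            false_positives=len(retained) - tp,
            false_negatives=len(gold_keys) - tp,
        )
        rows.append((tau, res.precision, res.recall, res.f1))
    return rows


def _as_span_keys(gold) -> set[SpanKey]:
    keys: set[SpanKey] = set()
    for g in gold:
        keys.add(g.key if isinstance(g, EntityMention) else tuple(g))
    return keys


# ---------------------------------------------------------------------------
# Model / Results surface

class EnsembleCombiner:
    """The ensemble model: extractor outputs plus gold annotations.

    ``fit()`` estimates the conditional-precision table (the model's
    2^n - 1 parameters) and returns an :class:`EnsembleResults`.
    """

    def __init__(
        self,
        outputs: Sequence[ExtractorOutput],
        gold: Iterable[SpanKey] | Iterable[EntityMention],
        smoothing: float = 0.0,
    ):
        if not outputs:
            raise ValueError("at least one extractor output is required")
        self.outputs = list(outputs)
        self.gold = _as_span_keys(gold)
        self.smoothing = smoothing

    @classmethod
    def from_files(
        cls, gold_path: str | Path, prediction_paths: Sequence[str | Path],
        names: Sequence[str] | None = None, smoothing: float = 0.0,
    ) -> "EnsembleCombiner":
        from .corpus import read_annotations

        outputs = [
            ExtractorOutput.from_mentions(
                names[i] if names else Path(p).stem, read_annotations(p)
            )
            for i, p in enumerate(prediction_paths)
        ]
        return cls(outputs, read_annotations(gold_path), smoothing)

    def fit(self) -> "EnsembleResults":
        table = estimate_table(self.outputs, self.gold, self.smoothing)
        return EnsembleResults(self, table)


@dataclass
class EnsembleResults:
    """A fitted ensemble: the conditional table plus scoring utilities."""

    model: EnsembleCombiner
    table: ConditionalTable

    def score(
        self,
        outputs: Sequence[ExtractorOutput] | None = None,
        fallback: str = "mean-singles",
    ) -> list[ScoredCandidate]:
        """Score a (possibly new) corpus's extractor outputs.

        With no arguments, scores the estimation corpus itself; passing
        fresh outputs mirrors estimating on one dataset and applying the
        estimates to another.
        """
        return score_outputs(outputs or self.model.outputs, self.table, fallback)

    def apply_threshold(self, tau: float, **kwargs) -> list[ScoredCandidate]:
        return apply_threshold(self.score(**kwargs), tau)

    def pr_curve(
        self,
        outputs: Sequence[ExtractorOutput] | None = None,
        gold: Iterable[SpanKey] | Iterable[EntityMention] | None = None,
    ) -> list[tuple[float, float, float, float]]:
        scored = self.score(outputs)
        gold_keys = self.model.gold if gold is None else gold
        return pr_curve(scored, gold_keys)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Ensemble conditional-precision table",
            "=" * 46,
            f"extractors ({t.n}): " + ", ".join(t.extractor_order),
            f"estimable parameters (2^n - 1): {t.n_estimable}",
            f"realized signatures: {len(t.cells)}",
            "",
            "\t".join(t.extractor_order) + "\tcandidates\thits\tprobability",
        ]
        for sig in sorted(t.cells):
            count, hits = t.cells[sig]
            lines.append(
                "\t".join(str(b) for b in sig)
                + f"\t{count}\t{hits}\t{t.probability(sig):.5f}"
            )
        return "\n".join(lines)

    def plot_pr_curve(self, ax=None, **kwargs):
        """Plot the precision-recall curve (matplotlib, optional)."""
        import matplotlib.pyplot as plt

        rows = self.pr_curve(**kwargs)
        if ax is None:
            _, ax = plt.subplots()
        recalls = [r for _, _, r, _ in rows]
        precisions = [p for _, p, _, _ in rows]
        ax.plot(recalls, precisions, marker="o")
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.set_title("Ensemble precision-recall over confidence thresholds")
        return ax
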