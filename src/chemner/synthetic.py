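"""Seeded synthetic corpora with planted chemical mentions, plus
simulated extractor outputs with a known conditional-precision structure.

The corpus generator emulates the shape of an annotated abstract corpus:
short documents (title + abstract) of filler prose with embedded
chemical-like mentions built from a fragment grammar (alkane-style stems
and suffixes, and formula tokens such as ``CO2`` and ``C2H5OH`` that
satisfy the no-two-consecutive-lowercase heuristic). Every mention is
whitespace-delimited by construction, so gold spans are token-aligned
under the default tokenizer and offsets are exact.

The extractor simulator is the generative inverse of conditional-
precision estimation: it fabricates candidate spans cell by cell, assigns
them to extractors according to the cell's signature, and marks a known
fraction gold — exactly (``exact`` mode) or i.i.d. (``stochastic`` mode)
— so the estimator's output can be checked against the generating table.

All randomness flows through one explicitly seeded generator; identical
configurations produce byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Document, EntityMention, SpanKey
from .ensemble import ConditionalTable, ExtractorOutput, Signature
from .features import ClusterMap

# ---------------------------------------------------------------------------
# Vocabulary grammar

_STEMS = ["meth", "eth", "prop", "but", "pent", "hex", "hept", "oct"]
_SUFFIXES = ["ane", "anol", "ylene", "oate", "ene", "yne", "anal", "anone"]
_PREFIXES = ["", "di", "tri", "cyclo", "iso", "neo", "poly", "per"]
_SECOND_WORDS = ["acid", "chloride", "oxide", "sulfate", "nitrate", "ester"]
_ELEMENTS = ["C", "H", "O", "N", "S", "Na", "Cl", "K", "Ca", "Fe"]

_FILLERS = (
    "the of and in to with for was were is are on by from at as an a "
    "study results measured observed reaction sample samples analysis "
    "method using during after before under between effect levels "
    "increased decreased significant treatment control group patients "
    "cells activity concentration solution mixture reported found shown "
    "present data values compared obtained performed determined"
).split()

_OPENERS = ["The", "We", "This", "These", "Our", "A"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate short abstracts with roughly one chemical mention
    per sentence, a fifth of mentions spanning two words and a quarter
    being formula-like tokens.
    """

    n_docs: int = 100
    seed: int = 0
    vocab_size: int = 120
    mention_rate: float = 1.0
    multiword_fraction: float = 0.2
    formula_fraction: float = 0.25
    sentences_per_doc: int = 4
    gazetteer_fraction: float = 0.7
    cluster_count: int = 50

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        for name in ("multiword_fraction", "formula_fraction", "gazetteer_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mention_rate < 0:
            raise ValueError("mention_rate must be non-negative")


def chemical_vocabulary(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    """Deterministic (names, formulas) chemical vocabulary for a config."""
    names = [
        p + s + suf for p in _PREFIXES for s in _STEMS for suf in _SUFFIXES
    ]
    rng = np.random.default_rng(config.seed + 1)
    n_formula = max(1, int(config.vocab_size * config.formula_fraction))
    n_names = max(1, config.vocab_size - n_formula)
    name_pick = [names[i] for i in rng.choice(len(names), size=min(n_names, len(names)), replace=False)]
    formulas: list[str] = []
    seen: set[str] = set()
    while len(formulas) < n_formula:
        k = int(rng.integers(2, 4))
        parts = []
        for el in rng.choice(_ELEMENTS, size=k, replace=False):
            count = int(rng.integers(1, 6))
            parts.append(el + (str(count) if count > 1 else ""))
        f = "".join(parts)
        if f not in seen:
            seen.add(f)
            formulas.append(f)
    return name_pick, formulas


@dataclass
class SyntheticCorpus:
    """The generator's output bundle."""

    documents: list[Document]
    gold: list[EntityMention]
    cluster_map: ClusterMap
    gazetteer_terms: list[str]
    chemical_vocab: list[str] = field(default_factory=list)


def gen_corpus(config: GeneratorConfig | None = None, **kwargs) -> SyntheticCorpus:
    """Generate a seeded corpus with exact, token-aligned gold offsets."""
    config = config or GeneratorConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    names, formulas = chemical_vocabulary(config)
    vocab = names + formulas

    documents: list[Document] = []
    gold: list[EntityMention] = []

    def draw_mention() -> str:
        if rng.random() < config.multiword_fraction:
            head = names[int(rng.integers(len(names)))]
            tail = _SECOND_WORDS[int(rng.integers(len(_SECOND_WORDS)))]
            return f"{head} {tail}"
        pool = formulas if rng.random() < config.formula_fraction else names
        return pool[int(rng.integers(len(pool)))]

    def build_sentence(mentions_out: list[tuple[int, str]]) -> str:
        """One sentence; appends (relative_offset, text) for each mention."""
        n_mentions = int(rng.poisson(config.mention_rate))
        n_fillers = int(rng.integers(5, 10))
        words = [_OPENERS[int(rng.integers(len(_OPENERS)))]]
        words += [_FILLERS[int(rng.integers(len(_FILLERS)))] for _ in range(n_fillers)]
        positions = sorted(
            int(p) for p in rng.integers(1, len(words) + 1, size=n_mentions)
        )
        for shift, pos in enumerate(positions):
            words.insert(pos + shift, draw_mention())
        text_parts: list[str] = []
        offset = 0
        for w in words:
            is_mention = (w in vocab) or (
                " " in w and w.split(" ")[0] in names and w.split(" ")[1] in _SECOND_WORDS
            )
            if is_mention:
                mentions_out.append((offset, w))
            text_parts.append(w)
            offset += len(w) + 1
        return " ".join(text_parts) + "."

    for d in range(config.n_docs):
        doc_id = f"SYN{config.seed}-{d:05d}"
        title_mentions: list[tuple[int, str]] = []
        title = build_sentence(title_mentions)
        abs_sentences: list[str] = []
        abs_mentions: list[tuple[int, str]] = []
        offset = 0
        for _ in range(config.sentences_per_doc):
            local: list[tuple[int, str]] = []
            sent = build_sentence(local)
            abs_mentions.extend((offset + o, t) for o, t in local)
            abs_sentences.append(sent)
            offset += len(sent) + 1
        abstract = " ".join(abs_sentences)
        documents.append(Document(doc_id, title, abstract))
        for o, t in title_mentions:
            gold.append(EntityMention(doc_id, "T", o, o + len(t), t))
        for o, t in abs_mentions:
            gold.append(EntityMention(doc_id, "A", o, o + len(t), t))

    all_chem_terms = sorted(set(vocab) | set(_SECOND_WORDS))
    cluster_map = gen_cluster_map(
        all_chem_terms + _FILLERS + [w.lower() for w in _OPENERS],
        k=config.cluster_count,
        seed=config.seed + 2,
        chemical_terms=all_chem_terms,
    )
    n_gaz = int(round(config.gazetteer_fraction * len(all_chem_terms)))
    gaz_idx = np.random.default_rng(config.seed + 3).choice(
        len(all_chem_terms), size=n_gaz, replace=False
    )
    gazetteer_terms = sorted(all_chem_terms[i] for i in gaz_idx)
    return SyntheticCorpus(documents, gold, cluster_map, gazetteer_terms, vocab)


N_CHEMICAL_CLUSTERS = 5


def gen_cluster_map(
    vocab: Sequence[str],
    k: int,
    seed: int = 0,
    chemical_terms: Sequence[str] = (),
) -> ClusterMap:
    """Seeded cluster assignment emulating embedding clusters.

    Chemical terms are concentrated in the first few dedicated cluster
    ids, mirroring the empirical observation that embedding clusters
    separate chemical entities from ordinary prose; all other vocabulary
    is scattered over the remaining ids.
    """
    if k < 2:
        raise ValueError("cluster count k must be >= 2")
    rng = np.random.default_rng(seed)
    chem = set(chemical_terms)
    n_chem_clusters = min(N_CHEMICAL_CLUSTERS, k - 1)
    mapping: dict[str, int] = {}
    for term in vocab:
        if term in chem:
            mapping[term] = int(rng.integers(0, n_chem_clusters))
        else:
            mapping[term] = int(rng.integers(n_chem_clusters, k))
    return ClusterMap(mapping, k)


# ---------------------------------------------------------------------------
# Extractor simulation

@dataclass
class SimulationSpec:
    """Generative twin of the conditional table.

    ``cells`` maps each signature to (candidate count, true fraction q):
    the simulator will fabricate that many candidate spans with that
    signature and make a q-fraction of them gold.
    """

    extractor_names: tuple[str, ...]
    cells: dict[Signature, tuple[int, float]]
    mode: str = "exact"  # exact | stochastic

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.cells:
            raise ValueError("at least one cell is required")
        n = len(self.extractor_names)
        for sig, (count, q) in self.cells.items():
            if len(sig) != n:
                raise ValueError(f"signature {sig} length != {n}")
            if not any(sig):
                raise ValueError("all-zero signature cannot produce candidates")
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"true fraction {q} outside [0, 1]")
            if count < 0:
                raise ValueError("cell counts must be non-negative")

    @classmethod
    def full_table(
        cls,
        extractor_names: Sequence[str],
        count_per_cell: int,
        probabilities: Sequence[float] | None = None,
        mode: str = "exact",
        seed: int = 0,
    ) -> "SimulationSpec":
        """A spec with every non-zero signature populated.

        Without explicit probabilities, cell q values are drawn uniformly
        from [0.05, 0.95] with the given seed.
        """
        names = tuple(extractor_names)
        n = len(names)
        sigs = [
            tuple((m >> i) & 1 for i in range(n)) for m in range(1, 2 ** n)
        ]
        if probabilities is None:
            rng = np.random.default_rng(seed)
            probabilities = [float(q) for q in rng.uniform(0.05, 0.95, len(sigs))]
        cells = {
            sig: (count_per_cell, probabilities[i]) for i, sig in enumerate(sigs)
        }
        return cls(names, cells, mode)


def simulate_extractors(
    spec: SimulationSpec, seed: int = 0
) -> tuple[list[ExtractorOutput], set[SpanKey], ConditionalTable]:
    """Fabricate extractor outputs realizing the spec's table.

    Returns the per-extractor span sets, the gold span set, and the
    realized true table (counts and hits actually planted, which in
    stochastic mode differ from the spec's q by sampling noise).
    """
    rng = np.random.default_rng(seed)
    n = len(spec.extractor_names)
    out_spans: list[set[SpanKey]] = [set() for _ in range(n)]
    gold: set[SpanKey] = set()
    realized: dict[Signature, tuple[int, int]] = {}
    serial = 0
    for sig in sorted(spec.cells):
        count, q = spec.cells[sig]
        hits = 0
        if spec.mode == "exact":
            n_gold = int(round(q * count))
            gold_flags = np.zeros(count, dtype=bool)
            gold_flags[:n_gold] = True
            gold_flags = gold_flags[rng.permutation(count)]
        else:
            gold_flags = rng.random(count) < q
        for j in range(count):
            span: SpanKey = (f"sim{serial:07d}", "A", 0, 3)
            serial += 1
            for i, bit in enumerate(sig):
                if bit:
                    out_spans[i].add(span)
            if gold_flags[j]:
                gold.add(span)
                hits += 1
        if count:
            realized[sig] = (count, hits)
    outputs = [
        ExtractorOutput(name, frozenset(spans))
        for name, spans in zip(spec.extractor_names, out_spans)
    ]
    true_table = ConditionalTable(spec.extractor_names, realized)
    return outputs, gold, true_table


# ---------------------------------------------------------------------------
# Small-corpus embedding-cluster training (integration utility)

def train_cluster_map(
    documents: Sequence[Document],
    k: int = 50,
    dim: int = 30,
    window: int = 2,
    seed: int = 0,
    tokenizer: str = "chem",
) -> ClusterMap:
    """Train term clusters from a small corpus.

    A count-based stand-alone pipeline: windowed co-occurrence counts ->
    positive PMI weighting -> truncated SVD embedding -> K-Means cluster
    ids. Suitable for integration tests on generated corpora; real
    deployments load a cluster map trained offline on a large
    domain corpus.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import TruncatedSVD
    import scipy.sparse as sp

    from .tokenization import tokenize_document

    token_seqs: list[list[str]] = []
    for doc in documents:
        for sents in tokenize_document(doc, tokenizer).values():
            for sent in sents:
                token_seqs.append([t.surface.lower() for t in sent])
    vocab: dict[str, int] = {}
    for seq in token_seqs:
        for w in seq:
            vocab.setdefault(w, len(vocab))
    if len(vocab) < k:
        raise ValueError(f"vocabulary ({len(vocab)}) smaller than k ({k})")
    rows, cols = [], []
    for seq in token_seqs:
        for i, w in enumerate(seq):
            wi = vocab[w]
            for j in range(max(0, i - window), min(len(seq), i + window + 1)):
                if j != i:
                    rows.append(wi)
                    cols.append(vocab[seq[j]])
    V = len(vocab)
    C = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(V, V)
    ).tocsr()
    total = C.sum()
    row_sums = np.asarray(C.sum(axis=1)).ravel()
    col_sums = np.asarray(C.sum(axis=0)).ravel()
    C = C.tocoo()
    pmi = np.log(
        (C.data * total) / (row_sums[C.row] * col_sums[C.col])
    )
    pmi = np.maximum(pmi, 0.0)
    M = sp.coo_matrix((pmi, (C.row, C.col)), shape=(V, V)).tocsr()
    dim = min(dim, V - 1)
    emb = TruncatedSVD(n_components=dim, random_state=seed).fit_transform(M)
    ids = KMeans(n_clusters=k, random_state=seed, n_init=4).fit_predict(emb)
    return ClusterMap({w: int(ids[i]) for w, i in vocab.items()}, k)
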