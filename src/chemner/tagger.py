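"""End-to-end CRF chemical-entity tagger: model and results objects.

:class:`ChemTagger` holds a corpus (documents plus gold span annotations),
a feature configuration and a tokenizer choice; :meth:`ChemTagger.fit`
trains the underlying linear-chain CRF and returns a
:class:`TaggerResults` that tags new documents, reports training
diagnostics and round-trips through JSON model files.

The pipeline is: sentence detection -> tokenization -> feature assembly
-> Viterbi decoding -> BIO span decoding. No post-processing or
abbreviation matching is applied; an optional blacklist filter (off by
default) can remove exact surface matches known to be false positives.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document, EntityMention, mentions_by_section
from .crf import LinearChainCRF
from .features import (
    ClusterMap,
    FeatureConfig,
    Gazetteer,
    assemble_features,
    decode_bio,
    label_bio,
)
from .tokenization import DEFAULT_TOKENIZER, tokenize_document

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingConfig:
    """Optimiser settings for CRF training.

    L-BFGS with an L2 (Gaussian prior) penalty; ``seed`` is kept for
    interface stability — training itself is deterministic from the data.
    """

    max_iterations: int = 100
    l2_penalty: float = 1.0
    optimizer: str = "L-BFGS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")
        if self.optimizer != "L-BFGS":
            raise ValueError("only L-BFGS training is supported")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = {"max_iterations", "l2_penalty", "optimizer", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown training config keys: {sorted(unknown)}")
        return cls(**d)


class ChemTagger:
    """Chemical NER model specification bound to a training corpus."""

    def __init__(
        self,
        documents: Sequence[Document],
        annotations: Iterable[EntityMention],
        feature_config: FeatureConfig | None = None,
        tokenizer: str = DEFAULT_TOKENIZER,
        cluster_map: ClusterMap | None = None,
        gazetteers: Sequence[Gazetteer] = (),
    ):
        self.documents = list(documents)
        self.annotations = list(annotations)
        self.feature_config = feature_config or FeatureConfig()
        self.tokenizer = tokenizer
        self.cluster_map = cluster_map
        self.gazetteers = list(gazetteers)

    def _prepare_sentences(self):
        """Tokenize, featurise and BIO-label the whole training corpus."""
        gold = mentions_by_section(self.annotations)
        sentences: list[list[set[str]]] = []
        label_seqs: list[list[str]] = []
        misaligned = 0
        n_b = 0
        for doc in self.documents:
            by_section = tokenize_document(doc, self.tokenizer)
            for section, sents in by_section.items():
                section_gold = gold.get((doc.doc_id, section), [])
                for toks in sents:
                    lo, hi = toks[0].start, toks[-1].end
                    in_sent = [m for m in section_gold if lo <= m.start and m.end <= hi]
                    labels, bad = label_bio(toks, in_sent)
                    misaligned += bad
                    n_b += labels.count("B")
                    feats = assemble_features(
                        toks, self.feature_config, self.cluster_map, self.gazetteers
                    )
                    sentences.append(feats)
                    label_seqs.append(labels)
        return sentences, label_seqs, misaligned, n_b

    def fit(self, training_config: TrainingConfig | None = None) -> "TaggerResults":
        """Train the CRF and return the fitted results object."""
        cfg = training_config or TrainingConfig()
        t0 = time.perf_counter()
        sentences, label_seqs, misaligned, n_b = self._prepare_sentences()
        if not sentences or n_b == 0:
            raise ValueError(
                "no usable training sentences: corpus contains no token-aligned "
                f"entity mentions ({misaligned} misaligned)"
            )
        crf = LinearChainCRF()
        crf.fit(
            sentences,
            label_seqs,
            l2_penalty=cfg.l2_penalty,
            max_iterations=cfg.max_iterations,
        )
        elapsed = time.perf_counter() - t0
        return TaggerResults(
            model=self,
            crf=crf,
            training_config=cfg,
            diagnostics={
                "n_sentences": len(sentences),
                "n_tokens": sum(len(s) for s in sentences),
                "n_features": len(crf.feature_index),
                "n_b_labels": n_b,
                "misaligned_mentions": misaligned,
                "iterations": crf.n_iter_,
                "converged": crf.converged_,
                "train_seconds": round(elapsed, 2),
            },
        )


@dataclass
class TaggerResults:
    """A fitted chemical tagger: decoding, diagnostics and persistence."""

    model: ChemTagger
    crf: LinearChainCRF
    training_config: TrainingConfig
    diagnostics: dict = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()

    def tag(
        self, document: Document, use_blacklist: bool = False
    ) -> list[tuple[EntityMention, float]]:
        """Tag one document, returning (mention, confidence) pairs.

        Confidence is the product of the per-token marginal probabilities
        of the decoded labels over the mention's tokens — a sequence-level
        certainty score in [0, 1]. With ``use_blacklist`` the configured
        surface-form blacklist removes exact matches (off by default).
        """
        if not self.crf.is_fitted:
            raise RuntimeError("model is not trained")
        m = self.model
        out: list[tuple[EntityMention, float]] = []
        by_section = tokenize_document(document, m.tokenizer)
        for section, sents in by_section.items():
            text = document.section_text(section)
            for toks in sents:
                feats = assemble_features(
                    toks, m.feature_config, m.cluster_map, m.gazetteers
                )
                labels = self.crf.viterbi(feats)
                marg = self.crf.marginals(feats)
                lab_idx = {lab: i for i, lab in enumerate(self.crf.labels)}
                mentions = decode_bio(
                    toks, labels, document.doc_id, section, source_text=text
                )
                for mention in mentions:
                    conf = 1.0
                    for t, (tok, lab) in enumerate(zip(toks, labels)):
                        if mention.start <= tok.start and tok.end <= mention.end:
                            conf *= float(marg[t, lab_idx[lab]])
                    conf = min(max(conf, 0.0), 1.0)
                    if use_blacklist and mention.text in self.blacklist:
                        continue
                    out.append((mention, conf))
        return out

    def tag_corpus(
        self, documents: Iterable[Document], use_blacklist: bool = False
    ) -> list[tuple[EntityMention, float]]:
        out: list[tuple[EntityMention, float]] = []
        for doc in documents:
            out.extend(self.tag(doc, use_blacklist=use_blacklist))
        return out

    def with_blacklist(self, surfaces: Iterable[str]) -> "TaggerResults":
        return TaggerResults(
            self.model, self.crf, self.training_config, self.diagnostics,
            frozenset(surfaces),
        )

    def summary(self) -> str:
        d = self.diagnostics
        fc = self.model.feature_config
        lines = [
            "Chemical CRF tagger",
            "=" * 40,
            f"tokenizer:            {self.model.tokenizer}",
            f"sentences trained:    {d.get('n_sentences', '?')}",
            f"tokens trained:       {d.get('n_tokens', '?')}",
            f"features:             {d.get('n_features', '?')}",
            f"B labels:             {d.get('n_b_labels', '?')}",
            f"misaligned mentions:  {d.get('misaligned_mentions', '?')}",
            f"L-BFGS iterations:    {d.get('iterations', '?')}"
            f" (converged: {d.get('converged', '?')})",
            f"L2 penalty:           {self.training_config.l2_penalty}",
            "feature families:     "
            + ", ".join(
                name
                for name, on in [
                    ("nlp", fc.use_nlp),
                    ("word2vec", fc.use_word2vec),
                    (f"soundex({fc.soundex_len})", fc.use_soundex),
                    ("gazetteers", fc.use_gazetteers),
                ]
                if on
            ),
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise the fitted tagger (weights + configuration) to JSON.

        The feature configuration and tokenizer name travel with the
        weights so tagging always reuses the training-time settings.
        """
        state = {
            "format_version": MODEL_FORMAT_VERSION,
            "tokenizer": self.model.tokenizer,
            "feature_config": self.model.feature_config.as_dict(),
            "training_config": {
                "max_iterations": self.training_config.max_iterations,
                "l2_penalty": self.training_config.l2_penalty,
                "optimizer": self.training_config.optimizer,
                "seed": self.training_config.seed,
            },
            "cluster_map": (
                None
                if self.model.cluster_map is None
                else {"k": self.model.cluster_map.k,
                      "mapping": self.model.cluster_map.mapping}
            ),
            "gazetteers": [
                {"name": g.name, "match_mode": g.match_mode, "boost": g.boost,
                 "entries": sorted(list(e) for e in g.entries)}
                for g in self.model.gazetteers
            ],
            "blacklist": sorted(self.blacklist),
            "diagnostics": self.diagnostics,
            "crf": self.crf.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TaggerResults":
        try:
            with open(path, encoding="utf-8") as fh:
                state = json.load(fh)
        except (json.JSONDecodeError, OSError) as exc:
            raise ValueError(f"cannot load model from {path}: {exc}") from exc
        version = state.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version mismatch: file has {version!r}, "
                f"expected {MODEL_FORMAT_VERSION}"
            )
        cm = state.get("cluster_map")
        cluster_map = (
            None if cm is None else ClusterMap(dict(cm["mapping"]), cm["k"])
        )
        gazetteers = [
            Gazetteer(
                g["name"],
                frozenset(tuple(e) for e in g["entries"]),
                g["match_mode"],
                g.get("boost", False),
            )
            for g in state.get("gazetteers", [])
        ]
        model = ChemTagger(
            documents=[],
            annotations=[],
            feature_config=FeatureConfig.from_dict(state["feature_config"]),
            tokenizer=state["tokenizer"],
            cluster_map=cluster_map,
            gazetteers=gazetteers,
        )
        return cls(
            model=model,
            crf=LinearChainCRF.from_dict(state["crf"]),
            training_config=TrainingConfig.from_dict(state["training_config"]),
            diagnostics=state.get("diagnostics", {}),
            blacklist=frozenset(state.get("blacklist", [])),
        )


def train(
    documents: Sequence[Document],
    annotations: Iterable[EntityMention],
    feature_config: FeatureConfig | None = None,
    training_config: TrainingConfig | None = None,
    **kwargs,
) -> TaggerResults:
    """Functional wrapper: build a :class:`ChemTagger` and fit it."""
    return ChemTagger(
        documents, annotations, feature_config=feature_config, **kwargs
    ).fit(training_config)
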