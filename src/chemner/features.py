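"""Token feature extraction and BIO label handling for the CRF tagger.

Each token is represented by a set of binary presence features drawn from
several families:

* surface features — the word itself and its lowercase form;
* shape predicates — capitalisation pattern, digits, signs, dashes;
* character n-grams (n = 2, 3, 4);
* a formula heuristic — set when no two consecutive characters are
  lowercase letters, which flags formula-like tokens such as ``CO2``;
* word-class conversion — per-character A/a/0/x shape, full and collapsed;
* Soundex — a phonetic surname code repurposed for chemistry, because
  families of chemical names (carbon, carbonate, carbonic, carbonyl) sound
  alike and share a code;
* word-embedding cluster ids — linking unseen test terms to training
  terms that fell into the same embedding cluster;
* gazetteer lookups — membership of the token (or a covering token run)
  in chemical dictionaries, affix lists and boost-term lists.

Neighbouring tokens contribute selected feature families within a small
window, re-keyed with their relative offset (``word[-1]=...``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import EntityMention
from .tokenization import Token

# ---------------------------------------------------------------------------
# Soundex

# American Soundex consonant classes; A,E,I,O,U,H,W,Y carry no code.
_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}

#: Sentinel code for tokens with no alphabetic characters (e.g. "2,4" or "+").
SOUNDEX_EMPTY = "#"


def soundex(word: str, max_digits: int = 7) -> str:
    """American Soundex code with a configurable digit budget.

    The code is the uppercased first letter followed by consonant-class
    digits. Adjacent letters with equal codes collapse to one digit, as do
    equal codes separated only by H or W; vowels (and Y) break such runs.
    Letters whose code equals the first letter's code and immediately
    follow it are skipped. Digits beyond ``max_digits`` are ignored and
    codes are not zero-padded, so ``soundex("carbon", 3)`` and
    ``soundex("carbonate", 3)`` both give ``"C615"`` while the full codes
    differ.

    Non-alphabetic characters are stripped first; a word with no letters
    maps to the sentinel ``"#"``.
    """
    if max_digits < 1:
        raise ValueError("max_digits must be >= 1")
    letters = [ch for ch in word.upper() if "A" <= ch <= "Z"]
    if not letters:
        return SOUNDEX_EMPTY
    first = letters[0]
    digits: list[str] = []
    last_code = _SOUNDEX_CODES.get(first)
    for ch in letters[1:]:
        code = _SOUNDEX_CODES.get(ch)
        if code is None:
            # H and W are transparent; vowels and Y reset the run
            if ch not in "HW":
                last_code = None
            continue
        if code != last_code:
            digits.append(code)
            if len(digits) >= max_digits:
                break
        last_code = code
    return first + "".join(digits)


# ---------------------------------------------------------------------------
# Word class

def word_class(word: str) -> tuple[str, str]:
    """Per-character shape: uppercase -> A, lowercase -> a, digit -> 0,
    other -> x. Returns the full pattern and the run-collapsed brief form."""
    full_chars: list[str] = []
    for ch in word:
        if ch.isupper():
            full_chars.append("A")
        elif ch.islower():
            full_chars.append("a")
        elif ch.isdigit():
            full_chars.append("0")
        else:
            full_chars.append("x")
    full = "".join(full_chars)
    brief_chars: list[str] = []
    for ch in full:
        if not brief_chars or brief_chars[-1] != ch:
            brief_chars.append(ch)
    return full, "".join(brief_chars)


def is_formula_like(word: str) -> bool:
    """Formula heuristic: true when no two consecutive characters are
    lowercase letters."""
    return not any(
        word[i].islower() and word[i + 1].islower() for i in range(len(word) - 1)
    )


# ---------------------------------------------------------------------------
# Cluster map

@dataclass
class ClusterMap:
    """Term -> embedding-cluster-id lookup table.

    Lookup tries the exact surface first, then the lowercased form;
    absent terms yield no value (never a default id), so the cluster
    feature is simply not set for out-of-vocabulary terms.
    """

    mapping: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        bad = [t for t, c in self.mapping.items() if not (0 <= c < self.k)]
        if bad:
            raise ValueError(f"cluster ids out of range [0, {self.k}): {bad[:5]}")

    def lookup(self, term: str) -> int | None:
        cid = self.mapping.get(term)
        if cid is None:
            cid = self.mapping.get(term.lower())
        return cid

    @classmethod
    def from_tsv(cls, path: str | Path, k: int | None = None) -> "ClusterMap":
        mapping: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                mapping[parts[0]] = int(parts[1])
        if k is None:
            k = max(mapping.values(), default=0) + 1
        return cls(mapping, k)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self.mapping):
                fh.write(f"{term}\t{self.mapping[term]}\n")


def cluster_feature(word: str, cluster_map: ClusterMap | None) -> str | None:
    """``cluster=<id>`` feature, or None when the term has no cluster id."""
    if cluster_map is None:
        return None
    cid = cluster_map.lookup(word)
    return None if cid is None else f"cluster={cid}"


# ---------------------------------------------------------------------------
# Gazetteers

@dataclass
class Gazetteer:
    """A dictionary of known terms used for lookup features.

    ``token`` mode entries are tokenized term sequences (multi-term
    dictionary entries would otherwise never match unigram tokens);
    ``prefix``/``suffix`` mode entries are surface affix strings;
    ``boost`` marks a boost-term list whose matches emit a bare ``boost``
    feature.
    """

    name: str
    entries: frozenset[tuple[str, ...]]
    match_mode: str = "token"  # token | prefix | suffix
    boost: bool = False

    _members: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.match_mode not in ("token", "prefix", "suffix"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        members = frozenset(
            tok.lower() for entry in self.entries for tok in entry
        )
        object.__setattr__(self, "_members", members)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        name: str | None = None,
        match_mode: str = "token",
        boost: bool = False,
        tokenizer: str = "chem",
    ) -> "Gazetteer":
        """Load a plain-text term list (one term per line, UTF-8).

        Token-mode terms are tokenized with the active tokenizer so that
        multi-term entries match token sequences.
        """
        from .tokenization import tokenize

        entries: set[tuple[str, ...]] = set()
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                term = raw.strip()
                if not term:
                    continue
                if match_mode == "token":
                    entries.add(tuple(t.surface for t in tokenize(term, tokenizer)))
                else:
                    entries.add((term,))
        if not entries:
            raise ValueError(f"gazetteer file {path} contains no terms")
        return cls(name or Path(path).stem, frozenset(entries), match_mode, boost)

    def contains_token(self, surface: str) -> bool:
        return surface.lower() in self._members


def gazetteer_features(
    tokens: Sequence[Token], index: int, gazetteers: Iterable[Gazetteer]
) -> set[str]:
    """Dictionary-lookup features for the token at ``index``.

    Token-mode gazetteers emit ``in_<name>`` when the token appears in any
    entry, plus ``in_<name>_full`` when a contiguous token run covering the
    index equals an entire entry. Prefix/suffix gazetteers test surface
    affixes; boost gazetteers additionally emit ``boost``.
    """
    if not (0 <= index < len(tokens)):
        raise IndexError(f"index {index} outside token sequence")
    surface = tokens[index].surface
    feats: set[str] = set()
    for gaz in gazetteers:
        hit = False
        if gaz.match_mode == "token":
            if gaz.contains_token(surface):
                feats.add(f"in_{gaz.name}")
                hit = True
            if _full_entry_match(tokens, index, gaz):
                feats.add(f"in_{gaz.name}_full")
                hit = True
        elif gaz.match_mode == "prefix":
            low = surface.lower()
            if any(low.startswith(e[0].lower()) and len(e[0]) < len(low)
                   for e in gaz.entries):
                feats.add(f"prefix_{gaz.name}")
                hit = True
        else:  # suffix
            low = surface.lower()
            if any(low.endswith(e[0].lower()) and len(e[0]) < len(low)
                   for e in gaz.entries):
                feats.add(f"suffix_{gaz.name}")
                hit = True
        if hit and gaz.boost:
            feats.add("boost")
    return feats


def _full_entry_match(
    tokens: Sequence[Token], index: int, gaz: Gazetteer
) -> bool:
    surfaces = [t.surface.lower() for t in tokens]
    for entry in gaz.entries:
        m = len(entry)
        entry_low = tuple(t.lower() for t in entry)
        lo = max(0, index - m + 1)
        for start in range(lo, min(index + 1, len(surfaces) - m + 1)):
            if tuple(surfaces[start : start + m]) == entry_low:
                return True
    return False


# ---------------------------------------------------------------------------
# Per-token features

_SIGN_CHARS = frozenset("+-±*")


def token_features(
    token: Token | str,
    is_sentence_start: bool = False,
    soundex_digits: int = 7,
    use_soundex: bool = True,
    use_nlp: bool = True,
    lemmatizer=None,
) -> set[str]:
    """Surface, shape, n-gram, formula-heuristic, word-class and Soundex
    features for one token.

    ``lemmatizer`` is a pluggable hook (callable ``str -> str``) defaulting
    to identity; when set, a ``lemma=`` feature is emitted.
    """
    w = token.surface if isinstance(token, Token) else token
    feats: set[str] = {f"word={w}", f"lower={w.lower()}"}
    letters = [ch for ch in w if ch.isalpha()]
    if any(ch.isdigit() for ch in w):
        feats.add("has_digit")
    if w and w[0].isupper():
        feats.add("init_cap")
    if letters and all(ch.isupper() for ch in letters):
        feats.add("all_caps")
    if letters and all(ch.islower() for ch in letters):
        feats.add("all_lower")
    if any(ch.isupper() for ch in letters) and any(ch.islower() for ch in letters):
        feats.add("mixed_case")
    if w and w[-1] in _SIGN_CHARS:
        feats.add("ends_sign")
    if w and w[-1].isdigit():
        feats.add("ends_digit")
    if "-" in w:
        feats.add("has_dash")
    if w and w[0].isdigit():
        feats.add("starts_digit")
    for n in (2, 3, 4):
        for i in range(len(w) - n + 1):
            feats.add(f"ngram{n}={w[i : i + n]}")
    if is_formula_like(w):
        feats.add("formula_like")
    if is_sentence_start:
        feats.add("sentence_start")
    if use_nlp:
        full, brief = word_class(w)
        feats.add(f"wc={full}")
        feats.add(f"wcb={brief}")
        if lemmatizer is not None:
            feats.add(f"lemma={lemmatizer(w)}")
    if use_soundex:
        feats.add(f"soundex={soundex(w, soundex_digits)}")
    return feats


# ---------------------------------------------------------------------------
# Feature configuration and sentence-level assembly

#: Feature families eligible for neighbour windows, keyed by the prefix
#: their keys start with.
_FAMILY_PREFIXES = {
    "word": ("word=", "lower="),
    "shape": (
        "has_digit", "init_cap", "all_caps", "all_lower", "mixed_case",
        "ends_sign", "ends_digit", "has_dash", "starts_digit",
        "formula_like",
    ),
    "wordclass": ("wc=", "wcb="),
    "cluster": ("cluster=",),
    "gazetteer": ("in_", "prefix_", "suffix_", "boost"),
    "soundex": ("soundex=",),
    "ngram": ("ngram2=", "ngram3=", "ngram4="),
}


@dataclass
class FeatureConfig:
    """Ablation toggles and neighbour-window widths.

    The window defaults give high-cardinality families (word/lower) the
    wider +/-2 context while shape, word-class, cluster and gazetteer
    families use +/-1 and Soundex/n-grams stay local; this keeps the
    parameter count in check while still letting context disambiguate.
    ``soundex_len`` in {3, 5, 7, 100} mirrors the benchmarked code lengths.
    """

    use_nlp: bool = True
    use_word2vec: bool = True
    use_soundex: bool = True
    use_gazetteers: bool = True
    soundex_len: int = 7
    windows: dict[str, int] = field(
        default_factory=lambda: {
            "word": 2,
            "shape": 1,
            "wordclass": 1,
            "cluster": 1,
            "gazetteer": 1,
            "soundex": 0,
            "ngram": 0,
        }
    )

    def as_dict(self) -> dict:
        return {
            "use_nlp": self.use_nlp,
            "use_word2vec": self.use_word2vec,
            "use_soundex": self.use_soundex,
            "use_gazetteers": self.use_gazetteers,
            "soundex_len": self.soundex_len,
            "windows": dict(self.windows),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureConfig":
        known = {"use_nlp", "use_word2vec", "use_soundex", "use_gazetteers",
                 "soundex_len", "windows"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown feature config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "windows" in kwargs:
            kwargs["windows"] = dict(kwargs["windows"])
        return cls(**kwargs)


def _family_of(key: str) -> str | None:
    for family, prefixes in _FAMILY_PREFIXES.items():
        for p in prefixes:
            if key.startswith(p) or key == p:
                return family
    return None


def assemble_features(
    tokens: Sequence[Token],
    config: FeatureConfig | None = None,
    cluster_map: ClusterMap | None = None,
    gazetteers: Sequence[Gazetteer] = (),
    lemmatizer=None,
) -> list[set[str]]:
    """Feature sets for every token of one sentence, with windowing.

    Each token's set is its own features plus selected neighbour features
    re-keyed with the relative offset (``word[-1]=...``); out-of-range
    neighbours are simply omitted at sentence boundaries.
    """
    cfg = config or FeatureConfig()
    own: list[set[str]] = []
    for i, tok in enumerate(tokens):
        feats = token_features(
            tok,
            is_sentence_start=(i == 0),
            soundex_digits=cfg.soundex_len,
            use_soundex=cfg.use_soundex,
            use_nlp=cfg.use_nlp,
            lemmatizer=lemmatizer,
        )
        if cfg.use_word2vec:
            cf = cluster_feature(tok.surface, cluster_map)
            if cf is not None:
                feats.add(cf)
        if cfg.use_gazetteers and gazetteers:
            feats |= gazetteer_features(tokens, i, gazetteers)
        own.append(feats)

    out: list[set[str]] = []
    n = len(tokens)
    for i in range(n):
        combined = set(own[i])
        for j in range(n):
            if j == i:
                continue
            offset = j - i
            for key in own[j]:
                family = _family_of(key)
                if family is None:
                    continue
                width = cfg.windows.get(family, 0)
                if abs(offset) <= width:
                    combined.add(_offset_key(key, offset))
        out.append(combined)
    return out


def _offset_key(key: str, offset: int) -> str:
    sign = f"+{offset}" if offset > 0 else str(offset)
    if "=" in key:
        name, value = key.split("=", 1)
        return f"{name}[{sign}]={value}"
    return f"{key}[{sign}]"


# ---------------------------------------------------------------------------
# BIO labels

B, I, O = "B", "I", "O"


def label_bio(
    tokens: Sequence[Token], gold: Sequence[EntityMention]
) -> tuple[list[str], int]:
    """BIO labels for one sentence's tokens against gold mentions.

    A token whose span starts a mention is labeled B, subsequent tokens
    inside the same mention I, everything else O. Mentions whose
    boundaries do not coincide with token boundaries are skipped and
    counted; the count is returned alongside the labels so callers can
    report tokenizer/annotation misalignment. Overlapping gold mentions
    are rejected.
    """
    ordered = sorted(gold, key=lambda m: (m.start, m.end))
    for a, b_ in zip(ordered, ordered[1:]):
        if b_.start < a.end:
            raise ValueError(
                f"overlapping gold mentions [{a.start},{a.end}) and [{b_.start},{b_.end})"
            )
    labels = [O] * len(tokens)
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i for i, t in enumerate(tokens)}
    misaligned = 0
    for m in ordered:
        i = starts.get(m.start)
        j = ends.get(m.end)
        if i is None or j is None or j < i:
            misaligned += 1
            continue
        labels[i] = B
        for k in range(i + 1, j + 1):
            labels[k] = I
    return labels, misaligned


def decode_bio(
    tokens: Sequence[Token],
    labels: Sequence[str],
    doc_id: str = "",
    section: str = "A",
    source_text: str | None = None,
) -> list[EntityMention]:
    """Decode a BIO label sequence into entity spans.

    Maximal runs matching ``B I*`` become mentions; an I not preceded by
    B or I is treated as B (models may emit such sequences even though the
    encoder never produces them). Mention text is the source slice when
    ``source_text`` is given, else the space-joined token surfaces.
    """
    if len(tokens) != len(labels):
        raise ValueError(
            f"length mismatch: {len(tokens)} tokens vs {len(labels)} labels"
        )
    mentions: list[EntityMention] = []
    run_start: int | None = None
    run_end: int | None = None

    def flush() -> None:
        nonlocal run_start, run_end
        if run_start is not None:
            text = (
                source_text[run_start:run_end]
                if source_text is not None
                else " ".join(
                    t.surface for t in tokens if run_start <= t.start and t.end <= run_end
                )
            )
            mentions.append(
                EntityMention(doc_id or "?", section, run_start, run_end, text)
            )
        run_start = run_end = None

    for tok, lab in zip(tokens, labels):
        if lab == B:
            flush()
            run_start, run_end = tok.start, tok.end
        elif lab == I:
            if run_start is None:
                run_start, run_end = tok.start, tok.end  # I-as-B
            else:
                run_end = tok.end
        else:
            flush()
    flush()
    return mentions
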