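"""Sentence splitting, pluggable tokenizers and the tokenizer-boundary benchmark.

Tokenization quality puts an upper bound on the recall any span extractor
can reach: a chemical mention whose boundaries the tokenizer never produces
cannot be labeled correctly. The benchmark here scores a tokenizer by how
many gold mentions it reproduces exactly — as a single token for space-free
mentions, or word-by-word for multi-word mentions.

Tokenizers are looked up by name in a registry; the default ``chem``
tokenizer keeps chemistry-internal punctuation (hyphens, digit commas,
balanced brackets) attached, approximating the behaviour of
chemistry-aware tokenizers such as OSCAR4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import Document, EntityMention


@dataclass(frozen=True)
class Token:
    """A token with its character offsets within the source section text."""

    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"invalid token span [{self.start}, {self.end})")


@dataclass(frozen=True)
class TokenizerReport:
    """Boundary-accuracy counts over a gold mention set.

    ``correct``: space-free mentions matched by a single token's exact span.
    ``split_correct``: multi-word mentions whose every space-separated word
    is exactly one token. ``incorrect``: everything else. Accuracy is the
    percentage of gold mentions tokenized correctly either way.
    """

    correct: int
    split_correct: int
    incorrect: int

    @property
    def total_correct(self) -> int:
        return self.correct + self.split_correct

    @property
    def accuracy(self) -> float:
        total = self.total_correct + self.incorrect
        return 100.0 * self.total_correct / total if total else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "correct": self.correct,
            "split_correct": self.split_correct,
            "total_correct": self.total_correct,
            "incorrect": self.incorrect,
            "accuracy": self.accuracy,
        }


_TERMINALS = frozenset(".!?")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans.

    A sentence ends at ``.``, ``!`` or ``?`` followed by whitespace and
    an uppercase letter, or at end of text. Spans exclude surrounding
    whitespace and jointly cover every non-whitespace character.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    i = 0
    while i < n and text[i].isspace():
        i += 1
    start = i
    while i < n:
        ch = text[i]
        if ch in _TERMINALS:
            j = i + 1
            while j < n and text[j].isspace():
                j += 1
            if j > i + 1 and (j == n or text[j].isupper()):
                spans.append((start, i + 1))
                start = j
                i = j
                continue
        i += 1
    if start < n:
        end = n
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            spans.append((start, end))
    return spans


def _is_word_char(ch: str) -> bool:
    # isalnum() is True for Greek letters and sub/superscript digits,
    # which chemical names require.
    return ch.isalnum()


_BRACKETS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def _balanced_within(fragment: str, ch: str) -> bool:
    """Whether bracket ``ch`` is balanced inside the fragment."""
    opener = ch if ch in _BRACKETS else _CLOSERS.get(ch)
    if opener is None:
        return False
    closer = _BRACKETS[opener]
    return fragment.count(opener) == fragment.count(closer) > 0


def tokenize_chem(text: str) -> list[Token]:
    """Chemistry-aware tokenizer (registry name ``chem``, the default).

    Splits on whitespace, then splits leading/trailing punctuation off
    each fragment — except brackets balanced within the fragment, which
    stay attached. Internal punctuation (hyphens, commas between digits,
    anything sandwiched between word characters) never splits a fragment.
    A trailing period is always split off.
    """
    tokens: list[Token] = []
    for frag_start, frag_end in _whitespace_spans(text):
        s, e = frag_start, frag_end
        while s < e:
            frag = text[s:e]
            ch = frag[0]
            if not _is_word_char(ch) and not _balanced_within(frag, ch):
                tokens.append(Token(ch, s, s + 1))
                s += 1
                continue
            # peel trailing punctuation into a pending stack
            trailing: list[Token] = []
            while s < e:
                frag = text[s:e]
                last = frag[-1]
                if _is_word_char(last):
                    break
                if last != "." and _balanced_within(frag, last):
                    break
                trailing.append(Token(last, e - 1, e))
                e -= 1
            if s < e:
                tokens.append(Token(text[s:e], s, e))
            tokens.extend(reversed(trailing))
            s = frag_end
            e = frag_end
    return tokens


def tokenize_whitespace(text: str) -> list[Token]:
    """Pure whitespace tokenizer (registry name ``whitespace``)."""
    return [Token(text[s:e], s, e) for s, e in _whitespace_spans(text)]


def tokenize_simple_punct(text: str) -> list[Token]:
    """Whitespace split, then every leading/trailing punctuation character
    becomes its own token (registry name ``simple-punct``)."""
    tokens: list[Token] = []
    for frag_start, frag_end in _whitespace_spans(text):
        s, e = frag_start, frag_end
        lead: list[Token] = []
        while s < e and not _is_word_char(text[s]):
            lead.append(Token(text[s], s, s + 1))
            s += 1
        trail: list[Token] = []
        while e > s and not _is_word_char(text[e - 1]):
            trail.append(Token(text[e - 1], e - 1, e))
            e -= 1
        tokens.extend(lead)
        if s < e:
            tokens.append(Token(text[s:e], s, e))
        tokens.extend(reversed(trail))
    return tokens


def _whitespace_spans(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start: int | None = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if start is not None:
                spans.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        spans.append((start, len(text)))
    return spans


TOKENIZERS: dict[str, Callable[[str], list[Token]]] = {
    "chem": tokenize_chem,
    "whitespace": tokenize_whitespace,
    "simple-punct": tokenize_simple_punct,
}

DEFAULT_TOKENIZER = "chem"


def get_tokenizer(name: str = DEFAULT_TOKENIZER) -> Callable[[str], list[Token]]:
    try:
        return TOKENIZERS[name]
    except KeyError:
        raise KeyError(
            f"unknown tokenizer {name!r}; available: {sorted(TOKENIZERS)}"
        ) from None


def tokenize(text: str, tokenizer: str = DEFAULT_TOKENIZER) -> list[Token]:
    """Tokenize ``text`` with the named registry tokenizer."""
    return get_tokenizer(tokenizer)(text)


def tokenize_document(
    document: Document, tokenizer: str = DEFAULT_TOKENIZER
) -> dict[str, list[list[Token]]]:
    """Tokenize both sections of a document, sentence by sentence.

    Returns a mapping section -> list of sentences, each a list of Tokens
    with offsets relative to the section text. Sentence splitting happens
    first, so tokens never cross sentence boundaries.
    """
    tok = get_tokenizer(tokenizer)
    out: dict[str, list[list[Token]]] = {}
    for section in ("T", "A"):
        text = document.section_text(section)
        sentences: list[list[Token]] = []
        for s, e in split_sentences(text):
            toks = [
                Token(t.surface, t.start + s, t.end + s) for t in tok(text[s:e])
            ]
            if toks:
                sentences.append(toks)
        out[section] = sentences
    return out


def evaluate_tokenizer(
    gold: Iterable[EntityMention],
    tokens_by_doc: Mapping[tuple[str, str], Sequence[Token]],
) -> TokenizerReport:
    """Score a tokenizer against gold mention boundaries.

    ``tokens_by_doc`` maps (doc_id, section) to that section's tokens.
    A space-free mention counts as Correct iff one token's (start, end)
    equals the mention span; a mention containing spaces counts as Split
    Correct iff each space-separated word is exactly one token.
    """
    correct = split_correct = incorrect = 0
    span_index: dict[tuple[str, str], set[tuple[int, int]]] = {}
    for key, toks in tokens_by_doc.items():
        span_index[key] = {(t.start, t.end) for t in toks}
    for m in gold:
        key = (m.doc_id, m.section)
        if key not in span_index:
            raise KeyError(f"no tokens supplied for document {m.doc_id!r} section {m.section!r}")
        spans = span_index[key]
        if " " not in m.text:
            if (m.start, m.end) in spans:
                correct += 1
            else:
                incorrect += 1
            continue
        # multi-word mention: every space-separated word must be one token
        ok = True
        pos = m.start
        for word in m.text.split(" "):
            if not word:
                continue
            if (pos, pos + len(word)) not in spans:
                ok = False
                break
            pos += len(word) + 1
        if ok:
            split_correct += 1
        else:
            incorrect += 1
    return TokenizerReport(correct, split_correct, incorrect)


def corpus_tokens(
    documents: Sequence[Document], tokenizer: str = DEFAULT_TOKENIZER
) -> dict[tuple[str, str], list[Token]]:
    """Flat (doc_id, section) -> tokens map for benchmark evaluation."""
    out: dict[tuple[str, str], list[Token]] = {}
    for doc in documents:
        sentences = tokenize_document(doc, tokenizer)
        for section, sents in sentences.items():
            out[(doc.doc_id, section)] = [t for sent in sents for t in sent]
    return out
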