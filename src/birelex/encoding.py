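"""Input construction for relation classification.

A :class:`RelationInstance` becomes an :class:`EncodedExample` — a token
sequence with segment ids and the indices of the two entity-representative
tokens — under one of five construction methods:

``default``
    ``[CLS] sentence [SEP]``; entities are represented by their first token.
``entity_marker``
    entity spans wrapped in ``[E1]…[/E1]`` / ``[E2]…[/E2]`` marker tokens;
    each entity is represented by its start marker (entity-start convention).
``masked``
    each entity's whole span replaced by a single ``[MASK]``.
``two_masked_sentence``
    the sentence duplicated across a ``[SEP]``: entity1 masked in the first
    copy, entity2 masked in the second, so one original surface form survives
    in each copy while the representative positions are always ``[MASK]``.
``two_sentence_entity_token``
    the same two-copy layout, but the replacement tokens are ``[E1]`` and
    ``[E2]`` instead of ``[MASK]``.

Masking the representative positions makes them invariant to the entity
surface form, which removes out-of-vocabulary entity mentions from the
positions the classification head reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

from .corpus import RelationInstance

__all__ = [
    "METHODS",
    "SINGLE_SENTENCE_METHODS",
    "TWO_SENTENCE_METHODS",
    "EncodingError",
    "LengthError",
    "TokenizerContract",
    "WhitespaceTokenizer",
    "EncodedExample",
    "align_spans_to_tokens",
    "encode",
]

METHODS: tuple[str, ...] = (
    "default",
    "entity_marker",
    "masked",
    "two_masked_sentence",
    "two_sentence_entity_token",
)
SINGLE_SENTENCE_METHODS = ("default", "entity_marker", "masked")
TWO_SENTENCE_METHODS = ("two_masked_sentence", "two_sentence_entity_token")

MARKER_TOKENS: tuple[str, ...] = ("[E1]", "[/E1]", "[E2]", "[/E2]")


class EncodingError(ValueError):
    """Encoding failure (bad method, span alignment, truncation)."""


class LengthError(EncodingError):
    """Truncation would drop a structurally required token."""


@runtime_checkable
class TokenizerContract(Protocol):
    """What the encoder pipeline needs from a tokenizer.

    ``tokenize`` must return character-offset triples that are monotone,
    non-overlapping and within the input; special and marker tokens are
    atomic (never split by ``tokenize``).
    """

    cls_token: str
    sep_token: str
    mask_token: str
    pad_token: str
    unk_token: str

    def tokenize(self, text: str) -> list[tuple[str, int, int]]: ...

    def register_tokens(self, tokens: Sequence[str]) -> None: ...

    def to_ids(self, tokens: Sequence[str]) -> list[int]: ...


class WhitespaceTokenizer:
    """Whitespace tokenizer with character offsets and a fitted vocabulary.

    Splits on maximal runs of non-space characters.  ``to_ids`` maps tokens
    absent from the fitted vocabulary to the ``[UNK]`` id, so out-of-vocabulary
    entity mentions are observable downstream.  Marker tokens added through
    :meth:`register_tokens` get stable ids for the lifetime of the instance.
    """

    cls_token = "[CLS]"
    sep_token = "[SEP]"
    mask_token = "[MASK]"
    pad_token = "[PAD]"
    unk_token = "[UNK]"

    _WORD = re.compile(r"\S+")

    def __init__(self, vocabulary: Sequence[str] = ()) -> None:
        self._vocab: dict[str, int] = {}
        for tok in (self.pad_token, self.unk_token, self.cls_token,
                    self.sep_token, self.mask_token):
            self._vocab[tok] = len(self._vocab)
        self.register_tokens(vocabulary)

    @property
    def vocab_size(self) -> int:
        return len(self._vocab)

    def fit(self, texts: Sequence[str]) -> "WhitespaceTokenizer":
        """Grow the vocabulary from raw texts; returns self."""
        for text in texts:
            self.register_tokens(tok for tok, _, _ in self.tokenize(text))
        return self

    def tokenize(self, text: str) -> list[tuple[str, int, int]]:
        return [(m.group(), m.start(), m.end())
                for m in self._WORD.finditer(text)]

    def register_tokens(self, tokens) -> None:
        for tok in tokens:
            if tok not in self._vocab:
                self._vocab[tok] = len(self._vocab)

    def to_ids(self, tokens: Sequence[str]) -> list[int]:
        unk = self._vocab[self.unk_token]
        return [self._vocab.get(tok, unk) for tok in tokens]


@dataclass(frozen=True)
class EncodedExample:
    """A constructed input sequence for one relation instance."""

    tokens: tuple[str, ...]
    segment_ids: tuple[int, ...]
    e1_index: int
    e2_index: int
    method: str
    label: str | None = None
    cls_index: int = 0

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.segment_ids):
            raise EncodingError("tokens and segment_ids length mismatch")


def align_spans_to_tokens(
    tokens: Sequence[tuple[str, int, int]], span: tuple[int, int]
) -> tuple[int, int]:
    """Map a character span to the smallest covering token range.

    Returns a half-open token-index range; a partial character overlap
    expands to the whole covering token.  Raises :class:`EncodingError` if
    the span covers no token.
    """
    start, end = span
    first = last = None
    for i, (_, tok_start, tok_end) in enumerate(tokens):
        if tok_start < end and tok_end > start:  # any character overlap
            if first is None:
                first = i
            last = i
    if first is None:
        raise EncodingError(f"span {span} covers no token")
    return first, last + 1


def _build_single(
    words: list[str],
    r1: tuple[int, int],
    r2: tuple[int, int],
    method: str,
    tok: TokenizerContract,
) -> tuple[list[str], int, int]:
    """Token body (no [CLS]/[SEP]) plus representative offsets within it."""
    (a1, b1), (a2, b2) = r1, r2
    if method == "default":
        return list(words), a1, a2
    if method == "masked":
        # Whole spans collapse to one [MASK] each; replace the later span
        # first so earlier indices stay valid.
        out = list(words)
        for a, b in sorted((r1, r2), reverse=True):
            out[a:b] = [tok.mask_token]

        def shifted(a: int) -> int:
            other_a, other_b = (r2 if a == a1 else r1)
            return a - (other_b - other_a - 1) if other_a < a else a

        return out, shifted(a1), shifted(a2)
    if method == "entity_marker":
        out: list[str] = []
        e1_pos = e2_pos = -1
        opens = {a1: "[E1]", a2: "[E2]"}
        closes = {b1: "[/E1]", b2: "[/E2]"}
        for i, word in enumerate(words):
            if i in closes:
                out.append(closes[i])
            if i in opens:
                if opens[i] == "[E1]":
                    e1_pos = len(out)
                else:
                    e2_pos = len(out)
                out.append(opens[i])
            out.append(word)
        for b in (b1, b2):
            if b == len(words):
                out.append(closes[b])
        return out, e1_pos, e2_pos
    raise EncodingError(f"unknown method: {method!r}")


def _replace_span(
    words: list[str], span: tuple[int, int], replacement: str
) -> tuple[list[str], int]:
    a, b = span
    return words[:a] + [replacement] + words[b:], a


def encode(
    instance: RelationInstance,
    method: str,
    tokenizer: TokenizerContract,
    max_len: int = 256,
) -> EncodedExample:
    """Construct the input sequence for ``instance`` under ``method``.

    Entity roles follow annotation order (entity1 = subject), not textual
    order.  Sequences longer than ``max_len`` are truncated from the sentence
    tail, immediately before the final ``[SEP]``; if a representative token
    or a structural separator would be dropped, :class:`LengthError` is
    raised instead of silently degrading.
    """
    if method not in METHODS:
        raise EncodingError(
            f"unknown method: {method!r}; expected one of {METHODS}"
        )
    toks = tokenizer.tokenize(instance.sentence)
    words = [t for t, _, _ in toks]
    r1 = align_spans_to_tokens(toks, (instance.entity1.start, instance.entity1.end))
    r2 = align_spans_to_tokens(toks, (instance.entity2.start, instance.entity2.end))
    if max(r1[0], r2[0]) < min(r1[1], r2[1]):
        raise EncodingError("entity token ranges overlap")

    cls, sep = tokenizer.cls_token, tokenizer.sep_token
    if method in SINGLE_SENTENCE_METHODS:
        body, p1, p2 = _build_single(words, r1, r2, method, tokenizer)
        tokens = [cls] + body + [sep]
        e1_index, e2_index = p1 + 1, p2 + 1
        segments = [0] * len(tokens)
    else:
        repl1, repl2 = (
            (tokenizer.mask_token, tokenizer.mask_token)
            if method == "two_masked_sentence"
            else ("[E1]", "[E2]")
        )
        first, p1 = _replace_span(words, r1, repl1)
        second, p2 = _replace_span(words, r2, repl2)
        tokens = [cls] + first + [sep] + second + [sep]
        e1_index = p1 + 1
        e2_index = p2 + 1 + len(first) + 1
        segments = [0] * (len(first) + 2) + [1] * (len(second) + 1)

    if len(tokens) > max_len:
        tokens, segments, e1_index, e2_index = _truncate(
            tokens, segments, e1_index, e2_index, max_len, sep
        )
    return EncodedExample(
        tokens=tuple(tokens),
        segment_ids=tuple(segments),
        e1_index=e1_index,
        e2_index=e2_index,
        method=method,
        label=instance.label,
    )


def _truncate(tokens, segments, e1, e2, max_len, sep):
    """Drop tokens from the tail, just before the final [SEP]."""
    excess = len(tokens) - max_len
    # Tokens that must survive: [CLS], both representatives, every [SEP].
    protected = {0, e1, e2} | {i for i, t in enumerate(tokens) if t == sep}
    cut_end = len(tokens) - 1  # position of the final [SEP]
    cut_start = cut_end - excess
    if any(i in protected for i in range(cut_start, cut_end)):
        raise LengthError(
            f"cannot truncate to max_len={max_len}: a representative or "
            "separator token would be dropped"
        )
    tokens = tokens[:cut_start] + tokens[cut_end:]
    segments = segments[:cut_start] + segments[cut_end:]
    return tokens, segments, e1, e2
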