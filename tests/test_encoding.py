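"""Input-construction layouts, span alignment, truncation, invariances."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birelex.corpus import EntityMention, RelationInstance
from birelex.encoding import (
    METHODS,
    SINGLE_SENTENCE_METHODS,
    TWO_SENTENCE_METHODS,
    EncodingError,
    LengthError,
    WhitespaceTokenizer,
    align_spans_to_tokens,
    encode,
)
from birelex.synthetic import GeneratorConfig, generate_corpus

TOKENS = [("A", 0, 1), ("activates", 2, 11), ("B", 12, 13)]


class TestSpanAlignment:
    @pytest.mark.parametrize(
        "span,expected",
        [((0, 1), (0, 1)), ((2, 11), (1, 2)), ((3, 8), (1, 2)),
         ((12, 13), (2, 3)), ((0, 13), (0, 3))],
    )
    def test_covering_range(self, span, expected):
        assert align_spans_to_tokens(TOKENS, span) == expected

    def test_span_covering_no_token_errors(self):
        with pytest.raises(EncodingError):
            align_spans_to_tokens(TOKENS, (11, 12))  # the space


EXPECTED_LAYOUTS = {
    "default": (
        "[CLS] A activates B C [SEP]", 1, 3, [0] * 6),
    "entity_marker": (
        "[CLS] [E1] A [/E1] activates [E2] B C [/E2] [SEP]", 1, 5, [0] * 10),
    "masked": (
        "[CLS] [MASK] activates [MASK] [SEP]", 1, 3, [0] * 5),
    "two_masked_sentence": (
        "[CLS] [MASK] activates B C [SEP] A activates [MASK] [SEP]",
        1, 8, [0] * 6 + [1] * 4),
    "two_sentence_entity_token": (
        "[CLS] [E1] activates B C [SEP] A activates [E2] [SEP]",
        1, 8, [0] * 6 + [1] * 4),
}


class TestLayouts:
    @pytest.mark.parametrize("method", METHODS)
    def test_worked_example(self, method, simple_instance, tokenizer):
        expected_tokens, e1, e2, segments = EXPECTED_LAYOUTS[method]
        ex = encode(simple_instance, method, tokenizer)
        assert list(ex.tokens) == expected_tokens.split()
        assert (ex.e1_index, ex.e2_index) == (e1, e2)
        assert list(ex.segment_ids) == segments
        assert ex.tokens[0] == "[CLS]" and ex.tokens[-1] == "[SEP]"

    def test_unknown_method_errors(self, simple_instance, tokenizer):
        with pytest.raises(EncodingError):
            encode(simple_instance, "triple_masked", tokenizer)

    def test_reversed_textual_order_follows_roles(self, tokenizer):
        # entity1 (subject role) appears AFTER entity2 in the text
        inst = RelationInstance(
            "p", 0, "B C represses A",
            EntityMention("A", 14, 15, "gene"),
            EntityMention("B C", 0, 3, "protein"),
            "negative_cause",
        )
        ex = encode(inst, "two_masked_sentence", tokenizer)
        # first copy masks entity1 ("A", textually last)
        assert list(ex.tokens) == (
            "[CLS] B C represses [MASK] [SEP] [MASK] represses A [SEP]"
        ).split()
        assert ex.tokens[ex.e1_index] == "[MASK]" and ex.e1_index == 4
        assert ex.tokens[ex.e2_index] == "[MASK]" and ex.e2_index == 6

    def test_masked_is_invariant_to_entity_surface(self, tokenizer):
        def variant(surface):
            sent = f"{surface} activates B C"
            off = len(surface)
            return RelationInstance(
                "p", 0, sent,
                EntityMention(surface, 0, off, "gene"),
                EntityMention("B C", off + 11, off + 14, "protein"),
                "positive_cause",
            )
        a = encode(variant("A"), "masked", tokenizer)
        b = encode(variant("ZZUNSEENZZ"), "masked", tokenizer)
        assert a.tokens == b.tokens
        assert (a.e1_index, a.e2_index) == (b.e1_index, b.e2_index)
        # ...but the unmasked copy in the two-sentence layout is NOT invariant
        a2 = encode(variant("A"), "two_masked_sentence", tokenizer)
        b2 = encode(variant("ZZUNSEENZZ"), "two_masked_sentence", tokenizer)
        assert a2.tokens != b2.tokens
        assert a2.tokens[a2.e1_index] == b2.tokens[b2.e1_index] == "[MASK]"

    def test_encode_is_deterministic(self, simple_instance, tokenizer):
        first = encode(simple_instance, "entity_marker", tokenizer)
        second = encode(simple_instance, "entity_marker", tokenizer)
        assert first == second


class TestTruncation:
    def _long_instance(self, n_tail):
        tail = " ".join(f"w{i}" for i in range(n_tail))
        sent = f"A activates B {tail}"
        return RelationInstance(
            "p", 0, sent,
            EntityMention("A", 0, 1, "gene"),
            EntityMention("B", 12, 13, "protein"),
            "positive_cause",
        )

    def test_tail_tokens_dropped_before_final_sep(self, tokenizer):
        inst = self._long_instance(20)
        ex = encode(inst, "default", tokenizer, max_len=10)
        assert len(ex.tokens) == 10
        assert ex.tokens[-1] == "[SEP]"
        assert ex.tokens[ex.e2_index] == "B"

    def test_representative_token_never_silently_cut(self, tokenizer):
        inst = self._long_instance(20)
        with pytest.raises(LengthError):
            encode(inst, "default", tokenizer, max_len=3)
        # two-sentence: entity2's mask sits in the second copy
        with pytest.raises(LengthError):
            encode(inst, "two_masked_sentence", tokenizer, max_len=20)


def _restore(ex, instance, tokenizer):
    """Strip markers and re-expand replaced spans; returns sentence copies."""
    words = [t for t, _, _ in tokenizer.tokenize(instance.sentence)]
    toks = tokenizer.tokenize(instance.sentence)
    span_words = {}
    for role, ent in (("e1", instance.entity1), ("e2", instance.entity2)):
        a, b = align_spans_to_tokens(toks, (ent.start, ent.end))
        span_words[role] = words[a:b]
    copies = []
    current = []
    for tok, seg in zip(ex.tokens, ex.segment_ids):
        if tok == "[SEP]":
            copies.append(current)
            current = []
        elif tok != "[CLS]":
            current.append(tok)
    restored = []
    masked_roles = (["e1", "e2"] if len(copies) == 1 else [["e1"], ["e2"]])
    for i, copy in enumerate(copies):
        roles = iter(masked_roles if len(copies) == 1 else masked_roles[i])
        out = []
        for tok in copy:
            if ex.method == "entity_marker":
                if tok not in ("[E1]", "[/E1]", "[E2]", "[/E2]"):
                    out.append(tok)  # markers wrap the span, drop them
            elif tok in ("[MASK]", "[E1]", "[E2]"):
                out.extend(span_words[next(roles)])  # replaced span
            else:
                out.append(tok)
        restored.append(out)
    return restored, words


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 2**31 - 1),
       method=st.sampled_from(METHODS))
def test_layout_invariants_on_random_instances(seed, method):
    tok = WhitespaceTokenizer()
    tok.register_tokens(["[E1]", "[/E1]", "[E2]", "[/E2]"])
    pairs = generate_corpus(GeneratorConfig(n_instances=5, seed=seed))
    for inst, _ in pairs:
        ex = encode(inst, method, tok)
        n_sep = ex.tokens.count("[SEP]")
        segments = list(ex.segment_ids)
        assert segments == sorted(segments)  # non-decreasing
        assert 0 < ex.e1_index < len(ex.tokens) - 1
        assert 0 < ex.e2_index < len(ex.tokens) - 1
        assert ex.e1_index != ex.e2_index
        if method in SINGLE_SENTENCE_METHODS:
            assert n_sep == 1 and 1 not in segments
        else:
            assert n_sep == 2 and segments[-1] == 1
        if method == "masked":
            assert ex.tokens.count("[MASK]") == 2
        if method == "two_masked_sentence":
            sep = ex.tokens.index("[SEP]")
            assert ex.tokens[:sep].count("[MASK]") == 1
            assert ex.tokens[sep:].count("[MASK]") == 1
        # masking/marking is reversible: restoring spans recovers tokens(S)
        restored, words = _restore(ex, inst, tok)
        for copy in restored:
            assert copy == words
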