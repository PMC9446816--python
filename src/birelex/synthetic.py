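"""Templated synthetic relation corpora with known cue structure.

Each sentence instantiates ``<modifier?> <E1> <verb phrase> <quantity?> <E2>
<tail?> .`` from small fixed lexicons.  The relation label is a deterministic
function of the cues (see :func:`oracle_label`):

* a *neutral* verb expresses correlation without causality — undirected link;
* an *ambiguous-causal* verb expresses causality without a recoverable
  direction — directed link;
* a polar causal verb yields positive/negative cause, with an intervention
  modifier ("knockdown of", ...) flipping the effective polarity, mirroring
  sentences where an inducing verb under a knockout reads as inhibition;
* an explicit quantity phrase on the object entity descends one more level:
  under a positive cause, an increase reads as ``positive_increase`` and a
  decrease as ``negative_decrease``; under a negative cause, an increase as
  ``negative_increase`` and a decrease as ``positive_decrease``.

The generator samples the label first (by ``class_weights``) and then a cue
combination consistent with it, so class frequencies follow the weights while
every instance's label equals the cue oracle by construction.  Entity surface
forms are abstract symbols; a disjoint symbol pool supports held-out splits
with out-of-vocabulary entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    DEFAULT_SCHEMA,
    ENTITY_TYPES,
    EntityMention,
    RelationInstance,
)

__all__ = [
    "GeneratorConfig",
    "CueRecord",
    "oracle_label",
    "generate_corpus",
    "generate_train_heldout",
    "write_cue_table",
    "TABLE5_TOTALS",
]

# Lexicons are deliberately small and versioned here so behaviour is stable.
POSITIVE_VERBS: tuple[str, ...] = (
    "activates", "induces", "upregulates", "promotes", "enhances",
)
NEGATIVE_VERBS: tuple[str, ...] = (
    "inhibits", "suppresses", "downregulates", "represses",
)
AMBIGUOUS_VERBS: tuple[str, ...] = ("regulates", "modulates")
NEUTRAL_VERBS: tuple[str, ...] = ("is associated with", "correlates with")
FLIP_MODIFIERS: tuple[str, ...] = (
    "knockdown of", "inhibition of", "silencing of", "loss of",
)
QUANTITY_PHRASES: dict[str, str] = {
    "an increase in": "increase",
    "elevated levels of": "increase",
    "a decrease in": "decrease",
    "reduced levels of": "decrease",
}
DISTRACTOR_TAILS: tuple[str, ...] = (
    "alongside an increase in dosage",
    "despite a decrease in viability",
)
PLAIN_TAILS: tuple[str, ...] = (
    "", "in tumor cells", "in vivo", "in patients", "under hypoxia",
)

# Relation-type totals over all splits of the reference corpus overview,
# used as the default class imbalance.
TABLE5_TOTALS: dict[str, int] = {
    "undirected_link": 1396,
    "directed_link": 833,
    "positive_cause": 1087,
    "negative_cause": 700,
    "positive_increase": 273,
    "negative_decrease": 364,
    "positive_decrease": 133,
    "negative_increase": 245,
}


def _default_weights() -> dict[str, float]:
    total = sum(TABLE5_TOTALS.values())
    return {k: v / total for k, v in TABLE5_TOTALS.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    ``negation_rate`` is the probability that a causal instance realizes its
    polarity through a flip modifier on an opposite-polarity verb instead of
    a direct verb.  ``quantity_rate`` is the probability that a sentence whose
    label carries no quantity level still contains a distractor quantity
    phrase in its tail, so quantity wording alone does not identify the
    third level.  ``oov_fraction_heldout`` is the fraction of held-out
    instances built from an entity-symbol pool disjoint from the training
    vocabulary (used by :func:`generate_train_heldout`).
    """

    n_instances: int = 2000
    class_weights: Mapping[str, float] = field(default_factory=_default_weights)
    n_entity_symbols: int = 200
    negation_rate: float = 0.3
    quantity_rate: float = 0.2
    oov_fraction_heldout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_weights) - set(DEFAULT_SCHEMA.relation_labels)
        if unknown:
            raise ValueError(f"class_weights name unknown labels: {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_weights sum to {total}, expected 1")
        for name in ("negation_rate", "quantity_rate", "oov_fraction_heldout"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_instances <= 0:
            raise ValueError("n_instances must be positive")


@dataclass(frozen=True)
class CueRecord:
    """The hidden cues that determine one instance's label."""

    verb_polarity: str  # positive | negative | ambiguous | neutral
    modifier: str | None
    quantity: str | None  # increase | decrease | None
    distractor: bool
    oov: bool


def oracle_label(cues: CueRecord) -> str:
    """Deterministic cue -> label mapping (the generator's ground truth)."""
    pol = cues.verb_polarity
    if pol == "neutral":
        return "undirected_link"
    if pol == "ambiguous":
        return "directed_link"
    if pol not in ("positive", "negative"):
        raise ValueError(f"unknown verb polarity: {pol!r}")
    flipped = cues.modifier is not None
    effective = pol if not flipped else ("negative" if pol == "positive" else "positive")
    if cues.quantity is None:
        return f"{effective}_cause"
    if cues.quantity not in ("increase", "decrease"):
        raise ValueError(f"unknown quantity cue: {cues.quantity!r}")
    if effective == "positive":
        return ("positive_increase" if cues.quantity == "increase"
                else "negative_decrease")
    return ("negative_increase" if cues.quantity == "increase"
            else "positive_decrease")


def _sample_cues(label: str, rng: np.random.Generator,
                 config: GeneratorConfig, oov: bool) -> CueRecord:
    """Sample a cue combination whose oracle label is ``label``."""
    modifier = None
    quantity = None
    distractor = False
    if label == "undirected_link":
        polarity = "neutral"
    elif label == "directed_link":
        polarity = "ambiguous"
    else:
        parent = ("positive" if label in
                  ("positive_cause", "positive_increase", "negative_decrease")
                  else "negative")
        if label in ("positive_increase", "negative_increase"):
            quantity = "increase"
        elif label in ("negative_decrease", "positive_decrease"):
            quantity = "decrease"
        if rng.random() < config.negation_rate:
            # opposite-polarity verb under a flipping modifier
            polarity = "negative" if parent == "positive" else "positive"
            modifier = FLIP_MODIFIERS[rng.integers(len(FLIP_MODIFIERS))]
        else:
            polarity = parent
    if quantity is None and rng.random() < config.quantity_rate:
        distractor = True
    return CueRecord(polarity, modifier, quantity, distractor, oov)


def _verb_for(polarity: str, rng: np.random.Generator) -> str:
    pool = {
        "positive": POSITIVE_VERBS,
        "negative": NEGATIVE_VERBS,
        "ambiguous": AMBIGUOUS_VERBS,
        "neutral": NEUTRAL_VERBS,
    }[polarity]
    return pool[rng.integers(len(pool))]


def _realize(cues: CueRecord, pmid: str, sent_id: int,
             rng: np.random.Generator, symbols: Sequence[str]) -> RelationInstance:
    """Render a cue record as a sentence with exact entity offsets."""
    i1 = rng.integers(len(symbols))
    i2 = rng.integers(len(symbols) - 1)
    if i2 >= i1:
        i2 += 1
    sym1, sym2 = symbols[i1], symbols[i2]
    type1, type2 = (ENTITY_TYPES[rng.integers(len(ENTITY_TYPES))]
                    for _ in range(2))
    verb = _verb_for(cues.verb_polarity, rng)
    quantity_phrase = None
    if cues.quantity is not None:
        options = [p for p, q in QUANTITY_PHRASES.items() if q == cues.quantity]
        quantity_phrase = options[rng.integers(len(options))]
    if cues.distractor:
        tail = DISTRACTOR_TAILS[rng.integers(len(DISTRACTOR_TAILS))]
    else:
        tail = PLAIN_TAILS[rng.integers(len(PLAIN_TAILS))]

    parts: list[str] = []
    offsets: dict[str, int] = {}

    def push(piece: str, key: str | None = None) -> None:
        if not piece:
            return
        if key is not None:
            offsets[key] = sum(len(p) + 1 for p in parts)
        parts.append(piece)

    if cues.modifier:
        push(cues.modifier)
    push(sym1, "e1")
    push(verb)
    if quantity_phrase:
        push(quantity_phrase)
    push(sym2, "e2")
    push(tail)
    push(".")
    sentence = " ".join(parts)
    e1 = EntityMention(sym1, offsets["e1"], offsets["e1"] + len(sym1), type1)
    e2 = EntityMention(sym2, offsets["e2"], offsets["e2"] + len(sym2), type2)
    return RelationInstance(
        pmid=pmid, sent_id=sent_id, sentence=sentence,
        entity1=e1, entity2=e2, label=oracle_label(cues),
    )


def _symbol_pool(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def generate_corpus(
    config: GeneratorConfig,
    *,
    rng: np.random.Generator | None = None,
    oov: bool = False,
    pmid_prefix: str = "SYN",
) -> list[tuple[RelationInstance, CueRecord]]:
    """Generate ``config.n_instances`` (instance, cue-record) pairs.

    Deterministic given ``config.seed``.  With ``oov=True`` every entity
    surface form comes from a symbol pool disjoint from the default one.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = sorted(config.class_weights)
    weights = np.array([config.class_weights[l] for l in labels])
    weights = weights / weights.sum()
    symbols = _symbol_pool(config.n_entity_symbols,
                           "NOV" if oov else "ENT")
    out = []
    for i in range(config.n_instances):
        label = labels[rng.choice(len(labels), p=weights)]
        cues = _sample_cues(label, rng, config, oov)
        inst = _realize(cues, f"{pmid_prefix}{i // 4}", i % 4, rng, symbols)
        out.append((inst, cues))
    return out


def generate_train_heldout(
    config: GeneratorConfig, n_heldout: int
) -> tuple[
    list[tuple[RelationInstance, CueRecord]],
    list[tuple[RelationInstance, CueRecord]],
]:
    """Training corpus plus a held-out corpus with OOV entity surfaces.

    The held-out corpus mixes in-vocabulary and out-of-vocabulary instances:
    a ``config.oov_fraction_heldout`` share uses entity symbols disjoint from
    the training pool, enabling out-of-vocabulary robustness experiments.
    """
    rng = np.random.default_rng(config.seed)
    train = generate_corpus(config, rng=rng, pmid_prefix="TRAIN")
    n_oov = int(round(config.oov_fraction_heldout * n_heldout))
    held_cfg = replace(config, n_instances=max(n_heldout - n_oov, 1))
    held = (generate_corpus(held_cfg, rng=rng, pmid_prefix="HELD")
            if n_heldout - n_oov > 0 else [])
    if n_oov > 0:
        oov_cfg = replace(config, n_instances=n_oov)
        held = held + generate_corpus(oov_cfg, rng=rng, oov=True,
                                      pmid_prefix="HELDOOV")
    return train, held


def write_cue_table(pairs: Sequence[tuple[RelationInstance, CueRecord]]) -> str:
    """Sidecar TSV of cue records, aligned row-for-row with the corpus."""
    rows = ["pmid\tsent_id\tverb_polarity\tmodifier\tquantity\tdistractor\toov"]
    for inst, cues in pairs:
        rows.append(
            f"{inst.pmid}\t{inst.sent_id}\t{cues.verb_polarity}"
            f"\t{cues.modifier or ''}\t{cues.quantity or ''}"
            f"\t{int(cues.distractor)}\t{int(cues.oov)}"
        )
    return "\n".join(rows) + "\n"
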