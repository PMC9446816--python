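"""Relation-annotated corpus I/O and validation.

A corpus is a list of :class:`RelationInstance` records: one sentence, two
typed entity mentions, and one of eight semantic relation labels arranged in
a three-level hierarchy (causality present? -> direction of causality ->
explicit quantity change).  Two on-disk dialects are supported: a TextAE-style
JSON document (``text`` + ``denotations`` + ``relations``) and a canonical
tab-separated table used as the exchange format throughout this package.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "CorpusError",
    "FormatError",
    "SchemaError",
    "StructuralError",
    "ValidationError",
    "LabelSchema",
    "DEFAULT_SCHEMA",
    "EntityMention",
    "RelationInstance",
    "CorpusStats",
    "normalize_label",
    "read_textae_json",
    "write_textae_json",
    "read_relation_table",
    "write_relation_table",
    "validate_instance",
    "corpus_stats",
    "collapse_to_binary",
    "label_parent",
]


class CorpusError(ValueError):
    """Base class for corpus I/O and validation failures."""


class FormatError(CorpusError):
    """Malformed file: missing columns, unparseable fields."""


class StructuralError(CorpusError):
    """Dangling cross-references inside an annotation document."""


class SchemaError(CorpusError):
    """A label or entity type outside the schema."""


class ValidationError(CorpusError):
    """Spans inconsistent with the sentence text."""


# ---------------------------------------------------------------------------
# Label schema
# ---------------------------------------------------------------------------

RELATION_LABELS: tuple[str, ...] = (
    "undirected_link",
    "directed_link",
    "positive_cause",
    "negative_cause",
    "positive_increase",
    "negative_decrease",
    "positive_decrease",
    "negative_increase",
)

# Three-level hierarchy: top level splits on whether causality is expressed;
# the second level on its direction; the third on an explicit quantity change.
PARENT_OF: dict[str, str | None] = {
    "undirected_link": None,
    "directed_link": None,
    "positive_cause": "directed_link",
    "negative_cause": "directed_link",
    "positive_increase": "positive_cause",
    "negative_decrease": "positive_cause",
    "positive_decrease": "negative_cause",
    "negative_increase": "negative_cause",
}

ENTITY_TYPES: tuple[str, ...] = (
    "biological_process",
    "cell",
    "compound",
    "dna",
    "enzyme",
    "gene",
    "hormone",
    "molecular_function",
    "phenotype",
    "protein",
    "rna",
    "virus",
)

SPLITS: tuple[str, ...] = ("train", "validate", "test")


def normalize_label(label: str) -> str:
    """Normalize a display form ("Positive Cause") to canonical snake_case."""
    return "_".join(str(label).strip().lower().replace("-", " ").split())


@dataclass(frozen=True)
class LabelSchema:
    """The 8 relation labels, their hierarchy, and the 12 entity types."""

    relation_labels: tuple[str, ...] = RELATION_LABELS
    parent_of: Mapping[str, str | None] = field(
        default_factory=lambda: dict(PARENT_OF)
    )
    negative_labels: frozenset[str] = frozenset({"undirected_link"})
    entity_types: tuple[str, ...] = ENTITY_TYPES

    def label_index(self, label: str) -> int:
        try:
            return self.relation_labels.index(label)
        except ValueError:
            raise SchemaError(f"unknown relation label: {label!r}") from None

    def canonical_label(self, label: str) -> str:
        name = normalize_label(label)
        if name not in self.relation_labels:
            raise SchemaError(f"unknown relation label: {label!r}")
        return name

    def canonical_entity_type(self, entity_type: str) -> str:
        name = normalize_label(entity_type)
        if name not in self.entity_types:
            raise SchemaError(f"unknown entity type: {entity_type!r}")
        return name


DEFAULT_SCHEMA = LabelSchema()


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntityMention:
    """A contiguous text span with a biomedical entity type.

    Offsets are 0-based, half-open: ``sentence[start:end] == text``.
    """

    text: str
    start: int
    end: int
    entity_type: str


@dataclass(frozen=True)
class RelationInstance:
    """One sentence with two entity mentions and their relation label.

    ``entity1`` is the subject role and ``entity2`` the object role; role
    order is annotation order, not textual order.  ``sent_id`` 0 denotes the
    document title.
    """

    pmid: str
    sent_id: int
    sentence: str
    entity1: EntityMention
    entity2: EntityMention
    label: str


def validate_instance(
    instance: RelationInstance, schema: LabelSchema = DEFAULT_SCHEMA
) -> list[str]:
    """Return a list of invariant violations (empty iff the instance is valid).

    Violations are data, not exceptions: each entry names the field and the
    rule broken.  Overlapping or nested entity pairs are rejected because the
    encoding layer's span-replacement operators are ill-defined on overlaps.
    """
    violations: list[str] = []
    if normalize_label(instance.label) not in schema.relation_labels:
        violations.append(f"label: unknown relation label {instance.label!r}")
    if instance.sent_id < 0:
        violations.append("sent_id: must be non-negative (0 = title)")
    n = len(instance.sentence)
    for name, ent in (("entity1", instance.entity1), ("entity2", instance.entity2)):
        if not 0 <= ent.start < ent.end <= n:
            violations.append(
                f"{name}: span ({ent.start}, {ent.end}) violates "
                f"0 <= start < end <= {n}"
            )
        elif instance.sentence[ent.start : ent.end] != ent.text:
            violations.append(
                f"{name}: sentence slice "
                f"{instance.sentence[ent.start:ent.end]!r} != surface {ent.text!r}"
            )
        if normalize_label(ent.entity_type) not in schema.entity_types:
            violations.append(f"{name}: unknown entity type {ent.entity_type!r}")
    e1, e2 = instance.entity1, instance.entity2
    if max(e1.start, e2.start) < min(e1.end, e2.end):
        violations.append("entity1/entity2: entity spans overlap")
    return violations


# ---------------------------------------------------------------------------
# TextAE-dialect JSON
# ---------------------------------------------------------------------------

def _as_documents(obj: object) -> list[dict]:
    if isinstance(obj, dict):
        return [obj]
    if isinstance(obj, list):
        return [d for d in obj]
    raise FormatError("TextAE JSON must be a document object or a list of them")


def read_textae_json(
    source: str | IO[str], schema: LabelSchema = DEFAULT_SCHEMA
) -> list[RelationInstance]:
    """Parse TextAE-dialect JSON into relation instances.

    Each document carries ``text``, ``denotations`` (entity spans:
    ``{id, span: {begin, end}, obj}``) and ``relations``
    (``{pred, subj, obj}`` referencing denotation ids).  ``subj`` maps to
    entity1 and ``obj`` to entity2; labels and entity types are normalized to
    canonical snake_case.
    """
    text = source.read() if hasattr(source, "read") else source
    try:
        parsed = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from exc

    instances: list[RelationInstance] = []
    for doc in _as_documents(parsed):
        if "text" not in doc:
            raise FormatError("TextAE document lacks a 'text' field")
        sent = doc["text"]
        pmid = str(doc.get("pmid", doc.get("sourceid", "")))
        sent_id = int(doc.get("sent_id", doc.get("divid", 0)))
        mentions: dict[str, EntityMention] = {}
        for den in doc.get("denotations", []):
            span = den["span"]
            begin, end = int(span["begin"]), int(span["end"])
            if not 0 <= begin < end <= len(sent):
                raise ValidationError(
                    f"denotation {den.get('id')!r}: span ({begin}, {end}) "
                    f"outside text of length {len(sent)}"
                )
            mentions[str(den["id"])] = EntityMention(
                text=sent[begin:end],
                start=begin,
                end=end,
                entity_type=schema.canonical_entity_type(den["obj"]),
            )
        for rel in doc.get("relations", []):
            subj, obj = str(rel["subj"]), str(rel["obj"])
            for ref in (subj, obj):
                if ref not in mentions:
                    raise StructuralError(
                        f"relation references missing denotation id {ref!r}"
                    )
            instances.append(
                RelationInstance(
                    pmid=pmid,
                    sent_id=sent_id,
                    sentence=sent,
                    entity1=mentions[subj],
                    entity2=mentions[obj],
                    label=schema.canonical_label(rel["pred"]),
                )
            )
    return instances


def write_textae_json(
    instances: Sequence[RelationInstance], schema: LabelSchema = DEFAULT_SCHEMA
) -> str:
    """Serialize instances as a list of TextAE-dialect documents.

    Instances sharing (pmid, sent_id, sentence) are merged into one document;
    denotations are deduplicated by span."""
    docs: dict[tuple[str, int, str], dict] = {}
    for inst in instances:
        key = (inst.pmid, inst.sent_id, inst.sentence)
        doc = docs.setdefault(
            key,
            {
                "pmid": inst.pmid,
                "sent_id": inst.sent_id,
                "text": inst.sentence,
                "denotations": [],
                "relations": [],
                "_spans": {},
            },
        )
        ids = []
        for ent in (inst.entity1, inst.entity2):
            span_key = (ent.start, ent.end)
            if span_key not in doc["_spans"]:
                tid = f"T{len(doc['_spans']) + 1}"
                doc["_spans"][span_key] = tid
                doc["denotations"].append(
                    {
                        "id": tid,
                        "span": {"begin": ent.start, "end": ent.end},
                        "obj": ent.entity_type,
                    }
                )
            ids.append(doc["_spans"][span_key])
        doc["relations"].append(
            {
                "id": f"R{len(doc['relations']) + 1}",
                "pred": inst.label,
                "subj": ids[0],
                "obj": ids[1],
            }
        )
    out = []
    for doc in docs.values():
        doc.pop("_spans")
        out.append(doc)
    return json.dumps(out, indent=2, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# Canonical relation table (TSV)
# ---------------------------------------------------------------------------

TABLE_COLUMNS: tuple[str, ...] = (
    "pmid",
    "sent_id",
    "sentence",
    "e1_text",
    "e1_start",
    "e1_end",
    "e1_type",
    "e2_text",
    "e2_start",
    "e2_end",
    "e2_type",
    "label",
)


def read_relation_table(
    source: str | IO[str], schema: LabelSchema = DEFAULT_SCHEMA
) -> list[RelationInstance]:
    """Read the canonical tab-separated relation table.

    The format is strict: UTF-8, LF line endings, the exact 12-column header,
    and no quoting or escaping — fields containing tabs or newlines are
    rejected at write time rather than escaped, so a plain split is exact.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    reader = csv.reader(handle, delimiter="\t", quoting=csv.QUOTE_NONE,
                        quotechar=None)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty relation table: missing header row") from None
    if tuple(header) != TABLE_COLUMNS:
        missing = set(TABLE_COLUMNS) - set(header)
        raise FormatError(
            f"bad header {header!r}; missing columns: {sorted(missing)}"
        )
    instances: list[RelationInstance] = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(TABLE_COLUMNS):
            raise FormatError(
                f"line {lineno}: expected {len(TABLE_COLUMNS)} fields, "
                f"got {len(row)}"
            )
        rec = dict(zip(TABLE_COLUMNS, row))
        try:
            sent_id = int(rec["sent_id"])
            e1 = EntityMention(rec["e1_text"], int(rec["e1_start"]),
                               int(rec["e1_end"]),
                               schema.canonical_entity_type(rec["e1_type"]))
            e2 = EntityMention(rec["e2_text"], int(rec["e2_start"]),
                               int(rec["e2_end"]),
                               schema.canonical_entity_type(rec["e2_type"]))
        except ValueError as exc:
            if isinstance(exc, CorpusError):
                raise
            raise FormatError(f"line {lineno}: {exc}") from exc
        inst = RelationInstance(
            pmid=rec["pmid"],
            sent_id=sent_id,
            sentence=rec["sentence"],
            entity1=e1,
            entity2=e2,
            label=schema.canonical_label(rec["label"]),
        )
        violations = validate_instance(inst, schema)
        if violations:
            raise ValidationError(f"line {lineno}: " + "; ".join(violations))
        instances.append(inst)
    return instances


def write_relation_table(
    instances: Iterable[RelationInstance], dest: IO[str] | None = None
) -> str:
    """Write the canonical relation table; returns the serialized text.

    Raises :class:`FormatError` on fields containing tab or newline, which
    the format forbids."""
    buf = io.StringIO()
    buf.write("\t".join(TABLE_COLUMNS) + "\n")
    for inst in instances:
        fields = [
            inst.pmid,
            str(inst.sent_id),
            inst.sentence,
            inst.entity1.text,
            str(inst.entity1.start),
            str(inst.entity1.end),
            inst.entity1.entity_type,
            inst.entity2.text,
            str(inst.entity2.start),
            str(inst.entity2.end),
            inst.entity2.entity_type,
            inst.label,
        ]
        for value in fields:
            if "\t" in value or "\n" in value or "\r" in value:
                raise FormatError(
                    f"field {value!r} contains a tab/newline; the relation "
                    "table does not escape"
                )
        buf.write("\t".join(fields) + "\n")
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------

@dataclass
class CorpusStats:
    """Counts over a corpus, per split and total.

    ``per_label_counts[split][label]`` and
    ``per_entity_type_counts[split][etype] = (left, right)`` where left/right
    is the textual position of the mention within the sentence.
    """

    n_documents: int
    n_relations: int
    n_entity_mentions: int
    per_label_counts: dict[str, dict[str, int]]
    per_entity_type_counts: dict[str, dict[str, tuple[int, int]]]

    def label_total(self, label: str) -> int:
        return sum(
            counts.get(label, 0) for counts in self.per_label_counts.values()
        )


def corpus_stats(
    splits: Mapping[str, Sequence[RelationInstance]] | Sequence[RelationInstance],
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> CorpusStats:
    """Summarize a corpus grouped by split (or a flat list, counted as train).

    Left/right mention counts follow textual order within the sentence: the
    mention starting earlier is the left one.
    """
    if not isinstance(splits, Mapping):
        splits = {"train": list(splits)}
    for name in splits:
        if name not in SPLITS:
            raise CorpusError(
                f"unknown split name {name!r}; expected one of {SPLITS}"
            )
    per_label: dict[str, dict[str, int]] = {}
    per_etype: dict[str, dict[str, list[int]]] = {}
    documents: set[str] = set()
    n_relations = 0
    for split, instances in splits.items():
        label_counts = per_label.setdefault(split, {})
        etype_counts = per_etype.setdefault(split, {})
        for inst in instances:
            n_relations += 1
            documents.add(inst.pmid)
            label = schema.canonical_label(inst.label)
            label_counts[label] = label_counts.get(label, 0) + 1
            left, right = sorted(
                (inst.entity1, inst.entity2), key=lambda e: (e.start, e.end)
            )
            for pos, ent in enumerate((left, right)):
                etype = schema.canonical_entity_type(ent.entity_type)
                etype_counts.setdefault(etype, [0, 0])[pos] += 1
    return CorpusStats(
        n_documents=len(documents),
        n_relations=n_relations,
        n_entity_mentions=2 * n_relations,
        per_label_counts=per_label,
        per_entity_type_counts={
            split: {etype: (c[0], c[1]) for etype, c in counts.items()}
            for split, counts in per_etype.items()
        },
    )


# ---------------------------------------------------------------------------
# Label hierarchy operations
# ---------------------------------------------------------------------------

def collapse_to_binary(label: str, schema: LabelSchema = DEFAULT_SCHEMA) -> str:
    """Collapse the 8-way schema to {positive, negative}.

    The undirected link — a correlation without causality — is the negative
    class; all seven directed labels are positive."""
    name = schema.canonical_label(label)
    return "negative" if name in schema.negative_labels else "positive"


def label_parent(label: str, schema: LabelSchema = DEFAULT_SCHEMA) -> str | None:
    """Parent of a label in the three-level hierarchy (None at the roots)."""
    return schema.parent_of[schema.canonical_label(label)]
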