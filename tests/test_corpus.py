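"""Corpus I/O: TextAE parsing, table round-trips, validation, statistics."""

import io
import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birelex.corpus import (
    DEFAULT_SCHEMA,
    CorpusError,
    EntityMention,
    FormatError,
    RelationInstance,
    SchemaError,
    StructuralError,
    ValidationError,
    collapse_to_binary,
    corpus_stats,
    label_parent,
    normalize_label,
    read_relation_table,
    read_textae_json,
    validate_instance,
    write_relation_table,
    write_textae_json,
)
from birelex.synthetic import GeneratorConfig, generate_corpus

MINIMAL_DOC = {
    "text": "A binds B",
    "denotations": [
        {"id": "T1", "span": {"begin": 0, "end": 1}, "obj": "gene"},
        {"id": "T2", "span": {"begin": 8, "end": 9}, "obj": "protein"},
    ],
    "relations": [{"id": "R1", "pred": "undirected_link",
                   "subj": "T1", "obj": "T2"}],
}


class TestLabelSchema:
    def test_eight_labels_twelve_entity_types(self):
        assert len(DEFAULT_SCHEMA.relation_labels) == 8
        assert len(DEFAULT_SCHEMA.entity_types) == 12
        assert DEFAULT_SCHEMA.negative_labels == {"undirected_link"}

    def test_hierarchy_reaches_a_root_within_two_steps(self):
        for label in DEFAULT_SCHEMA.relation_labels:
            steps = 0
            while label_parent(label) is not None:
                label = label_parent(label)
                steps += 1
                assert steps <= 2

    @pytest.mark.parametrize(
        "label,parent",
        [
            ("positive_increase", "positive_cause"),
            ("negative_decrease", "positive_cause"),
            ("positive_decrease", "negative_cause"),
            ("negative_increase", "negative_cause"),
            ("positive_cause", "directed_link"),
            ("negative_cause", "directed_link"),
            ("directed_link", None),
            ("undirected_link", None),
        ],
    )
    def test_label_parent(self, label, parent):
        assert label_parent(label) == parent

    def test_binary_collapse_maps_exactly_one_label_negative(self):
        collapsed = {l: collapse_to_binary(l)
                     for l in DEFAULT_SCHEMA.relation_labels}
        assert [l for l, b in collapsed.items() if b == "negative"] == [
            "undirected_link"
        ]
        assert collapse_to_binary("positive_increase") == "positive"

    def test_display_form_normalization(self):
        assert normalize_label("Positive Cause") == "positive_cause"
        assert collapse_to_binary("Positive Cause") == "positive"

    def test_unknown_label_errors(self):
        with pytest.raises(SchemaError):
            collapse_to_binary("sideways_link")
        with pytest.raises(SchemaError):
            label_parent("sideways_link")


class TestTextAE:
    def test_minimal_document(self):
        instances = read_textae_json(json.dumps(MINIMAL_DOC))
        assert len(instances) == 1
        inst = instances[0]
        assert inst.label == "undirected_link"
        assert inst.entity1.text == "A" and inst.entity2.text == "B"
        assert validate_instance(inst) == []

    def test_empty_relation_list(self):
        doc = dict(MINIMAL_DOC, relations=[])
        assert read_textae_json(json.dumps(doc)) == []

    def test_dangling_reference_is_structural_error(self):
        doc = dict(MINIMAL_DOC)
        doc["relations"] = [{"pred": "undirected_link", "subj": "T9",
                             "obj": "T2"}]
        with pytest.raises(StructuralError, match="T9"):
            read_textae_json(json.dumps(doc))

    def test_span_outside_text_is_validation_error(self):
        doc = json.loads(json.dumps(MINIMAL_DOC))
        doc["denotations"][0]["span"]["end"] = 99
        with pytest.raises(ValidationError):
            read_textae_json(json.dumps(doc))

    def test_unknown_pred_or_entity_type_is_schema_error(self):
        doc = json.loads(json.dumps(MINIMAL_DOC))
        doc["relations"][0]["pred"] = "mystery_link"
        with pytest.raises(SchemaError):
            read_textae_json(json.dumps(doc))
        doc = json.loads(json.dumps(MINIMAL_DOC))
        doc["denotations"][0]["obj"] = "gadget"
        with pytest.raises(SchemaError):
            read_textae_json(json.dumps(doc))

    def test_write_read_round_trip(self, small_corpus):
        instances = [inst for inst, _ in small_corpus]
        again = read_textae_json(write_textae_json(instances))
        assert again == instances


class TestRelationTable:
    def test_single_row_round_trip_is_byte_identical(self, simple_instance):
        text = write_relation_table([simple_instance])
        instances = read_relation_table(text)
        assert instances == [simple_instance]
        assert write_relation_table(instances) == text

    def test_header_only_gives_empty_list(self):
        header = write_relation_table([])
        assert read_relation_table(io.StringIO(header)) == []

    def test_missing_column_is_format_error(self):
        with pytest.raises(FormatError, match="label"):
            read_relation_table("pmid\tsent_id\n")

    def test_unparseable_offset_is_format_error(self, simple_instance):
        text = write_relation_table([simple_instance]).replace("\t0\t1\t", "\tx\t1\t")
        with pytest.raises(FormatError):
            read_relation_table(text)

    def test_surface_slice_mismatch_is_validation_error(self, simple_instance):
        bad = RelationInstance(
            "p", 0, "A activates B C",
            EntityMention("Z", 0, 1, "gene"),
            simple_instance.entity2, "positive_cause",
        )
        line = write_relation_table([simple_instance]).splitlines()[1]
        text = (write_relation_table([]) +
                line.replace("\tA\t", "\tZ\t", 1) + "\n")
        with pytest.raises(ValidationError):
            read_relation_table(text)
        assert any("surface" in v or "slice" in v
                   for v in validate_instance(bad))

    def test_tab_in_field_rejected_not_escaped(self):
        inst = RelationInstance(
            "p", 0, "A\tactivates B",
            EntityMention("A", 0, 1, "gene"),
            EntityMention("B", 12, 13, "protein"), "positive_cause",
        )
        with pytest.raises(FormatError):
            write_relation_table([inst])

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 30))
    def test_round_trip_identity_property(self, seed, n):
        instances = [
            inst for inst, _ in
            generate_corpus(GeneratorConfig(n_instances=n, seed=seed))
        ]
        assert read_relation_table(write_relation_table(instances)) == instances


class TestValidation:
    def test_valid_instance_has_no_violations(self, simple_instance):
        assert validate_instance(simple_instance) == []

    def test_inverted_span(self):
        inst = RelationInstance(
            "p", 0, "A activates B",
            EntityMention("A", 5, 3, "gene"),
            EntityMention("B", 12, 13, "protein"), "positive_cause",
        )
        violations = validate_instance(inst)
        assert len(violations) == 1
        assert "start < end" in violations[0]

    def test_overlapping_spans_rejected(self):
        inst = RelationInstance(
            "p", 0, "ABC activates D",
            EntityMention("ABC", 0, 3, "gene"),
            EntityMention("BC", 1, 3, "protein"), "positive_cause",
        )
        assert any("overlap" in v for v in validate_instance(inst))


class TestCorpusStats:
    def test_two_instance_example(self):
        instances = [
            RelationInstance("p1", 0, "A activates B",
                             EntityMention("A", 0, 1, "gene"),
                             EntityMention("B", 12, 13, "protein"),
                             "positive_cause"),
            RelationInstance("p2", 1, "A binds B",
                             EntityMention("A", 0, 1, "gene"),
                             EntityMention("B", 8, 9, "protein"),
                             "undirected_link"),
        ]
        report = corpus_stats(instances)
        assert report.n_relations == 2
        assert report.n_entity_mentions == 4
        assert report.n_documents == 2
        assert report.label_total("positive_cause") == 1

    def test_mentions_are_twice_relations(self):
        for n in (1, 7, 40, 100):
            pairs = generate_corpus(GeneratorConfig(n_instances=n, seed=n))
            report = corpus_stats([inst for inst, _ in pairs])
            assert report.n_entity_mentions == 2 * report.n_relations == 2 * n

    def test_split_totals_sum(self, small_corpus):
        instances = [inst for inst, _ in small_corpus]
        splits = {
            "train": instances[:60],
            "validate": instances[60:90],
            "test": instances[90:],
        }
        report = corpus_stats(splits)
        flat = corpus_stats(instances)
        for label in DEFAULT_SCHEMA.relation_labels:
            assert report.label_total(label) == flat.label_total(label)
        left_right = sum(
            c[0] + c[1]
            for counts in report.per_entity_type_counts.values()
            for c in counts.values()
        )
        assert left_right == report.n_entity_mentions

    def test_unknown_split_name_errors(self, simple_instance):
        with pytest.raises(CorpusError):
            corpus_stats({"dev": [simple_instance]})
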