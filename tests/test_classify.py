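"""Descriptor extraction, generic-name construction, step-1 grouping."""

import itertools
import random

import pytest

from foodagg.classify import (
    MatchConflict,
    build_generic_name,
    flag_multipacks,
    group_step1,
    match_dimension,
    parse_descriptors,
)
from foodagg.io import vocabulary_from_dict
from foodagg._text import normalize_text
from foodagg.model import PER_100ML

from conftest import MILK_PATH, make_record

GREEK_MILK_VOCAB = vocabulary_from_dict(
    {
        "categories": {
            MILK_PATH[0]: {
                "dimensions": [
                    {
                        "name": "animal_of_origin",
                        "tier": "primary",
                        "values": [
                            {"value": "cow milk", "patterns": ["αγελαδ"]},
                            {"value": "sheep milk", "patterns": ["προβει"]},
                        ],
                    },
                    {
                        "name": "processing",
                        "tier": "primary",
                        "values": [{"value": "strained", "patterns": ["στραγγιστ"]}],
                    },
                    {
                        "name": "fat_content",
                        "tier": "primary",
                        "values": [
                            {"value": "0% fat", "patterns": ["0%"]},
                            {"value": "2% fat", "patterns": ["2%"]},
                        ],
                    },
                    {
                        "name": "flavor",
                        "tier": "primary",
                        "default": "plain",
                        "values": [
                            {"value": "plain", "patterns": ["πλαιν"]},
                            {"value": "chocolate", "patterns": ["σοκολατ"]},
                        ],
                    },
                ]
            }
        }
    }
)


class TestMultipacks:
    def test_combo_name_flagged(self, vocabulary):
        records = [
            make_record("P1", long_name="ham and cheese combo"),
            make_record("P2", long_name="Bread, multigrain, wholegrain, sliced"),
        ]
        eligible, multipack = flag_multipacks(records, vocabulary)
        assert multipack == ["P1"]
        assert [r.product_id for r in eligible] == ["P2"]

    def test_empty_pattern_list_keeps_all(self, vocabulary):
        from foodagg.model import DescriptorVocabulary

        bare = DescriptorVocabulary(categories=dict(vocabulary.categories))
        records = [make_record("P1", long_name="crackers and jam combo")]
        eligible, multipack = flag_multipacks(records, bare)
        assert len(eligible) == 1 and multipack == []

    def test_partition(self, vocabulary):
        records = [make_record(f"P{i}", long_name=n) for i, n in enumerate(
            ["yogurt combo pack", "plain yogurt", "milk & cookies", "strained yogurt"]
        )]
        eligible, multipack = flag_multipacks(records, vocabulary)
        assert len(eligible) + len(multipack) == len(records)
        assert set(multipack) == {"P0", "P2"}


class TestParseDescriptors:
    def test_greek_long_name_matches_printed_example(self):
        record = make_record("P1", long_name="Γιαούρτι αγελάδος στραγγιστό 0% πλαίν")
        assignment = parse_descriptors(record, GREEK_MILK_VOCAB)
        assert assignment == {
            "animal_of_origin": "cow milk",
            "processing": "strained",
            "fat_content": "0% fat",
            "flavor": "plain",
        }
        name = build_generic_name(MILK_PATH, assignment, GREEK_MILK_VOCAB)
        assert name == "Yogurt, cow milk, strained, 0% fat, plain"

    def test_no_match_falls_back_to_defaults(self):
        record = make_record("P1", long_name="Παιδικο επιδορπιο")
        # flavor has a default; dimensions without one are omitted
        assert parse_descriptors(record, GREEK_MILK_VOCAB) == {"flavor": "plain"}

    def test_vocabulary_order_breaks_two_value_conflicts(self):
        record = make_record("P1", long_name="Γιαούρτι αγελάδος και πρόβειο")
        conflicts: list[MatchConflict] = []
        assignment = parse_descriptors(record, GREEK_MILK_VOCAB, conflicts=conflicts)
        assert assignment["animal_of_origin"] == "cow milk"  # earlier vocabulary value
        assert len(conflicts) == 1
        assert conflicts[0].matched_values == ("cow milk", "sheep milk")

    def test_tie_break_matches_brute_force(self):
        """The engine's first-match rule equals a naive scan over values."""
        dims = GREEK_MILK_VOCAB.dimensions_for(MILK_PATH[0])
        tokens = ["αγελαδ", "προβει", "στραγγιστ", "0%", "2%", "πλαιν", "σοκολατ"]
        rng = random.Random(3)
        for _ in range(50):
            name = " ".join(rng.sample(tokens, rng.randint(0, len(tokens))))
            record = make_record("P1", long_name=name or "x")
            assignment = parse_descriptors(record, GREEK_MILK_VOCAB)
            text = normalize_text(record.long_name)
            for dim in dims:
                expected = next(
                    (v.value for v in dim.values if any(p.search(text) for p in v.compiled)),
                    dim.default_value,
                )
                assert assignment.get(dim.name) == expected


class TestGenericName:
    def test_canonical_order_is_insertion_independent(self):
        a = {"flavor": "plain", "animal_of_origin": "cow milk"}
        b = {"animal_of_origin": "cow milk", "flavor": "plain"}
        na = build_generic_name(MILK_PATH, a, GREEK_MILK_VOCAB)
        nb = build_generic_name(MILK_PATH, b, GREEK_MILK_VOCAB)
        assert na == nb == "Yogurt, cow milk, plain"

    def test_empty_assignment_is_base_term(self):
        assert build_generic_name(MILK_PATH, {}, GREEK_MILK_VOCAB) == "Yogurt"


class TestGroupStep1:
    def test_partitions_by_descriptor_profile(self, vocabulary):
        records = [
            make_record(f"P{i}", long_name="Yogurt cow strained 0% fat plain")
            for i in range(4)
        ] + [
            make_record(f"Q{i}", long_name="Yogurt sheep classic full fat plain")
            for i in range(2)
        ]
        groups = group_step1(records, vocabulary)
        assert sorted(g.n for g in groups) == [2, 4]
        assert sum(g.n for g in groups) == 6
        all_ids = list(itertools.chain.from_iterable(g.member_ids for g in groups))
        assert sorted(all_ids) == sorted(r.product_id for r in records)

    def test_singleton(self, vocabulary):
        groups = group_step1([make_record("P1")], vocabulary)
        assert len(groups) == 1 and groups[0].n == 1

    def test_basis_is_part_of_the_key(self, vocabulary):
        records = [
            make_record("P1", long_name="Yogurt cow classic full fat plain"),
            make_record("P2", long_name="Yogurt cow classic full fat plain", basis=PER_100ML),
        ]
        groups = group_step1(records, vocabulary)
        assert len(groups) == 2  # per-100g and per-100mL never aggregate together

    def test_determinism(self, vocabulary, worked_records):
        eligible, _ = flag_multipacks(worked_records, vocabulary)
        first = group_step1(eligible, vocabulary)
        second = group_step1(list(eligible), vocabulary)
        assert [g.generic_name for g in first] == [g.generic_name for g in second]
        assert [g.member_ids for g in first] == [g.member_ids for g in second]
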