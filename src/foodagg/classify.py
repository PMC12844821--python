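"""Step 1 of the aggregation framework: deterministic descriptor extraction.

Product long names are screened within the category hierarchy for shared
qualitative attributes (animal or plant of origin, processing type, fat
level, flavoring, ...). Matching is rule-based on normalized text: for each
primary dimension the first matching descriptor value in vocabulary order
wins, with longer patterns tried first inside a value; multiple matches are
recorded as conflicts so the engine's tie-breaks stay auditable. Multipacks
of different foods (combo products) are flagged from the long name and
excluded from aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ._text import normalize_text
from .model import (
    PRIMARY,
    SECONDARY,
    STEP1,
    DescriptorVocabulary,
    Dimension,
    FoodRecord,
    GenericFoodGroup,
    assignment_key,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchConflict:
    """Several descriptor values of one dimension matched the same text."""

    product_id: str
    dimension: str
    matched_values: tuple[str, ...]
    assigned: str


def flag_multipacks(
    records: Sequence[FoodRecord], vocabulary: DescriptorVocabulary
) -> tuple[list[FoodRecord], list[str]]:
    """Partition records into aggregation-eligible ones and multipacks.

    Detection uses the long name only. With no multipack patterns configured
    every record is eligible.
    """
    eligible: list[FoodRecord] = []
    multipack_ids: list[str] = []
    for record in records:
        text = normalize_text(record.long_name)
        if any(p.search(text) for p in vocabulary.multipack_compiled):
            multipack_ids.append(record.product_id)
        else:
            eligible.append(record)
    return eligible, multipack_ids


def match_dimension(dimension: Dimension, text: str) -> tuple[Optional[str], tuple[str, ...]]:
    """Match normalized text against one dimension.

    Returns ``(assigned_value, all_matching_values)``. The assigned value is
    the first matching value in vocabulary order, or the dimension's default
    (``None`` if unset) when nothing matches.
    """
    matched = tuple(
        dv.value for dv in dimension.values if any(p.search(text) for p in dv.compiled)
    )
    if matched:
        return matched[0], matched
    return dimension.default_value, ()


def parse_descriptors(
    record: FoodRecord,
    vocabulary: DescriptorVocabulary,
    conflicts: Optional[list[MatchConflict]] = None,
    tier: str = PRIMARY,
) -> dict[str, str]:
    """Extract the descriptor assignment for one record.

    Primary dimensions are matched against the long name; secondary ones
    against the ingredient list and claims. Unmatched dimensions take their
    default value or are omitted. Pass a list as ``conflicts`` to collect
    multi-match events.
    """
    if tier == PRIMARY:
        text = normalize_text(record.long_name)
    elif tier == SECONDARY:
        parts = [record.ingredients_text or ""] + list(record.claims)
        text = normalize_text(" ".join(parts))
    else:
        raise ValueError(f"unknown tier {tier!r}")

    assignment: dict[str, str] = {}
    for dimension in vocabulary.dimensions_for(record.category, tier=tier):
        value, matched = match_dimension(dimension, text)
        if len(matched) > 1:
            logger.info(
                "record %s: dimension %r matched %s; assigned %r (vocabulary order)",
                record.product_id,
                dimension.name,
                list(matched),
                value,
            )
            if conflicts is not None:
                conflicts.append(
                    MatchConflict(record.product_id, dimension.name, matched, value)
                )
        if value is not None:
            assignment[dimension.name] = value
    return assignment


def build_generic_name(
    category_path: tuple[str, str, str, str],
    descriptor_assignment: Mapping[str, str],
    vocabulary: DescriptorVocabulary,
) -> str:
    """Canonical generic food name: base food term, then descriptor values.

    The base term is the deepest non-empty hierarchy level; descriptor values
    follow in the vocabulary's dimension order, comma-joined. Identical
    assignments always yield identical strings.
    """
    base = next((level for level in reversed(category_path) if level), category_path[0])
    dims = vocabulary.dimensions_for(category_path[0])
    ordered = assignment_key(descriptor_assignment, dims)
    return ", ".join([base] + [value for _, value in ordered])


def group_step1(
    records: Sequence[FoodRecord],
    vocabulary: DescriptorVocabulary,
    conflicts: Optional[list[MatchConflict]] = None,
) -> list[GenericFoodGroup]:
    """Partition records into candidate generic foods.

    The group key is (category_path, declaration basis, primary descriptor
    assignment); basis is part of the key so per-100 g and per-100 mL
    products never aggregate together. Groups are returned sorted by
    category path and generic name; membership order follows the input.
    """
    buckets: dict[tuple, list[FoodRecord]] = {}
    assignments: dict[tuple, dict[str, str]] = {}
    for record in records:
        assignment = parse_descriptors(record, vocabulary, conflicts=conflicts)
        dims = vocabulary.dimensions_for(record.category)
        key = (
            record.category_path,
            record.nutrients.basis,
            assignment_key(assignment, dims),
        )
        buckets.setdefault(key, []).append(record)
        assignments[key] = assignment

    groups = []
    for key, members in buckets.items():
        category_path, basis, _ = key
        assignment = assignments[key]
        groups.append(
            GenericFoodGroup(
                generic_name=build_generic_name(category_path, assignment, vocabulary),
                category_path=category_path,
                descriptor_assignment=dict(assignment),
                member_ids=tuple(r.product_id for r in members),
                basis=basis,
                provenance=STEP1,
            )
        )
    groups.sort(key=lambda g: (g.category_path, g.basis, g.generic_name))
    return groups
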