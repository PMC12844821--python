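"""Steps 2–3: homogeneity testing and iterative group refinement.

For every candidate generic food the mean, sample SD and coefficient of
variation (CV = SD/mean) of energy and the macronutrients are computed over
members with complete data. A CV above 20% in any trigger nutrient marks the
group heterogeneous; heterogeneous groups are split on secondary descriptors
mined from ingredient lists and on-pack claims, recursively, until every
subgroup is homogeneous or no candidate split improves on the parent — in
which case the heterogeneity is recorded as inherent.

A candidate split is accepted when every subgroup keeps at least two members
and the member-weighted mean of the subgroups' worst (max-over-nutrients) CV
falls strictly below the parent's worst CV; among accepted candidates the
largest improvement wins, with vocabulary order breaking ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import (
    MatchConflict,
    build_generic_name,
    flag_multipacks,
    group_step1,
    match_dimension,
)
from ._text import normalize_text
from .model import (
    GRADE_20_40,
    GRADE_GE40,
    GRADE_LT20,
    GRADE_UNDEFINED,
    SECONDARY,
    STAT_NUTRIENTS,
    STEP3_REFINED,
    TRIGGER_NUTRIENTS,
    AggregateProfile,
    DescriptorVocabulary,
    Dimension,
    FoodRecord,
    GenericFoodGroup,
    NutrientStats,
    QCResult,
)
from .qc import QCConfig, qc_filter

#: Value assigned to members matching no value of a secondary dimension that
#: has no configured default, so refined assignments always extend the parent.
UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class AggregationConfig:
    """Tunables of the homogeneity screen and refinement loop."""

    cv_heterogeneity_threshold: float = 0.20
    cv_grade_edges: tuple[float, float] = (0.20, 0.40)
    min_group_size_for_values: int = 3
    trigger_nutrients: tuple[str, ...] = TRIGGER_NUTRIENTS

    def __post_init__(self) -> None:
        if not 0 < self.cv_heterogeneity_threshold < 1:
            raise ValueError("cv_heterogeneity_threshold must lie in (0, 1)")
        lo, hi = self.cv_grade_edges
        if not lo < hi:
            raise ValueError("cv_grade_edges must be strictly increasing")
        if self.min_group_size_for_values < 2:
            raise ValueError("min_group_size_for_values must be >= 2")
        unknown = set(self.trigger_nutrients) - set(STAT_NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown trigger nutrients {sorted(unknown)}")


def grade_cv(cv: Optional[float], config: AggregationConfig | None = None) -> str:
    """CV homogeneity grade: <20%, 20–40%, >=40%, or undefined (passes through)."""
    if config is None:
        config = AggregationConfig()
    if cv is None:
        return GRADE_UNDEFINED
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    lo, hi = config.cv_grade_edges
    if cv < lo:
        return GRADE_LT20
    if cv < hi:
        return GRADE_20_40
    return GRADE_GE40


def summarize_group(
    group: GenericFoodGroup,
    records: Mapping[str, FoodRecord] | Sequence[FoodRecord],
    config: AggregationConfig | None = None,
) -> AggregateProfile:
    """Mean / sample SD / CV per nutrient over the group's complete members.

    Only members declaring every trigger nutrient enter the statistics
    (``n_complete``); fiber is additionally summarized over the complete
    members that declare it, but never graded or triggered on. CV conventions:
    SD/mean for positive means; 0 when both are 0; undefined (heterogeneous)
    when the mean is 0 with positive SD; undefined with no trigger effect when
    fewer than two values exist.
    """
    if config is None:
        config = AggregationConfig()
    by_id = _as_mapping(records)
    members = [by_id[pid] for pid in group.member_ids]
    complete = [m for m in members if m.nutrients.has_all(config.trigger_nutrients)]

    stats: dict[str, NutrientStats] = {}
    for nutrient in STAT_NUTRIENTS:
        values = np.array(
            [
                m.nutrients.get(nutrient)
                for m in complete
                if m.nutrients.get(nutrient) is not None
            ],
            dtype=float,
        )
        n = values.size
        if n == 0:
            stats[nutrient] = NutrientStats(None, None, None, GRADE_UNDEFINED, 0)
            continue
        mean = float(values.mean())
        if n < 2:
            stats[nutrient] = NutrientStats(mean, None, None, GRADE_UNDEFINED, n)
            continue
        sd = float(values.std(ddof=1))
        if mean > 0:
            cv: Optional[float] = sd / mean
        elif sd == 0:
            cv = 0.0  # all members identically zero: homogeneous
        else:
            cv = None  # zero mean with spread: CV undefined, heterogeneous
        grade = grade_cv(cv, config)
        if nutrient not in config.trigger_nutrients and nutrient not in TRIGGER_NUTRIENTS:
            grade = None  # descriptive-only nutrients are not graded
        stats[nutrient] = NutrientStats(mean, sd, cv, grade, n)

    return AggregateProfile(stats=stats, n_complete=len(complete), n_members=len(members))


def is_heterogeneous(profile: AggregateProfile, config: AggregationConfig | None = None) -> bool:
    """True iff any trigger nutrient's CV strictly exceeds the threshold, or
    is undefined because the mean is zero with positive spread.

    Groups with fewer than two complete members carry no variance estimate
    and therefore no evidence of heterogeneity.
    """
    if config is None:
        config = AggregationConfig()
    for nutrient in config.trigger_nutrients:
        st = profile.get(nutrient)
        if st is None:
            continue
        if st.cv is not None and st.cv > config.cv_heterogeneity_threshold:
            return True
        if st.zero_mean_spread:
            return True
    return False


def max_trigger_cv(profile: AggregateProfile, config: AggregationConfig) -> float:
    """Worst CV over the trigger nutrients; +inf for an undefined CV from a
    zero mean with spread, 0 when no CV is estimable."""
    worst = 0.0
    for nutrient in config.trigger_nutrients:
        st = profile.get(nutrient)
        if st is None:
            continue
        if st.zero_mean_spread:
            return math.inf
        if st.cv is not None:
            worst = max(worst, st.cv)
    return worst


@dataclass(frozen=True)
class RefinementStep:
    """One applied (or rejected-terminal) decision of the refinement loop."""

    parent_name: str
    dimension: Optional[str]  # None when the group was declared inherent
    parent_max_cv: float
    child_score: Optional[float]
    children: tuple[tuple[str, int], ...] = ()  # (generic_name, n) pairs


def _as_mapping(records: Mapping[str, FoodRecord] | Sequence[FoodRecord]) -> Mapping[str, FoodRecord]:
    if isinstance(records, Mapping):
        return records
    return {r.product_id: r for r in records}


def _secondary_value(record: FoodRecord, dimension: Dimension) -> str:
    text = normalize_text(" ".join([record.ingredients_text or ""] + list(record.claims)))
    value, _ = match_dimension(dimension, text)
    if value is None:
        value = UNSPECIFIED
    return value


def _partition_by(
    members: Sequence[FoodRecord], dimension: Dimension
) -> dict[str, list[FoodRecord]]:
    buckets: dict[str, list[FoodRecord]] = {}
    for member in members:
        buckets.setdefault(_secondary_value(member, dimension), []).append(member)
    return buckets


def _make_child(
    parent: GenericFoodGroup,
    dimension: Dimension,
    value: str,
    members: Sequence[FoodRecord],
    vocabulary: DescriptorVocabulary,
) -> GenericFoodGroup:
    assignment = dict(parent.descriptor_assignment)
    assignment[dimension.name] = value
    return GenericFoodGroup(
        generic_name=build_generic_name(parent.category_path, assignment, vocabulary),
        category_path=parent.category_path,
        descriptor_assignment=assignment,
        member_ids=tuple(m.product_id for m in members),
        basis=parent.basis,
        provenance=STEP3_REFINED,
    )


def refine_group(
    group: GenericFoodGroup,
    records: Mapping[str, FoodRecord] | Sequence[FoodRecord],
    vocabulary: DescriptorVocabulary,
    config: AggregationConfig | None = None,
    log: Optional[list[RefinementStep]] = None,
) -> tuple[list[GenericFoodGroup], bool]:
    """Split a heterogeneous group on secondary descriptors, recursively.

    Every unused secondary dimension of the category is evaluated; accepted
    candidates must keep >= 2 members per subgroup and strictly lower the
    member-weighted mean of the subgroups' worst CV below the parent's worst
    CV. The best accepted candidate is applied and each still-heterogeneous
    subgroup is refined with the remaining dimensions. With no accepted
    candidate the group is returned intact with ``inherent = True``.

    Raises ``ValueError`` when called on a homogeneous group.
    """
    if config is None:
        config = AggregationConfig()
    by_id = _as_mapping(records)
    profile = summarize_group(group, by_id, config)
    if not is_heterogeneous(profile, config):
        raise ValueError(
            f"refine_group called on homogeneous group {group.generic_name!r}"
        )

    members = [by_id[pid] for pid in group.member_ids]
    unused = [
        d
        for d in vocabulary.dimensions_for(group.category, tier=SECONDARY)
        if d.name not in group.descriptor_assignment
    ]
    parent_score = max_trigger_cv(profile, config)

    best: Optional[tuple[float, Dimension, dict[str, list[FoodRecord]], float]] = None
    for dimension in unused:  # vocabulary order: ties keep the earlier dimension
        buckets = _partition_by(members, dimension)
        if len(buckets) < 2 or any(len(b) < 2 for b in buckets.values()):
            continue
        total = 0
        weighted = 0.0
        for value, bucket in buckets.items():
            child = _make_child(group, dimension, value, bucket, vocabulary)
            child_profile = summarize_group(child, by_id, config)
            weighted += len(bucket) * max_trigger_cv(child_profile, config)
            total += len(bucket)
        score = weighted / total
        if score < parent_score and (best is None or score < best[0]):
            best = (score, dimension, buckets, parent_score)

    if best is None:
        refined = replace(group, inherent_heterogeneity=True)
        if log is not None:
            log.append(
                RefinementStep(group.generic_name, None, parent_score, None)
            )
        return [refined], True

    score, dimension, buckets, parent_score = best
    children = [
        _make_child(group, dimension, value, bucket, vocabulary)
        for value, bucket in sorted(buckets.items())
    ]
    if log is not None:
        log.append(
            RefinementStep(
                group.generic_name,
                dimension.name,
                parent_score,
                score,
                tuple((c.generic_name, c.n) for c in children),
            )
        )

    leaves: list[GenericFoodGroup] = []
    for child in children:
        child_profile = summarize_group(child, by_id, config)
        if is_heterogeneous(child_profile, config):
            sub_leaves, _ = refine_group(child, by_id, vocabulary, config, log)
            leaves.extend(sub_leaves)
        else:
            leaves.append(child)
    return leaves, False


@dataclass
class PipelineResult:
    """Everything the full aggregation run produces."""

    groups: list[GenericFoodGroup]
    profiles: dict[str, AggregateProfile]  # keyed by generic_name, all groups
    emitted_profiles: dict[str, AggregateProfile]  # n_complete >= min size
    qc_results: list[QCResult]
    excluded_ids: list[str]
    multipack_ids: list[str]
    refinement_log: list[RefinementStep] = field(default_factory=list)
    conflicts: list[MatchConflict] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "input": len(self.qc_results),
            "excluded": len(self.excluded_ids),
            "multipack": len(self.multipack_ids),
            "grouped": sum(g.n for g in self.groups),
            "groups": len(self.groups),
        }


def aggregate_pipeline(
    records: Sequence[FoodRecord],
    vocabulary: DescriptorVocabulary,
    qc_config: QCConfig | None = None,
    agg_config: AggregationConfig | None = None,
) -> PipelineResult:
    """Run the full three-step aggregation: QC screen, multipack exclusion,
    name-based grouping, homogeneity testing and secondary refinement.

    Every input record ends up in exactly one place: QC-excluded, multipack,
    or member of exactly one final group. Aggregated values are emitted only
    for groups whose complete-member count reaches
    ``agg_config.min_group_size_for_values``.
    """
    if qc_config is None:
        qc_config = QCConfig()
    if agg_config is None:
        agg_config = AggregationConfig()

    included, qc_results = qc_filter(records, qc_config)
    excluded_ids = [r.product_id for r in qc_results if r.status == "excluded"]
    eligible, multipack_ids = flag_multipacks(included, vocabulary)

    conflicts: list[MatchConflict] = []
    step1_groups = group_step1(eligible, vocabulary, conflicts=conflicts)

    by_id = {r.product_id: r for r in eligible}
    log: list[RefinementStep] = []
    final_groups: list[GenericFoodGroup] = []
    for group in step1_groups:
        profile = summarize_group(group, by_id, agg_config)
        if is_heterogeneous(profile, agg_config):
            leaves, _ = refine_group(group, by_id, vocabulary, agg_config, log)
            final_groups.extend(leaves)
        else:
            final_groups.append(group)
    final_groups.sort(key=lambda g: (g.category_path, g.basis, g.generic_name))

    profiles = {
        g.generic_name: summarize_group(g, by_id, agg_config) for g in final_groups
    }
    emitted = {
        name: p
        for name, p in profiles.items()
        if p.n_complete >= agg_config.min_group_size_for_values
    }
    return PipelineResult(
        groups=final_groups,
        profiles=profiles,
        emitted_profiles=emitted,
        qc_results=qc_results,
        excluded_ids=excluded_ids,
        multipack_ids=multipack_ids,
        refinement_log=log,
        conflicts=conflicts,
    )
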