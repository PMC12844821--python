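"""Domain types for branded-food composition aggregation.

A branded food composition database (BFCD) holds per-product label-declared
nutrition data. The types here carry one branded product (:class:`FoodRecord`
with its :class:`NutrientProfile`), the verdict of the plausibility screen
(:class:`QCResult`), the descriptor vocabulary driving name-based grouping
(:class:`DescriptorVocabulary`), a candidate generic food
(:class:`GenericFoodGroup`) and its aggregated nutrient statistics
(:class:`AggregateProfile`).

Nutrient amounts are declared per 100 g or per 100 mL: energy in kcal,
sodium in mg, everything else in g. Every nutrient is optional — label
completeness varies — and missingness is preserved, never imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Pattern, Sequence

from ._text import normalize_pattern

#: All nutrient fields carried by a profile, in canonical column order.
NUTRIENTS: tuple[str, ...] = (
    "energy",
    "protein",
    "total_fat",
    "sfa",
    "carbohydrate",
    "total_sugars",
    "fiber",
    "polyols",
    "sodium",
)

#: Nutrients that participate in the CV heterogeneity trigger. Fiber and
#: polyols feed the energy audit only; fiber is still described by means.
TRIGGER_NUTRIENTS: tuple[str, ...] = (
    "energy",
    "protein",
    "total_fat",
    "sfa",
    "carbohydrate",
    "total_sugars",
    "sodium",
)

#: Nutrients summarized per group (the trigger set plus fiber).
STAT_NUTRIENTS: tuple[str, ...] = TRIGGER_NUTRIENTS + ("fiber",)

PER_100G = "per_100g"
PER_100ML = "per_100mL"
BASES = (PER_100G, PER_100ML)

# QC reason codes
ENERGY_MISMATCH = "energy_mismatch"
SFA_GT_FAT = "sfa_gt_fat"
SUGARS_GT_CARB = "sugars_gt_carb"
IMPROBABLE_VALUE = "improbable_value"
MISSING_IMAGE_PROXY = "missing_image_proxy"
QC_REASONS = (
    ENERGY_MISMATCH,
    SFA_GT_FAT,
    SUGARS_GT_CARB,
    IMPROBABLE_VALUE,
    MISSING_IMAGE_PROXY,
)

PRIMARY = "primary"
SECONDARY = "secondary"

STEP1 = "step1"
STEP3_REFINED = "step3_refined"

# CV grade labels
GRADE_LT20 = "lt20"
GRADE_20_40 = "between20and40"
GRADE_GE40 = "ge40"
GRADE_UNDEFINED = "undefined"
GRADES = (GRADE_LT20, GRADE_20_40, GRADE_GE40, GRADE_UNDEFINED)


@dataclass(frozen=True)
class NutrientProfile:
    """Label-declared nutrient amounts per 100 g / 100 mL of product."""

    energy: Optional[float] = None
    protein: Optional[float] = None
    total_fat: Optional[float] = None
    sfa: Optional[float] = None
    carbohydrate: Optional[float] = None
    total_sugars: Optional[float] = None
    fiber: Optional[float] = None
    polyols: Optional[float] = None
    sodium: Optional[float] = None
    basis: str = PER_100G

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}; expected one of {BASES}")
        for name in NUTRIENTS:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"nutrient {name!r} must be >= 0, got {value}")
        # sfa > total_fat and total_sugars > carbohydrate are *legal* here:
        # they are label errors the QC screen exists to catch.

    def get(self, nutrient: str) -> Optional[float]:
        if nutrient not in NUTRIENTS:
            raise KeyError(nutrient)
        return getattr(self, nutrient)

    def has_all(self, nutrients: Iterable[str]) -> bool:
        return all(self.get(n) is not None for n in nutrients)


@dataclass(frozen=True)
class FoodRecord:
    """One branded product as read from the description/nutrients/claims files."""

    product_id: str
    long_name: str
    category_path: tuple[str, str, str, str]
    nutrients: NutrientProfile
    ingredients_text: Optional[str] = None
    claims: tuple[str, ...] = ()
    image_complete: bool = True

    def __post_init__(self) -> None:
        if not self.product_id:
            raise ValueError("product_id must be non-empty")
        if not self.long_name:
            raise ValueError(f"record {self.product_id}: long_name must be non-empty")
        if len(self.category_path) != 4:
            raise ValueError(
                f"record {self.product_id}: category_path must have 4 levels"
            )
        seen_empty = False
        for level in self.category_path:
            if level == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"record {self.product_id}: category_path levels must be "
                    "non-empty from the left (no gaps)"
                )
        if self.category_path[0] == "":
            raise ValueError(f"record {self.product_id}: category level is empty")

    @property
    def category(self) -> str:
        return self.category_path[0]

    @property
    def subgroup(self) -> str:
        """Deepest non-empty level of the hierarchy; the base food term."""
        for level in reversed(self.category_path):
            if level:
                return level
        return self.category_path[0]


@dataclass(frozen=True)
class QCResult:
    """Verdict of the plausibility screen for one record."""

    product_id: str
    status: str  # "included" | "excluded"
    reasons: frozenset[str] = frozenset()
    energy_calculated: Optional[float] = None
    energy_rel_diff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("included", "excluded"):
            raise ValueError(f"unknown status {self.status!r}")
        unknown = set(self.reasons) - set(QC_REASONS)
        if unknown:
            raise ValueError(f"unknown QC reasons {sorted(unknown)}")
        if (self.status == "excluded") != bool(self.reasons):
            raise ValueError("status must be 'excluded' iff reasons is non-empty")


@dataclass(frozen=True)
class DescriptorValue:
    """One allowed value of a descriptor dimension with its match patterns."""

    value: str
    patterns: tuple[str, ...]
    compiled: tuple[Pattern[str], ...] = field(
        default=(), compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("descriptor value must be non-empty")
        if not self.patterns:
            raise ValueError(f"descriptor value {self.value!r} has no patterns")
        if not self.compiled:
            compiled = []
            # Longest pattern first so the most specific token wins within a value.
            for pat in sorted(self.patterns, key=len, reverse=True):
                try:
                    compiled.append(re.compile(normalize_pattern(pat)))
                except re.error as exc:
                    raise ValueError(
                        f"invalid pattern {pat!r} for descriptor value "
                        f"{self.value!r}: {exc}"
                    ) from exc
            object.__setattr__(self, "compiled", tuple(compiled))


@dataclass(frozen=True)
class Dimension:
    """A descriptor dimension (e.g. animal of origin, fat content).

    ``primary`` dimensions match against the product long name; ``secondary``
    dimensions match against ingredient lists and on-pack claims.
    """

    name: str
    tier: str
    values: tuple[DescriptorValue, ...]
    default_value: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("dimension name must be non-empty")
        if self.tier not in (PRIMARY, SECONDARY):
            raise ValueError(
                f"dimension {self.name!r}: unknown tier {self.tier!r} "
                f"(expected {PRIMARY!r} or {SECONDARY!r})"
            )
        if not self.values:
            raise ValueError(f"dimension {self.name!r} must have >= 1 value")


@dataclass(frozen=True)
class DescriptorVocabulary:
    """Per-category descriptor dimensions plus multipack detection patterns."""

    categories: Mapping[str, tuple[Dimension, ...]]
    multipack_patterns: tuple[str, ...] = ()
    multipack_compiled: tuple[Pattern[str], ...] = field(
        default=(), compare=False, repr=False
    )

    def __post_init__(self) -> None:
        for category, dims in self.categories.items():
            names = [d.name for d in dims]
            if len(names) != len(set(names)):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise ValueError(
                    f"category {category!r}: duplicate dimension names {dupes}"
                )
        if not self.multipack_compiled:
            compiled = []
            for pat in self.multipack_patterns:
                try:
                    compiled.append(re.compile(normalize_pattern(pat)))
                except re.error as exc:
                    raise ValueError(f"invalid multipack pattern {pat!r}: {exc}") from exc
            object.__setattr__(self, "multipack_compiled", tuple(compiled))

    def dimensions_for(self, category: str, tier: Optional[str] = None) -> tuple[Dimension, ...]:
        dims = tuple(self.categories.get(category, ()))
        if tier is None:
            return dims
        return tuple(d for d in dims if d.tier == tier)


@dataclass
class GenericFoodGroup:
    """A candidate generic food: shared hierarchy position + descriptor values."""

    generic_name: str
    category_path: tuple[str, str, str, str]
    descriptor_assignment: dict[str, str]
    member_ids: tuple[str, ...]
    basis: str = PER_100G
    provenance: str = STEP1
    inherent_heterogeneity: bool = False

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError(f"group {self.generic_name!r} must have >= 1 member")
        if self.provenance not in (STEP1, STEP3_REFINED):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")

    @property
    def n(self) -> int:
        return len(self.member_ids)

    @property
    def category(self) -> str:
        return self.category_path[0]


@dataclass(frozen=True)
class NutrientStats:
    """Mean / sample SD / CV and homogeneity grade for one nutrient in a group.

    ``sd`` and ``cv`` are ``None`` when fewer than two values are available.
    ``cv`` is also ``None`` when the mean is zero with positive spread — that
    case carries ``grade == "undefined"`` and counts as heterogeneous.
    """

    mean: Optional[float]
    sd: Optional[float]
    cv: Optional[float]
    grade: Optional[str]
    n: int

    @property
    def zero_mean_spread(self) -> bool:
        return (
            self.mean is not None
            and self.mean == 0
            and self.sd is not None
            and self.sd > 0
        )


@dataclass(frozen=True)
class AggregateProfile:
    """Per-nutrient descriptive statistics for one generic food group."""

    stats: Mapping[str, NutrientStats]
    n_complete: int
    n_members: int

    def get(self, nutrient: str) -> Optional[NutrientStats]:
        return self.stats.get(nutrient)


def assignment_key(
    assignment: Mapping[str, str], dimensions: Sequence[Dimension]
) -> tuple[tuple[str, str], ...]:
    """Canonical ordering of a descriptor assignment: vocabulary dimension
    order first, then (for dimensions unknown to the vocabulary) name order."""
    order = {d.name: i for i, d in enumerate(dimensions)}
    return tuple(
        (name, assignment[name])
        for name in sorted(assignment, key=lambda n: (order.get(n, len(order)), n))
    )
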