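"""Synthetic branded-food databases with known ground truth.

The generator emits the same multi-file layout the reader consumes
(description / nutrients / claims / ingredients) plus a truth table mapping
every product to its planted group, latent secondary descriptor, QC
violation, multipack flag and boundary flag — so every pipeline stage can be
tested end-to-end without any real database.

Study conditions baked into the defaults: group sizes are skewed small (many
candidate generic foods come from one or two products), within-group
nutrient values are truncated-normal with ~8% CV (homogeneous formulations),
a minority of groups hide a binary formulation split (e.g. sugar-sweetened
vs. non-nutritive-sweetened) that shifts one nutrient's mean by several
within-group SDs, and a few percent of labels carry planted quality
violations. Declared energy is derived from the drawn macronutrients with
small relative noise for clean records and an out-of-tolerance offset for
planted energy violations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ENERGY_MISMATCH,
    IMPROBABLE_VALUE,
    MISSING_IMAGE_PROXY,
    NUTRIENTS,
    PER_100G,
    PER_100ML,
    PRIMARY,
    SECONDARY,
    SFA_GT_FAT,
    SUGARS_GT_CARB,
    DescriptorValue,
    DescriptorVocabulary,
    Dimension,
    FoodRecord,
    NutrientProfile,
)
from .qc import QCConfig, compute_energy

# ---------------------------------------------------------------------------
# Category templates
# ---------------------------------------------------------------------------

#: effect ops applied to a group's mean vector: ("set"|"mul"|"add", value)
Effect = tuple[str, float]


@dataclass(frozen=True)
class DimValueSpec:
    value: str
    token: str  # word(s) planted in the long name
    effects: Mapping[str, Effect] = field(default_factory=dict)


@dataclass(frozen=True)
class DimSpec:
    name: str
    values: tuple[DimValueSpec, ...]


@dataclass(frozen=True)
class LatentSpec:
    """A binary secondary descriptor hidden in the ingredient list."""

    dimension: str
    high_value: str
    high_token: str
    high_patterns: tuple[str, ...]
    low_value: str
    low_token: str
    low_patterns: tuple[str, ...]
    target: str  # nutrient whose mean is shifted on the high side
    vocab_order: tuple[str, ...]  # value order in the vocabulary


@dataclass(frozen=True)
class SubgroupTemplate:
    path: tuple[str, str, str, str]
    basis: str
    means: Mapping[str, float]  # protein, total_fat, carbohydrate, fiber, sodium
    sfa_ratio: float
    sugars_ratio: float
    ingredients: str


@dataclass(frozen=True)
class CategoryTemplate:
    name: str
    subgroups: tuple[SubgroupTemplate, ...]
    dims: tuple[DimSpec, ...]
    latent: Optional[LatentSpec] = None


_MILK = "Milk, milk product or milk substitute"
_GRAIN = "Grain or grain product"
_VEG = "Vegetable or vegetable product"
_FAT = "Fat or fat product"
_MISC = "Miscellaneous food product"

MILK_TEMPLATE = CategoryTemplate(
    name=_MILK,
    subgroups=(
        SubgroupTemplate(
            (_MILK, "Dairy", "Fermented milks", "Yogurt"),
            PER_100G,
            {"protein": 5.0, "total_fat": 3.0, "carbohydrate": 5.0, "fiber": 0.0, "sodium": 60.0},
            sfa_ratio=0.65,
            sugars_ratio=0.85,
            ingredients="pasteurized milk, yogurt cultures",
        ),
        SubgroupTemplate(
            (_MILK, "Dairy", "Liquid milks", "Milk"),
            PER_100ML,
            {"protein": 3.3, "total_fat": 3.5, "carbohydrate": 4.8, "fiber": 0.0, "sodium": 45.0},
            sfa_ratio=0.65,
            sugars_ratio=0.95,
            ingredients="pasteurized cow milk",
        ),
    ),
    dims=(
        DimSpec(
            "animal_of_origin",
            (
                DimValueSpec("cow", "cow"),
                DimValueSpec("sheep", "sheep", {"total_fat": ("mul", 1.7), "protein": ("mul", 1.15)}),
                DimValueSpec("goat", "goat", {"total_fat": ("mul", 1.25)}),
            ),
        ),
        DimSpec(
            "processing",
            (
                DimValueSpec("strained", "strained", {"protein": ("mul", 1.8)}),
                DimValueSpec("classic", "classic"),
                DimValueSpec("pasteurized", "pasteurized"),
                DimValueSpec("UHT", "uht"),
            ),
        ),
        DimSpec(
            "fat_content",
            (
                DimValueSpec("0% fat", "0% fat", {"total_fat": ("set", 0.2)}),
                DimValueSpec("2% fat", "2% fat", {"total_fat": ("set", 2.0)}),
                DimValueSpec("full fat", "full fat"),
            ),
        ),
        DimSpec(
            "flavor",
            (
                DimValueSpec("plain", "plain"),
                DimValueSpec("chocolate", "chocolate", {"carbohydrate": ("add", 8.0)}),
                DimValueSpec("strawberry", "strawberry", {"carbohydrate": ("add", 6.0)}),
            ),
        ),
    ),
    latent=LatentSpec(
        dimension="sweetener",
        high_value="with sugar",
        high_token="sugar",
        high_patterns=(r"\bsugar\b",),
        low_value="with sweeteners",
        low_token="sweeteners (stevia)",
        low_patterns=(r"\bstevia\b", r"\bsweeteners?\b"),
        target="carbohydrate",
        vocab_order=("with sweeteners", "with sugar"),
    ),
)

GRAIN_TEMPLATE = CategoryTemplate(
    name=_GRAIN,
    subgroups=(
        SubgroupTemplate(
            (_GRAIN, "Cereal products", "Breads", "Bread"),
            PER_100G,
            {"protein": 9.0, "total_fat": 1.5, "carbohydrate": 46.0, "fiber": 5.0, "sodium": 450.0},
            sfa_ratio=0.2,
            sugars_ratio=0.07,
            ingredients="wheat flour, water, yeast, salt",
        ),
        SubgroupTemplate(
            (_GRAIN, "Cereal products", "Sweet bakery", "Biscuits"),
            PER_100G,
            {"protein": 7.0, "total_fat": 16.0, "carbohydrate": 62.0, "fiber": 3.0, "sodium": 300.0},
            sfa_ratio=0.45,
            sugars_ratio=0.35,
            ingredients="wheat flour, vegetable oils",
        ),
        SubgroupTemplate(
            (_GRAIN, "Cereal products", "Breakfast cereals", "Breakfast cereal"),
            PER_100G,
            {"protein": 8.5, "total_fat": 5.0, "carbohydrate": 65.0, "fiber": 7.0, "sodium": 200.0},
            sfa_ratio=0.3,
            sugars_ratio=0.25,
            ingredients="wheat flour, oat flakes",
        ),
    ),
    dims=(
        DimSpec(
            "main_grain",
            (
                DimValueSpec("wheat", "wheat"),
                DimValueSpec("oat", "oat", {"fiber": ("mul", 1.3)}),
                DimValueSpec("multigrain", "multigrain", {"fiber": ("mul", 1.2)}),
                DimValueSpec("spelt", "spelt"),
            ),
        ),
        DimSpec(
            "processing",
            (
                DimValueSpec("wholegrain", "wholegrain", {"fiber": ("mul", 1.6)}),
                DimValueSpec("white", "white"),
            ),
        ),
        DimSpec(
            "format",
            (
                DimValueSpec("sliced", "sliced"),
                DimValueSpec("toast", "toast"),
            ),
        ),
        DimSpec(
            "coating",
            (
                DimValueSpec(
                    "chocolate coating",
                    "chocolate coating",
                    {"carbohydrate": ("add", 5.0), "total_fat": ("add", 6.0)},
                ),
                DimValueSpec("plain", "plain"),
            ),
        ),
    ),
    latent=LatentSpec(
        dimension="fortification",
        high_value="protein fortified",
        high_token="whey protein",
        high_patterns=(r"\bwhey protein\b", r"\bpea protein\b"),
        low_value="standard",
        low_token="",  # the base recipe already names flour
        low_patterns=(r"\bflour\b",),
        target="protein",
        vocab_order=("protein fortified", "standard"),
    ),
)

VEG_TEMPLATE = CategoryTemplate(
    name=_VEG,
    subgroups=(
        SubgroupTemplate(
            (_VEG, "Vegetables", "Canned vegetables", "Asparagus"),
            PER_100G,
            {"protein": 1.8, "total_fat": 0.3, "carbohydrate": 3.0, "fiber": 1.5, "sodium": 280.0},
            sfa_ratio=0.2,
            sugars_ratio=0.5,
            ingredients="asparagus, water",
        ),
        SubgroupTemplate(
            (_VEG, "Vegetables", "Frozen vegetables", "Spinach"),
            PER_100G,
            {"protein": 2.8, "total_fat": 0.4, "carbohydrate": 2.0, "fiber": 2.2, "sodium": 70.0},
            sfa_ratio=0.2,
            sugars_ratio=0.45,
            ingredients="spinach",
        ),
        SubgroupTemplate(
            (_VEG, "Vegetables", "Canned vegetables", "Mushrooms"),
            PER_100G,
            {"protein": 2.5, "total_fat": 0.4, "carbohydrate": 3.5, "fiber": 1.8, "sodium": 320.0},
            sfa_ratio=0.2,
            sugars_ratio=0.5,
            ingredients="mushrooms, water",
        ),
    ),
    dims=(
        DimSpec(
            "processing",
            (
                DimValueSpec("canned", "canned"),
                DimValueSpec("frozen", "frozen"),
                DimValueSpec(
                    "dried",
                    "dried",
                    {
                        "protein": ("mul", 4.0),
                        "carbohydrate": ("mul", 4.0),
                        "fiber": ("mul", 4.0),
                        "sodium": ("mul", 2.0),
                    },
                ),
            ),
        ),
        DimSpec(
            "liquid_matrix",
            (
                DimValueSpec("in brine", "in brine", {"sodium": ("mul", 2.2)}),
                DimValueSpec("in oil", "in oil", {"total_fat": ("add", 8.0)}),
                DimValueSpec("in syrup", "in syrup", {"carbohydrate": ("add", 8.0)}),
            ),
        ),
        DimSpec(
            "additions",
            (DimValueSpec("with spices", "with spices"),),
        ),
    ),
    latent=LatentSpec(
        dimension="liquid_consumed",
        high_value="non-drained",
        high_token="with brine liquid",
        high_patterns=(r"\bbrine liquid\b",),
        low_value="drained",
        low_token="drained",
        low_patterns=(r"\bdrained\b",),
        target="sodium",
        vocab_order=("non-drained", "drained"),
    ),
)

FAT_TEMPLATE = CategoryTemplate(
    name=_FAT,
    subgroups=(
        SubgroupTemplate(
            (_FAT, "Fats", "Animal fats", "Butter"),
            PER_100G,
            {"protein": 0.7, "total_fat": 82.0, "carbohydrate": 0.7, "fiber": 0.0, "sodium": 20.0},
            sfa_ratio=0.65,
            sugars_ratio=0.85,
            ingredients="cream",
        ),
        SubgroupTemplate(
            (_FAT, "Fats", "Plant fats", "Margarine"),
            PER_100G,
            {"protein": 0.2, "total_fat": 60.0, "carbohydrate": 0.5, "fiber": 0.0, "sodium": 150.0},
            sfa_ratio=0.35,
            sugars_ratio=0.6,
            ingredients="vegetable oils, water, emulsifier",
        ),
    ),
    dims=(
        DimSpec(
            "origin",
            (
                DimValueSpec("cow", "cow"),
                DimValueSpec("sunflower", "sunflower"),
                DimValueSpec("olive oil mix", "olive"),
            ),
        ),
        DimSpec(
            "form",
            (
                DimValueSpec("spreadable", "spreadable"),
                DimValueSpec("solid", "block"),
            ),
        ),
        DimSpec(
            "salt_level",
            (
                DimValueSpec("unsalted", "unsalted", {"sodium": ("set", 15.0)}),
                DimValueSpec("salted", "salted", {"sodium": ("set", 600.0)}),
            ),
        ),
    ),
    latent=LatentSpec(
        dimension="milk_solids",
        high_value="with yogurt",
        high_token="yogurt",
        high_patterns=(r"\byogurt\b",),
        low_value="classic recipe",
        low_token="",
        low_patterns=(r"\bcream\b", r"\bvegetable oils\b"),
        target="carbohydrate",
        vocab_order=("with yogurt", "classic recipe"),
    ),
)

ALL_TEMPLATES: tuple[CategoryTemplate, ...] = (
    MILK_TEMPLATE,
    GRAIN_TEMPLATE,
    VEG_TEMPLATE,
    FAT_TEMPLATE,
)

MULTIPACK_PATTERNS = (r"\bcombo\b", r"\bmultipack\b", r"&")
_MULTIPACK_PATH = (_MISC, "Combos", "Mixed packs", "Combo pack")
_MULTIPACK_NAMES = (
    "Ham and cheese combo",
    "Crackers and jam combo",
    "Cheese and breadsticks combo",
    "Yogurt and cereal combo",
)
_MULTIPACK_MEANS = {"protein": 12.0, "total_fat": 15.0, "carbohydrate": 20.0, "fiber": 1.0, "sodium": 800.0}


def default_vocabulary(
    templates: Sequence[CategoryTemplate] = ALL_TEMPLATES,
) -> DescriptorVocabulary:
    """The descriptor vocabulary matching the generator's category templates.

    Primary dimensions match the name tokens the generator plants; each
    category's latent descriptor becomes a secondary dimension.
    """
    categories: dict[str, tuple[Dimension, ...]] = {}
    for template in templates:
        dims: list[Dimension] = []
        for dim in template.dims:
            values = tuple(
                DescriptorValue(
                    value=v.value,
                    patterns=(r"\b" + re.escape(v.token) + r"\b",),
                )
                for v in dim.values
            )
            dims.append(Dimension(name=dim.name, tier=PRIMARY, values=values))
        latent = template.latent
        if latent is not None:
            patterns_by_value = {
                latent.high_value: latent.high_patterns,
                latent.low_value: latent.low_patterns,
            }
            values = tuple(
                DescriptorValue(value=v, patterns=patterns_by_value[v])
                for v in latent.vocab_order
            )
            dims.append(Dimension(name=latent.dimension, tier=SECONDARY, values=values))
        categories[template.name] = tuple(dims)
    categories[_MISC] = ()
    return DescriptorVocabulary(
        categories=categories, multipack_patterns=MULTIPACK_PATTERNS
    )


# ---------------------------------------------------------------------------
# Simulation config
# ---------------------------------------------------------------------------

_DEFAULT_SIZES = (1, 2, 3, 4, 5, 6, 8, 10, 12)
_DEFAULT_SIZE_PROBS = (0.28, 0.16, 0.14, 0.12, 0.10, 0.08, 0.06, 0.04, 0.02)

_DEFAULT_VIOLATION_RATES = {
    ENERGY_MISMATCH: 0.05,
    SFA_GT_FAT: 0.01,
    SUGARS_GT_CARB: 0.01,
    IMPROBABLE_VALUE: 0.005,
    MISSING_IMAGE_PROXY: 0.005,
}

_DEFAULT_MISSINGNESS = {
    "energy": 0.01,
    "protein": 0.02,
    "total_fat": 0.01,
    "sfa": 0.03,
    "carbohydrate": 0.01,
    "total_sugars": 0.03,
    "fiber": 0.25,
    "polyols": 0.70,
    "sodium": 0.04,
}

_CORRUPTIBLE = {ENERGY_MISMATCH, SFA_GT_FAT, SUGARS_GT_CARB, IMPROBABLE_VALUE, MISSING_IMAGE_PROXY}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic database."""

    seed: int = 0
    n_groups: int = 60
    categories: tuple[str, ...] = tuple(t.name for t in ALL_TEMPLATES)
    group_sizes: tuple[int, ...] = _DEFAULT_SIZES
    group_size_probs: tuple[float, ...] = _DEFAULT_SIZE_PROBS
    within_cv: float = 0.08
    cv_targets: Mapping[str, float] = field(default_factory=dict)
    latent_split_fraction: float = 0.30
    latent_min_size: int = 4
    latent_shift_sd: float = 12.0
    violation_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_VIOLATION_RATES)
    )
    boundary_rate: float = 0.01
    multipack_rate: float = 0.05
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    claim_rate: float = 0.25

    def __post_init__(self) -> None:
        known = {t.name for t in ALL_TEMPLATES}
        unknown = set(self.categories) - known
        if unknown:
            raise ValueError(f"unknown category template(s) {sorted(unknown)}")
        if not self.categories:
            raise ValueError("at least one category template is required")
        bad = set(self.violation_rates) - _CORRUPTIBLE
        if bad:
            raise ValueError(f"violation rates for unknown reason(s) {sorted(bad)}")
        for label, rates in (
            ("violation_rates", self.violation_rates.values()),
            ("missingness", self.missingness.values()),
            (
                "fractions",
                (self.latent_split_fraction, self.boundary_rate, self.multipack_rate, self.claim_rate),
            ),
        ):
            for r in rates:
                if not 0 <= r <= 1:
                    raise ValueError(f"{label} must lie in [0, 1], got {r}")
        if len(self.group_sizes) != len(self.group_size_probs):
            raise ValueError("group_sizes and group_size_probs must have equal length")
        if abs(sum(self.group_size_probs) - 1.0) > 1e-9:
            raise ValueError("group_size_probs must sum to 1")
        if self.within_cv < 0 or any(v < 0 for v in self.cv_targets.values()):
            raise ValueError("CV targets must be >= 0")
        if self.latent_min_size < 4:
            raise ValueError("latent_min_size must be >= 4 (two members per side)")

    def cv_for(self, nutrient: str) -> float:
        return float(self.cv_targets.get(nutrient, self.within_cv))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw(
    rng: np.random.Generator, mean: float, cv: float, upper: float = np.inf
) -> float:
    """One truncated normal draw with the given mean and CV.

    Truncated at zero (amounts are nonnegative) and, for gram-denominated
    nutrients, at 100 g per 100 g — a label can never declare more.
    """
    if mean <= 0 or cv == 0:
        return round(float(mean), 3)
    sd = cv * mean
    value = stats.truncnorm.rvs(
        (0.0 - mean) / sd, (upper - mean) / sd, loc=mean, scale=sd, random_state=rng
    )
    return round(float(value), 3)


#: per-100g upper bounds used by the generator's draws
_DRAW_UPPER = {"protein": 100.0, "total_fat": 100.0, "carbohydrate": 100.0, "fiber": 100.0}


def _apply_effects(means: dict[str, float], effects: Mapping[str, Effect]) -> None:
    for key, (op, x) in effects.items():
        if op == "set":
            means[key] = x
        elif op == "mul":
            means[key] = means[key] * x
        elif op == "add":
            means[key] = means[key] + x
        else:  # pragma: no cover - template authoring error
            raise ValueError(f"unknown effect op {op!r}")


_BOUNDARY_ENERGY_MACROS = {
    # exact decimals: computed energy 330.0, declared 412.5, relative
    # difference exactly 82.5/412.5 = 0.20 in binary floating point
    "protein": 10.0,
    "total_fat": 10.0,
    "carbohydrate": 50.0,
    "sfa": 4.0,
    "total_sugars": 20.0,
    "fiber": 0.0,
    "sodium": 500.0,
}


def generate_records(config: SimConfig) -> tuple[list[FoodRecord], pd.DataFrame]:
    """Generate FoodRecords plus the truth table, entirely in memory."""
    rng = np.random.default_rng(config.seed)
    qc_config = QCConfig()
    templates = [t for t in ALL_TEMPLATES if t.name in set(config.categories)]

    records: list[FoodRecord] = []
    truth_rows: list[dict] = []
    used_combos: set[tuple] = set()
    serial = 0

    reason_order = [
        ENERGY_MISMATCH,
        SFA_GT_FAT,
        SUGARS_GT_CARB,
        IMPROBABLE_VALUE,
        MISSING_IMAGE_PROXY,
    ]

    for group_index in range(config.n_groups):
        template = templates[int(rng.integers(len(templates)))]
        subgroup = template.subgroups[int(rng.integers(len(template.subgroups)))]

        # Sample a primary descriptor assignment unused within this subgroup
        # so every planted group is a distinct candidate generic food.
        chosen: Optional[list[DimValueSpec]] = None
        for _ in range(80):
            candidate = [
                dim.values[int(rng.integers(len(dim.values)))] for dim in template.dims
            ]
            key = (subgroup.path, tuple(v.value for v in candidate))
            if key not in used_combos:
                used_combos.add(key)
                chosen = candidate
                break
        if chosen is None:
            continue  # descriptor space of this subgroup exhausted

        size = int(rng.choice(config.group_sizes, p=config.group_size_probs))
        group_id = f"G{group_index + 1:04d}"

        means = dict(subgroup.means)
        for value_spec in chosen:
            _apply_effects(means, value_spec.effects)
        name_tokens = " ".join(v.token for v in chosen)

        latent = template.latent
        has_latent = (
            latent is not None
            and size >= config.latent_min_size
            and rng.random() < config.latent_split_fraction
        )
        high_side: set[int] = set()
        delta = 0.0
        if has_latent:
            # both sides keep >= 2 members and a 25-75% balance, so the
            # planted shift always drives the group CV over the 20% trigger
            lo = max(2, -(-size // 4))
            hi = min(size - 2, (3 * size) // 4)
            n_high = int(rng.integers(lo, hi + 1))
            high_side = set(rng.choice(size, n_high, replace=False).tolist())
            delta = config.latent_shift_sd * config.cv_for(latent.target) * means[latent.target]

        for position in range(size):
            serial += 1
            pid = f"P{serial:05d}"
            member_means = dict(means)
            latent_value = ""
            ingredients = subgroup.ingredients
            claims: list[str] = []
            if has_latent:
                if position in high_side:
                    member_means[latent.target] += delta
                    latent_value = latent.high_value
                    token = latent.high_token
                else:
                    latent_value = latent.low_value
                    token = latent.low_token
                if token:
                    ingredients = f"{ingredients}, {token}"
                if token and rng.random() < config.claim_rate:
                    claims.append(token)

            values: dict[str, Optional[float]] = {
                n: _draw(rng, member_means[n], config.cv_for(n), _DRAW_UPPER.get(n, np.inf))
                for n in ("protein", "total_fat", "carbohydrate", "fiber", "sodium")
            }
            values["sfa"] = round(subgroup.sfa_ratio * values["total_fat"], 3)
            values["total_sugars"] = round(subgroup.sugars_ratio * values["carbohydrate"], 3)
            values["polyols"] = 0.0

            # decide the record's fate: planted violation, boundary, or clean
            u = rng.random()
            reason = ""
            boundary = False
            cursor = 0.0
            for candidate_reason in reason_order:
                cursor += config.violation_rates.get(candidate_reason, 0.0)
                if u < cursor:
                    reason = candidate_reason
                    break
            else:
                if u < cursor + config.boundary_rate:
                    boundary = True

            image_complete = True
            if reason == SFA_GT_FAT:
                values["sfa"] = round(values["total_fat"] * rng.uniform(1.05, 1.4), 3)
            elif reason == SUGARS_GT_CARB:
                values["total_sugars"] = round(
                    min(values["carbohydrate"] * rng.uniform(1.05, 1.3), 99.0), 3
                )
            elif reason == IMPROBABLE_VALUE:
                values["protein"] = round(rng.uniform(120.0, 200.0), 3)
            elif reason == MISSING_IMAGE_PROXY:
                image_complete = False
            elif boundary:
                if rng.random() < 0.5:
                    values.update(_BOUNDARY_ENERGY_MACROS)
                    values["polyols"] = 0.0
                    boundary_kind = "energy"
                else:
                    values["sfa"] = values["total_fat"]  # ratio exactly 1.0
                    values["total_sugars"] = values["carbohydrate"]
                    boundary_kind = "ratio"

            # Missingness is decided first so the declared energy can be made
            # consistent with the nutrients the label actually declares (the
            # screen audits only the declared composition).
            missing: set[str] = set()
            if reason == "" and not boundary:
                for nutrient, rate in config.missingness.items():
                    if rate > 0 and rng.random() < rate:
                        missing.add(nutrient)
            declared_values = {
                k: (None if k in missing else v) for k, v in values.items()
            }
            calc = compute_energy(NutrientProfile(**declared_values), qc_config)
            if calc is None:
                # a macronutrient is undeclared: the energy check will be
                # skipped, so anchor the label on the full composition
                calc = compute_energy(NutrientProfile(**values), qc_config)
            assert calc is not None
            if boundary and boundary_kind == "energy":
                declared = 412.5  # exact 20% relative difference to 330 kcal
            elif reason == ENERGY_MISMATCH:
                r = rng.uniform(0.25, 0.50)
                declared = calc / (1.0 - r) if rng.random() < 0.5 else calc / (1.0 + r)
                declared = round(declared, 3)
            else:
                r = rng.uniform(0.0, 0.12)
                declared = calc / (1.0 - r) if rng.random() < 0.5 else calc / (1.0 + r)
                declared = round(declared, 3)
            values = declared_values
            values["energy"] = None if "energy" in missing else declared

            long_name = f"{subgroup.path[3]} {name_tokens} brand {serial}"
            records.append(
                FoodRecord(
                    product_id=pid,
                    long_name=long_name,
                    category_path=subgroup.path,
                    nutrients=NutrientProfile(basis=subgroup.basis, **values),
                    ingredients_text=ingredients,
                    claims=tuple(claims),
                    image_complete=image_complete,
                )
            )
            truth_rows.append(
                {
                    "product_id": pid,
                    "category": subgroup.path[0],
                    "subcategory": subgroup.path[1],
                    "group": subgroup.path[2],
                    "subgroup": subgroup.path[3],
                    "true_group_id": group_id,
                    "latent_value": latent_value,
                    "qc_reason": reason,
                    "multipack": False,
                    "boundary": boundary,
                }
            )

    # standalone multipack products, excluded from aggregation by name
    n_multipack = int(round(config.multipack_rate * len(records)))
    for i in range(n_multipack):
        serial += 1
        pid = f"P{serial:05d}"
        values = {
            n: _draw(rng, _MULTIPACK_MEANS[n], config.cv_for(n), _DRAW_UPPER.get(n, np.inf))
            for n in ("protein", "total_fat", "carbohydrate", "fiber", "sodium")
        }
        values["sfa"] = round(0.4 * values["total_fat"], 3)
        values["total_sugars"] = round(0.15 * values["carbohydrate"], 3)
        values["polyols"] = 0.0
        calc = compute_energy(NutrientProfile(**values), qc_config)
        values["energy"] = round(calc, 3)
        records.append(
            FoodRecord(
                product_id=pid,
                long_name=f"{_MULTIPACK_NAMES[i % len(_MULTIPACK_NAMES)]} brand {serial}",
                category_path=_MULTIPACK_PATH,
                nutrients=NutrientProfile(basis=PER_100G, **values),
                ingredients_text="assorted components",
            )
        )
        truth_rows.append(
            {
                "product_id": pid,
                "category": _MULTIPACK_PATH[0],
                "subcategory": _MULTIPACK_PATH[1],
                "group": _MULTIPACK_PATH[2],
                "subgroup": _MULTIPACK_PATH[3],
                "true_group_id": "",
                "latent_value": "",
                "qc_reason": "",
                "multipack": True,
                "boundary": False,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "product_id",
            "category",
            "subcategory",
            "group",
            "subgroup",
            "true_group_id",
            "latent_value",
            "qc_reason",
            "multipack",
            "boundary",
        ],
    )
    return records, truth


def records_to_tables(records: Sequence[FoodRecord]) -> dict[str, pd.DataFrame]:
    """Lay FoodRecords out as the four BFCD tables."""
    description = pd.DataFrame(
        {
            "product_id": [r.product_id for r in records],
            "long_name": [r.long_name for r in records],
            "category": [r.category_path[0] for r in records],
            "subcategory": [r.category_path[1] for r in records],
            "group": [r.category_path[2] for r in records],
            "subgroup": [r.category_path[3] for r in records],
            "basis": [r.nutrients.basis for r in records],
            "image_complete": [r.image_complete for r in records],
        }
    )
    nutrients = pd.DataFrame(
        [
            {
                "product_id": r.product_id,
                **{
                    n: ("" if r.nutrients.get(n) is None else str(r.nutrients.get(n)))
                    for n in NUTRIENTS
                },
            }
            for r in records
        ]
    )
    claims = pd.DataFrame(
        [
            {"product_id": r.product_id, "claim_text": claim}
            for r in records
            for claim in r.claims
        ],
        columns=["product_id", "claim_text"],
    )
    ingredients = pd.DataFrame(
        [
            {"product_id": r.product_id, "ingredients_text": r.ingredients_text}
            for r in records
            if r.ingredients_text
        ],
        columns=["product_id", "ingredients_text"],
    )
    return {
        "description": description,
        "nutrients": nutrients,
        "claims": claims,
        "ingredients": ingredients,
    }


def generate_db(
    config: SimConfig, out_dir: str | Path
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write a synthetic BFCD (plus truth.csv) under ``out_dir``.

    The four data files are readable by :func:`foodagg.io.read_bfcd`; the
    same seed always produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_records(config)
    tables = records_to_tables(records)
    paths: dict[str, Path] = {}
    for name, frame in tables.items():
        paths[name] = out_dir / f"{name}.csv"
        frame.to_csv(paths[name], index=False)
    paths["truth"] = out_dir / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    return paths, truth


# ---------------------------------------------------------------------------
# Worked fixture
# ---------------------------------------------------------------------------

# Hand-written product rows: (id, subgroup_key, name tokens, ingredients,
# protein, total_fat, sfa, carbohydrate, total_sugars, fiber, sodium).
# Declared energy is always exactly the macronutrient computation, so the
# fixture passes QC with zero exclusions.
_FIXTURE_SUBGROUPS = {
    "yogurt": ((_MILK, "Dairy", "Fermented milks", "Yogurt"), PER_100G),
    "milk": ((_MILK, "Dairy", "Liquid milks", "Milk"), PER_100ML),
    "bread": ((_GRAIN, "Cereal products", "Breads", "Bread"), PER_100G),
    "biscuits": ((_GRAIN, "Cereal products", "Sweet bakery", "Biscuits"), PER_100G),
    "asparagus": ((_VEG, "Vegetables", "Canned vegetables", "Asparagus"), PER_100G),
    "spinach": ((_VEG, "Vegetables", "Frozen vegetables", "Spinach"), PER_100G),
    "mushrooms": ((_VEG, "Vegetables", "Canned vegetables", "Mushrooms"), PER_100G),
    "butter": ((_FAT, "Fats", "Animal fats", "Butter"), PER_100G),
    "margarine": ((_FAT, "Fats", "Plant fats", "Margarine"), PER_100G),
    "combo": (_MULTIPACK_PATH, PER_100G),
}

_YOG = "pasteurized milk, yogurt cultures"
_FIXTURE_ROWS = (
    # strained 0% plain yogurts — homogeneous, n=4
    ("M01", "yogurt", "cow strained 0% fat plain", _YOG, 9.0, 0.2, 0.1, 4.0, 3.6, 0.0, 55.0),
    ("M02", "yogurt", "cow strained 0% fat plain", _YOG, 10.0, 0.2, 0.1, 4.4, 4.0, 0.0, 60.0),
    ("M03", "yogurt", "cow strained 0% fat plain", _YOG, 10.0, 0.2, 0.1, 4.0, 3.6, 0.0, 60.0),
    ("M04", "yogurt", "cow strained 0% fat plain", _YOG, 11.0, 0.2, 0.1, 3.6, 3.2, 0.0, 65.0),
    # strawberry yogurts with a hidden sweetener split — heterogeneous, n=4
    ("M05", "yogurt", "cow classic full fat strawberry", _YOG + ", sugar, strawberries", 3.2, 3.0, 2.0, 16.0, 14.0, 0.0, 50.0),
    ("M06", "yogurt", "cow classic full fat strawberry", _YOG + ", sugar, strawberries", 3.4, 3.0, 2.0, 17.0, 15.0, 0.0, 50.0),
    ("M07", "yogurt", "cow classic full fat strawberry", _YOG + ", sweeteners (stevia), strawberries", 3.3, 3.0, 2.0, 5.0, 4.0, 0.0, 50.0),
    ("M08", "yogurt", "cow classic full fat strawberry", _YOG + ", sweeteners (stevia), strawberries", 3.1, 3.0, 2.0, 5.5, 4.4, 0.0, 50.0),
    # semi-skimmed plain milk — homogeneous, n=3
    ("M09", "milk", "cow pasteurized 2% fat plain", "pasteurized cow milk", 3.3, 2.0, 1.3, 4.8, 4.8, 0.0, 44.0),
    ("M10", "milk", "cow pasteurized 2% fat plain", "pasteurized cow milk", 3.4, 2.0, 1.3, 5.0, 5.0, 0.0, 45.0),
    ("M11", "milk", "cow pasteurized 2% fat plain", "pasteurized cow milk", 3.2, 2.0, 1.3, 4.6, 4.6, 0.0, 46.0),
    # full-fat chocolate milk — homogeneous, n=3
    ("M12", "milk", "cow pasteurized full fat chocolate", "pasteurized cow milk, cocoa", 3.3, 3.5, 2.3, 10.0, 9.5, 0.5, 60.0),
    ("M13", "milk", "cow pasteurized full fat chocolate", "pasteurized cow milk, cocoa", 3.2, 3.5, 2.3, 10.5, 10.0, 0.5, 62.0),
    ("M14", "milk", "cow pasteurized full fat chocolate", "pasteurized cow milk, cocoa", 3.4, 3.5, 2.3, 9.5, 9.0, 0.5, 58.0),
    # multigrain wholegrain bread — homogeneous, n=5
    ("B01", "bread", "multigrain wholegrain sliced", "wheat flour, rye flour, oat flakes, water, yeast", 9.0, 1.4, 0.3, 45.0, 3.0, 6.0, 450.0),
    ("B02", "bread", "multigrain wholegrain sliced", "wheat flour, rye flour, oat flakes, water, yeast", 9.5, 1.5, 0.3, 47.0, 3.2, 7.0, 470.0),
    ("B03", "bread", "multigrain wholegrain sliced", "wheat flour, rye flour, oat flakes, water, yeast", 10.0, 1.6, 0.3, 46.0, 3.1, 6.5, 460.0),
    ("B04", "bread", "multigrain wholegrain sliced", "wheat flour, rye flour, oat flakes, water, yeast", 10.5, 1.5, 0.3, 44.0, 2.9, 6.0, 440.0),
    ("B05", "bread", "multigrain wholegrain sliced", "wheat flour, rye flour, oat flakes, water, yeast", 9.0, 1.5, 0.3, 48.0, 3.3, 7.0, 480.0),
    # white wheat bread — homogeneous, n=3
    ("B06", "bread", "wheat white sliced", "wheat flour, water, yeast, salt", 8.5, 1.2, 0.25, 50.0, 2.5, 2.8, 480.0),
    ("B07", "bread", "wheat white sliced", "wheat flour, water, yeast, salt", 8.8, 1.3, 0.25, 52.0, 2.6, 3.0, 500.0),
    ("B08", "bread", "wheat white sliced", "wheat flour, water, yeast, salt", 8.2, 1.1, 0.25, 48.0, 2.4, 2.6, 460.0),
    # chocolate-coated biscuits — homogeneous, n=3
    ("B09", "biscuits", "wheat chocolate coating", "wheat flour, vegetable oils, cocoa", 6.5, 22.0, 11.0, 62.0, 28.0, 3.0, 300.0),
    ("B10", "biscuits", "wheat chocolate coating", "wheat flour, vegetable oils, cocoa", 7.0, 23.0, 11.5, 64.0, 30.0, 3.0, 320.0),
    ("B11", "biscuits", "wheat chocolate coating", "wheat flour, vegetable oils, cocoa", 6.8, 21.0, 10.5, 60.0, 26.0, 3.0, 280.0),
    # plain biscuits — singleton
    ("B12", "biscuits", "wheat plain", "wheat flour, vegetable oils", 7.5, 14.0, 6.0, 68.0, 20.0, 3.5, 350.0),
    # asparagus in brine — homogeneous, n=3
    ("V01", "asparagus", "white in brine", "asparagus, water, salt", 1.8, 0.3, 0.1, 3.0, 1.5, 1.5, 280.0),
    ("V02", "asparagus", "white in brine", "asparagus, water, salt", 1.9, 0.3, 0.1, 3.2, 1.6, 1.6, 300.0),
    ("V03", "asparagus", "white in brine", "asparagus, water, salt", 1.7, 0.3, 0.1, 2.8, 1.4, 1.4, 260.0),
    # frozen spinach — n=2 (counted, but no aggregated values)
    ("V04", "spinach", "leaves frozen", "spinach", 2.8, 0.4, 0.1, 2.0, 0.8, 2.2, 70.0),
    ("V05", "spinach", "leaves frozen", "spinach", 3.0, 0.4, 0.1, 2.2, 0.9, 2.4, 74.0),
    # dried mushrooms — singleton
    ("V06", "mushrooms", "shitake dried with spices", "mushrooms, spices", 9.6, 1.0, 0.2, 14.0, 2.0, 7.0, 640.0),
    # unsalted spreadable butter — homogeneous, n=3
    ("F01", "butter", "cow spreadable unsalted", "cream", 0.7, 81.0, 52.0, 0.7, 0.6, 0.0, 15.0),
    ("F02", "butter", "cow spreadable unsalted", "cream", 0.7, 82.0, 53.0, 0.7, 0.6, 0.0, 15.0),
    ("F03", "butter", "cow spreadable unsalted", "cream", 0.7, 83.0, 54.0, 0.7, 0.6, 0.0, 15.0),
    # margarine — singleton
    ("F04", "margarine", "sunflower spreadable", "vegetable oils, water, emulsifier", 0.2, 60.0, 21.0, 0.5, 0.3, 0.0, 150.0),
    # multipacks of different foods — excluded from aggregation by name
    ("X01", "combo", "", "ham, cheese, crackers", 12.0, 15.0, 6.0, 20.0, 3.0, 1.0, 800.0),
    ("X02", "combo", "", "crackers, jam", 8.0, 10.0, 4.0, 40.0, 12.0, 2.0, 600.0),
)
_FIXTURE_COMBO_NAMES = {"X01": "Ham and cheese combo", "X02": "Crackers and jam combo"}


def generate_worked_fixture() -> list[FoodRecord]:
    """A 38-product database spanning four categories, built by hand.

    Clean by construction (declared energy equals the macronutrient
    computation exactly), with one heterogeneous group — strawberry yogurts —
    whose heterogeneity resolves on the sweetener descriptor hidden in the
    ingredient lists, two multipack products and several size-1/size-2
    groups. Parses fully under :func:`default_vocabulary`.
    """
    qc_config = QCConfig()
    records = []
    for (pid, key, tokens, ingredients, protein, fat, sfa, carb, sugars, fiber, sodium) in _FIXTURE_ROWS:
        path, basis = _FIXTURE_SUBGROUPS[key]
        values = {
            "protein": protein,
            "total_fat": fat,
            "sfa": sfa,
            "carbohydrate": carb,
            "total_sugars": sugars,
            "fiber": fiber,
            "sodium": sodium,
            "polyols": 0.0,
        }
        values["energy"] = compute_energy(NutrientProfile(**values), qc_config)
        if pid in _FIXTURE_COMBO_NAMES:
            long_name = _FIXTURE_COMBO_NAMES[pid]
        else:
            long_name = f"{path[3]} {tokens}".strip()
        records.append(
            FoodRecord(
                product_id=pid,
                long_name=long_name,
                category_path=path,
                nutrients=NutrientProfile(basis=basis, **values),
                ingredients_text=ingredients,
            )
        )
    return records
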