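"""Plausibility screen for label-declared nutrient values.

Branded labels are audited, not corrected: a record is either included or
excluded, with machine-readable reason codes. Three formula checks are
applied — the declared energy is reconciled against an Atwater-type
computation from the declared macronutrients (protein and carbohydrate at
4 kcal/g, fat at 9, fiber at 2, polyols at 2.4), and the SFA:total-fat and
total-sugars:carbohydrate ratios must not exceed 1 — plus configurable
per-nutrient range checks for grossly improbable amounts. A check whose
inputs are missing is skipped, never failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    ENERGY_MISMATCH,
    IMPROBABLE_VALUE,
    MISSING_IMAGE_PROXY,
    SFA_GT_FAT,
    SUGARS_GT_CARB,
    FoodRecord,
    NutrientProfile,
    QCResult,
)

logger = logging.getLogger(__name__)

#: kcal released per gram, by macronutrient.
DEFAULT_KCAL_PER_G = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "fat": 9.0,
    "fiber": 2.0,
    "polyols": 2.4,
}

#: Upper bounds for the improbable-value screen, per 100 g/mL. Gram-denominated
#: nutrients cannot exceed 100 g; sodium is capped at pure-salt territory.
DEFAULT_MAX_VALUES = {
    "protein": 100.0,
    "total_fat": 100.0,
    "sfa": 100.0,
    "carbohydrate": 100.0,
    "total_sugars": 100.0,
    "fiber": 100.0,
    "polyols": 100.0,
    "sodium": 40000.0,
}


@dataclass(frozen=True)
class QCConfig:
    """Tunables of the plausibility screen.

    energy_tolerance is the maximum allowed relative difference between the
    declared and the computed energy (fraction of declared); ratio_limit is
    the ceiling for SFA:TF and TS:CHO. Both are strict: a record exactly at
    the boundary is included. ``polyols_within_carbohydrate`` states whether
    the declared carbohydrate already includes polyols (EU labeling
    convention), in which case polyols are moved from the 4 kcal/g term to
    their own 2.4 kcal/g factor.
    """

    kcal_per_g: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KCAL_PER_G))
    energy_tolerance: float = 0.20
    ratio_limit: float = 1.0
    polyols_within_carbohydrate: bool = True
    max_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAX_VALUES))

    def __post_init__(self) -> None:
        for name, factor in self.kcal_per_g.items():
            if factor <= 0:
                raise ValueError(f"kcal_per_g[{name!r}] must be > 0")
        if not 0 < self.energy_tolerance < 1:
            raise ValueError("energy_tolerance must lie in (0, 1)")
        if self.ratio_limit <= 0:
            raise ValueError("ratio_limit must be > 0")


def compute_energy(profile: NutrientProfile, config: QCConfig | None = None) -> Optional[float]:
    """Energy (kcal per 100 g/mL) computed from the declared macronutrients.

    Returns ``None`` when protein, carbohydrate or total fat is missing (the
    energy check is then skipped). Absent fiber/polyols count as zero. When
    carbohydrate is declared inclusive of polyols, the available-carbohydrate
    term is clamped at zero if polyols exceed carbohydrate.
    """
    if config is None:
        config = QCConfig()
    protein = profile.protein
    carbohydrate = profile.carbohydrate
    fat = profile.total_fat
    if protein is None or carbohydrate is None or fat is None:
        return None
    fiber = profile.fiber or 0.0
    polyols = profile.polyols or 0.0
    f = config.kcal_per_g
    if config.polyols_within_carbohydrate:
        available_carb = carbohydrate - polyols
        if available_carb < 0:
            logger.warning(
                "polyols (%.3g g) exceed carbohydrate (%.3g g); clamping the "
                "available-carbohydrate energy term at 0",
                polyols,
                carbohydrate,
            )
            available_carb = 0.0
    else:
        available_carb = carbohydrate
    return (
        f["protein"] * protein
        + f["carbohydrate"] * available_carb
        + f["fat"] * fat
        + f["fiber"] * fiber
        + f["polyols"] * polyols
    )


def qc_screen(record: FoodRecord, config: QCConfig | None = None) -> QCResult:
    """Screen one record; returns its verdict with reason codes.

    Excluded iff any check fails. Checks with unavailable inputs (missing
    nutrients, zero denominators) are skipped with a debug note.
    """
    if config is None:
        config = QCConfig()
    profile = record.nutrients
    reasons: set[str] = set()

    energy_calculated = compute_energy(profile, config)
    energy_rel_diff: Optional[float] = None
    declared = profile.energy
    if energy_calculated is not None and declared is not None and declared > 0:
        energy_rel_diff = abs(declared - energy_calculated) / declared
        if energy_rel_diff > config.energy_tolerance:
            reasons.add(ENERGY_MISMATCH)
    else:
        logger.debug("record %s: energy check skipped (inputs unavailable)", record.product_id)

    sfa, fat = profile.sfa, profile.total_fat
    if sfa is not None and fat is not None and fat > 0:
        if sfa / fat > config.ratio_limit:
            reasons.add(SFA_GT_FAT)
    sugars, carb = profile.total_sugars, profile.carbohydrate
    if sugars is not None and carb is not None and carb > 0:
        if sugars / carb > config.ratio_limit:
            reasons.add(SUGARS_GT_CARB)

    for nutrient, ceiling in config.max_values.items():
        value = profile.get(nutrient)
        if value is not None and value > ceiling:
            reasons.add(IMPROBABLE_VALUE)

    # Pass-through curation flag: image completeness is recorded upstream in
    # the description file, never computed here.
    if not record.image_complete:
        reasons.add(MISSING_IMAGE_PROXY)

    return QCResult(
        product_id=record.product_id,
        status="excluded" if reasons else "included",
        reasons=frozenset(reasons),
        energy_calculated=energy_calculated,
        energy_rel_diff=energy_rel_diff,
    )


def qc_filter(
    records: Sequence[FoodRecord], config: QCConfig | None = None
) -> tuple[list[FoodRecord], list[QCResult]]:
    """Screen every record; returns (included records in input order, all verdicts)."""
    if config is None:
        config = QCConfig()
    results = [qc_screen(record, config) for record in records]
    included = [r for r, res in zip(records, results) if res.status == "included"]
    return included, results


def reason_counts(results: Sequence[QCResult]) -> dict[str, int]:
    """Exclusion counts by reason code (a record may carry several reasons)."""
    counts: dict[str, int] = {}
    for res in results:
        for reason in res.reasons:
            counts[reason] = counts.get(reason, 0) + 1
    return counts
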