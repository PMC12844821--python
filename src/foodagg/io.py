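"""Readers and writers for the multi-file BFCD layout and the derived FCD.

The branded database arrives as delimited text with a header row: a
description table (identity, long name, 4-level category path, declaration
basis), a nutrients table (one row per product), a claims table (one row per
claim) and an ingredients table (one row per product). An allergens file may
exist alongside; the framework never consults it. The derived generic FCD is
written as one CSV row per generic food and round-trips losslessly through
the companion reader.

Missing nutrient cells stay missing: nothing is imputed at the I/O layer.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    BASES,
    GRADES,
    NUTRIENTS,
    PER_100G,
    STAT_NUTRIENTS,
    AggregateProfile,
    DescriptorValue,
    DescriptorVocabulary,
    Dimension,
    FoodRecord,
    GenericFoodGroup,
    NutrientProfile,
    NutrientStats,
)

logger = logging.getLogger(__name__)

DESCRIPTION_COLUMNS = ("product_id", "long_name", "category", "subcategory", "group", "subgroup")
NUTRIENT_COLUMNS = ("product_id",) + NUTRIENTS

#: Cell rendered for an absent statistic or grade in the generic FCD.
SENTINEL = "NA"

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _read_table(path: str | Path, delimiter: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")
    return frame


def _parse_float(cell: str, path_name: str, row: int, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"{path_name}: non-numeric value {cell!r} in column {column!r}, "
            f"data row {row}"
        ) from None


def read_bfcd(
    description_path: str | Path,
    nutrients_path: str | Path,
    claims_path: str | Path | None = None,
    ingredients_path: str | Path | None = None,
    delimiter: str = ",",
) -> list[FoodRecord]:
    """Read a branded food composition database into FoodRecords.

    One record per description row, in description-file order; nutrient,
    claim and ingredient rows are joined on ``product_id``. Auxiliary rows
    whose id is absent from the description are logged and dropped.
    Duplicate ids, non-numeric nutrient cells and missing mandatory columns
    are hard errors.
    """
    desc = _read_table(description_path, delimiter, DESCRIPTION_COLUMNS)
    dupes = desc["product_id"][desc["product_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(
            f"duplicate product_id in description: {sorted(set(dupes))[:5]}"
        )

    nut = _read_table(nutrients_path, delimiter, NUTRIENT_COLUMNS)
    nut_name = Path(nutrients_path).name
    known = set(desc["product_id"])
    profiles: dict[str, dict[str, Optional[float]]] = {}
    for i, row in enumerate(nut.itertuples(index=False), start=1):
        pid = row.product_id
        if pid not in known:
            logger.warning("%s: dropping orphan nutrients row for id %r", nut_name, pid)
            continue
        profiles[pid] = {
            col: _parse_float(getattr(row, col), nut_name, i, col) for col in NUTRIENTS
        }

    claims: dict[str, list[str]] = {}
    if claims_path is not None and Path(claims_path).exists():
        cl = _read_table(claims_path, delimiter, ("product_id", "claim_text"))
        for row in cl.itertuples(index=False):
            if row.product_id not in known:
                logger.warning("dropping orphan claims row for id %r", row.product_id)
                continue
            if row.claim_text:
                claims.setdefault(row.product_id, []).append(row.claim_text)

    ingredients: dict[str, str] = {}
    if ingredients_path is not None and Path(ingredients_path).exists():
        ing = _read_table(ingredients_path, delimiter, ("product_id", "ingredients_text"))
        for row in ing.itertuples(index=False):
            if row.product_id not in known:
                logger.warning("dropping orphan ingredients row for id %r", row.product_id)
                continue
            if row.ingredients_text:
                ingredients[row.product_id] = row.ingredients_text

    has_basis = "basis" in desc.columns
    if not has_basis:
        logger.warning(
            "description file has no 'basis' column; assuming %s for every record",
            PER_100G,
        )
    has_image = "image_complete" in desc.columns

    records: list[FoodRecord] = []
    for row in desc.itertuples(index=False):
        pid = row.product_id
        basis = getattr(row, "basis", PER_100G) if has_basis else PER_100G
        if basis == "":
            basis = PER_100G
        if basis not in BASES:
            raise ValueError(f"record {pid!r}: unknown basis {basis!r}")
        values = profiles.get(pid, {})
        profile = NutrientProfile(basis=basis, **values)
        image_complete = True
        if has_image:
            raw = str(getattr(row, "image_complete")).strip().lower()
            if raw in _FALSY:
                image_complete = False
            elif raw not in _TRUTHY:
                raise ValueError(f"record {pid!r}: unparseable image_complete {raw!r}")
        records.append(
            FoodRecord(
                product_id=pid,
                long_name=row.long_name,
                category_path=(row.category, row.subcategory, row.group, row.subgroup),
                nutrients=profile,
                ingredients_text=ingredients.get(pid),
                claims=tuple(claims.get(pid, ())),
                image_complete=image_complete,
            )
        )
    return records


def _fmt(value: Optional[float]) -> str:
    # str(float) is the shortest round-trip representation: lossless and
    # deterministic across platforms.
    return SENTINEL if value is None else str(value)


def write_generic_fcd(
    groups: Sequence[GenericFoodGroup],
    profiles: Mapping[str, AggregateProfile],
    path: str | Path,
) -> None:
    """Serialize the derived generic FCD: one row per group.

    ``profiles`` may cover a subset of ``groups`` (groups below the minimum
    size carry no aggregated values); every profiled name must appear among
    the groups, and generic names must be unique keys.
    """
    names = [g.generic_name for g in groups]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"generic_name collision: {dupes[:5]}")
    orphans = set(profiles) - set(names)
    if orphans:
        raise ValueError(f"profiles reference unknown groups: {sorted(orphans)[:5]}")

    rows = []
    for g in groups:
        row: dict[str, object] = {
            "generic_name": g.generic_name,
            "category": g.category_path[0],
            "subcategory": g.category_path[1],
            "group": g.category_path[2],
            "subgroup": g.category_path[3],
            "basis": g.basis,
            "n": g.n,
            "provenance": g.provenance,
            "inherent_heterogeneity": g.inherent_heterogeneity,
            "descriptors": ";".join(f"{k}={v}" for k, v in g.descriptor_assignment.items()),
            "member_ids": ";".join(g.member_ids),
        }
        profile = profiles.get(g.generic_name)
        row["n_complete"] = profile.n_complete if profile is not None else SENTINEL
        for nutrient in STAT_NUTRIENTS:
            st = profile.get(nutrient) if profile is not None else None
            if st is None:
                st = NutrientStats(None, None, None, None, 0)
            row[f"{nutrient}_mean"] = _fmt(st.mean)
            row[f"{nutrient}_sd"] = _fmt(st.sd)
            row[f"{nutrient}_cv"] = _fmt(st.cv)
            row[f"{nutrient}_grade"] = st.grade if st.grade is not None else SENTINEL
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_generic_fcd(
    path: str | Path,
) -> tuple[list[GenericFoodGroup], dict[str, AggregateProfile]]:
    """Read a generic FCD written by :func:`write_generic_fcd`."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    groups: list[GenericFoodGroup] = []
    profiles: dict[str, AggregateProfile] = {}
    for row in frame.itertuples(index=False):
        assignment = {}
        if row.descriptors:
            for item in row.descriptors.split(";"):
                key, _, value = item.partition("=")
                assignment[key] = value
        group = GenericFoodGroup(
            generic_name=row.generic_name,
            category_path=(row.category, row.subcategory, row.group, row.subgroup),
            descriptor_assignment=assignment,
            member_ids=tuple(row.member_ids.split(";")),
            basis=row.basis,
            provenance=row.provenance,
            inherent_heterogeneity=str(row.inherent_heterogeneity).lower() in _TRUTHY,
        )
        groups.append(group)
        if row.n_complete == SENTINEL:
            continue
        stats: dict[str, NutrientStats] = {}
        for nutrient in STAT_NUTRIENTS:
            mean = getattr(row, f"{nutrient}_mean")
            sd = getattr(row, f"{nutrient}_sd")
            cv = getattr(row, f"{nutrient}_cv")
            grade = getattr(row, f"{nutrient}_grade")
            stats[nutrient] = NutrientStats(
                mean=None if mean == SENTINEL else float(mean),
                sd=None if sd == SENTINEL else float(sd),
                cv=None if cv == SENTINEL else float(cv),
                grade=None if grade == SENTINEL else grade,
                n=0,
            )
        profiles[group.generic_name] = AggregateProfile(
            stats=stats, n_complete=int(row.n_complete), n_members=group.n
        )
    return groups, profiles


def load_vocabulary(config_path: str | Path) -> DescriptorVocabulary:
    """Load a descriptor vocabulary from its YAML config.

    Layout::

        multipack_patterns: ["\\\\bcombo\\\\b"]
        categories:
          "Milk, milk product or milk substitute":
            dimensions:
              - name: animal_of_origin
                tier: primary
                default: null
                values:
                  - value: cow
                    patterns: ["\\\\bcow\\\\b"]
    """
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return vocabulary_from_dict(raw)


def vocabulary_from_dict(raw: Mapping) -> DescriptorVocabulary:
    """Build (and validate) a vocabulary from its config mapping."""
    categories: dict[str, tuple[Dimension, ...]] = {}
    for category, spec in (raw.get("categories") or {}).items():
        dims: list[Dimension] = []
        for dim_spec in (spec or {}).get("dimensions") or []:
            values = tuple(
                DescriptorValue(
                    value=v["value"], patterns=tuple(v.get("patterns") or ())
                )
                for v in dim_spec.get("values") or []
            )
            dims.append(
                Dimension(
                    name=dim_spec.get("name", ""),
                    tier=dim_spec.get("tier", ""),
                    values=values,
                    default_value=dim_spec.get("default"),
                )
            )
        categories[category] = tuple(dims)
    return DescriptorVocabulary(
        categories=categories,
        multipack_patterns=tuple(raw.get("multipack_patterns") or ()),
    )


def vocabulary_to_dict(vocabulary: DescriptorVocabulary) -> dict:
    """Inverse of :func:`vocabulary_from_dict` (for writing configs)."""
    return {
        "multipack_patterns": list(vocabulary.multipack_patterns),
        "categories": {
            category: {
                "dimensions": [
                    {
                        "name": d.name,
                        "tier": d.tier,
                        "default": d.default_value,
                        "values": [
                            {"value": v.value, "patterns": list(v.patterns)}
                            for v in d.values
                        ],
                    }
                    for d in dims
                ]
            }
            for category, dims in vocabulary.categories.items()
        },
    }


def save_vocabulary(vocabulary: DescriptorVocabulary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(vocabulary_to_dict(vocabulary), fh, allow_unicode=True, sort_keys=False)
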