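"""Result surfaces of an aggregation run.

Four tables, all pure functions of the final groups and their profiles:
per-category generic-name yield (how many names come from 1, 2 or >= 3
products), aggregation capacity (share of products falling into names with
>= 3 products, and the name-per-product reduction), the CV-grade
distribution per nutrient, and the category distribution of highly
heterogeneous (CV >= 40%) values. Percentages are reported to one decimal
place with the raw counts always alongside.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .model import (
    GRADE_20_40,
    GRADE_GE40,
    GRADE_LT20,
    GRADE_UNDEFINED,
    TRIGGER_NUTRIENTS,
    AggregateProfile,
    GenericFoodGroup,
)

TOTAL_LABEL = "Total"


def _pct(numerator: float, denominator: float) -> float:
    return round(100.0 * numerator / denominator, 1) if denominator else 0.0


def yield_table(groups: Sequence[GenericFoodGroup]) -> pd.DataFrame:
    """Per-category counts of products and generic names by population size.

    Columns: products, generic_names, names_from_1, names_from_2,
    names_from_ge3 (the three size classes always sum to generic_names).
    A Total row closes the table.
    """
    rows: dict[str, dict[str, int]] = {}
    for group in groups:
        row = rows.setdefault(
            group.category,
            {"products": 0, "generic_names": 0, "names_from_1": 0, "names_from_2": 0, "names_from_ge3": 0},
        )
        row["products"] += group.n
        row["generic_names"] += 1
        if group.n == 1:
            row["names_from_1"] += 1
        elif group.n == 2:
            row["names_from_2"] += 1
        else:
            row["names_from_ge3"] += 1

    columns = ["products", "generic_names", "names_from_1", "names_from_2", "names_from_ge3"]
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if frame.empty:
        frame = pd.DataFrame(columns=columns, dtype=int)
    frame = frame.reindex(columns=columns).sort_index()
    frame.index.name = "category"
    frame.loc[TOTAL_LABEL] = frame.sum(axis=0).astype(int)
    return frame.astype(int)


def aggregation_capacity(groups: Sequence[GenericFoodGroup]) -> pd.DataFrame:
    """Per-category aggregation capacity and name reduction.

    ``capacity_pct`` is the percentage of products that fall into generic
    names populated by >= 3 products; ``reduction_pct`` is
    100 * (1 - generic_names / products). An Overall row closes the table.
    """
    rows: dict[str, dict[str, float]] = {}
    for group in groups:
        row = rows.setdefault(group.category, {"products": 0, "generic_names": 0, "products_in_ge3": 0})
        row["products"] += group.n
        row["generic_names"] += 1
        if group.n >= 3:
            row["products_in_ge3"] += group.n

    records = []
    overall = {"products": 0, "generic_names": 0, "products_in_ge3": 0}
    for category in sorted(rows):
        row = rows[category]
        for key in overall:
            overall[key] += row[key]
        records.append(
            {
                "category": category,
                "products": int(row["products"]),
                "generic_names": int(row["generic_names"]),
                "products_in_ge3": int(row["products_in_ge3"]),
                "capacity_pct": _pct(row["products_in_ge3"], row["products"]),
                "reduction_pct": _pct(row["products"] - row["generic_names"], row["products"]),
            }
        )
    records.append(
        {
            "category": TOTAL_LABEL,
            "products": int(overall["products"]),
            "generic_names": int(overall["generic_names"]),
            "products_in_ge3": int(overall["products_in_ge3"]),
            "capacity_pct": _pct(overall["products_in_ge3"], overall["products"]),
            "reduction_pct": _pct(overall["products"] - overall["generic_names"], overall["products"]),
        }
    )
    return pd.DataFrame.from_records(records).set_index("category")


def cv_grade_distribution(
    profiles: Mapping[str, AggregateProfile],
    nutrients: Sequence[str] = TRIGGER_NUTRIENTS,
) -> pd.DataFrame:
    """Counts and percentages of groups per CV grade, per nutrient.

    Percentages are over groups with a defined grade for that nutrient (the
    three bands sum to 100); undefined grades are counted separately.
    """
    records = []
    for nutrient in nutrients:
        counts = {GRADE_LT20: 0, GRADE_20_40: 0, GRADE_GE40: 0, GRADE_UNDEFINED: 0}
        for profile in profiles.values():
            st = profile.get(nutrient)
            if st is None or st.grade is None:
                continue
            counts[st.grade] += 1
        graded = counts[GRADE_LT20] + counts[GRADE_20_40] + counts[GRADE_GE40]
        records.append(
            {
                "nutrient": nutrient,
                "n_graded": graded,
                "n_lt20": counts[GRADE_LT20],
                "n_20_40": counts[GRADE_20_40],
                "n_ge40": counts[GRADE_GE40],
                "n_undefined": counts[GRADE_UNDEFINED],
                "pct_lt20": _pct(counts[GRADE_LT20], graded),
                "pct_20_40": _pct(counts[GRADE_20_40], graded),
                "pct_ge40": _pct(counts[GRADE_GE40], graded),
            }
        )
    frame = pd.DataFrame.from_records(
        records,
        columns=[
            "nutrient",
            "n_graded",
            "n_lt20",
            "n_20_40",
            "n_ge40",
            "n_undefined",
            "pct_lt20",
            "pct_20_40",
            "pct_ge40",
        ],
    )
    return frame.set_index("nutrient")


def heterogeneity_by_category(
    profiles: Mapping[str, AggregateProfile],
    groups: Sequence[GenericFoodGroup],
    nutrients: Sequence[str] = TRIGGER_NUTRIENTS,
) -> pd.DataFrame:
    """Contingency counts of highly heterogeneous (CV >= 40%) values:
    categories as rows, nutrients as columns. Column sums equal the ge40
    counts of :func:`cv_grade_distribution` over the same profiles."""
    by_name = {g.generic_name: g for g in groups}
    categories = sorted({g.category for g in groups})
    frame = pd.DataFrame(0, index=categories, columns=list(nutrients), dtype=int)
    frame.index.name = "category"
    for name, profile in profiles.items():
        group = by_name.get(name)
        if group is None:
            continue
        for nutrient in nutrients:
            st = profile.get(nutrient)
            if st is not None and st.grade == GRADE_GE40:
                frame.loc[group.category, nutrient] += 1
    return frame
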