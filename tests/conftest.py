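"""Shared fixtures: a default vocabulary, the worked fixture, record builders."""

from __future__ import annotations

import pytest

from foodagg import default_vocabulary, generate_worked_fixture
from foodagg.model import FoodRecord, NutrientProfile

MILK_PATH = ("Milk, milk product or milk substitute", "Dairy", "Fermented milks", "Yogurt")


def make_record(
    product_id: str,
    long_name: str = "Yogurt cow classic full fat plain",
    category_path=MILK_PATH,
    ingredients_text=None,
    claims=(),
    basis="per_100g",
    image_complete=True,
    **nutrients,
) -> FoodRecord:
    """Terse builder for hand-rolled test records."""
    return FoodRecord(
        product_id=product_id,
        long_name=long_name,
        category_path=category_path,
        nutrients=NutrientProfile(basis=basis, **nutrients),
        ingredients_text=ingredients_text,
        claims=tuple(claims),
        image_complete=image_complete,
    )


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture(scope="session")
def worked_records():
    return generate_worked_fixture()
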