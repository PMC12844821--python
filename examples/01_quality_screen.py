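"""Quality-screen a few label declarations.

Builds three branded products by hand — one consistent label, one whose
declared energy disagrees with the Atwater-type computation by more than
20%, one declaring more saturated fat than total fat — and prints each
verdict with its reason codes and the reconciled energy.
"""

from foodagg import NutrientProfile, qc_screen
from foodagg.model import FoodRecord

PATH = ("Grain or grain product", "Cereal products", "Breads", "Bread")

products = [
    FoodRecord(
        "clean", "Bread wheat white sliced", PATH,
        NutrientProfile(energy=249.0, protein=8.5, total_fat=1.2, sfa=0.25,
                        carbohydrate=50.0, total_sugars=2.5, fiber=2.8, sodium=480.0),
    ),
    FoodRecord(
        "energy-off", "Bread rye sliced", PATH,
        # computed: 4*9 + 4*45 + 9*1.5 = 229.5 kcal, declared 160 -> 43% off
        NutrientProfile(energy=160.0, protein=9.0, total_fat=1.5, carbohydrate=45.0),
    ),
    FoodRecord(
        "sfa-gt-fat", "Biscuits butter flavor", PATH,
        NutrientProfile(total_fat=4.0, sfa=5.0, carbohydrate=60.0, total_sugars=20.0),
    ),
]

for record in products:
    result = qc_screen(record)
    print(f"{record.product_id:11s} -> {result.status:8s}", sorted(result.reasons) or "")
    if result.energy_rel_diff is not None:
        print(f"{'':14s} declared {record.nutrients.energy:.1f} kcal, "
              f"computed {result.energy_calculated:.1f} kcal, "
              f"relative difference {100 * result.energy_rel_diff:.1f}% (limit 20%)")

# The screen audits labels; it never corrects them. A record is excluded as
# soon as any check fails, and checks with missing inputs are skipped.
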