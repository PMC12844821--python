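# foodagg

Aggregate branded packaged-food composition data into generic food items.

Branded food composition databases (BFCDs) hold label-declared nutrition for
thousands of retail products — far too granular for nutritional
epidemiology or mHealth apps, which need *generic* foods ("yogurt, cow
milk, strained, 0% fat, plain") whose values average the similar branded
products on the market. `foodagg` implements a three-step aggregation
framework:

1. **Quality screen** — audit each label without correcting it: recompute
   energy from the macronutrients with Atwater-type factors (protein and
   carbohydrate 4 kcal/g, fat 9, fiber 2, polyols 2.4) and exclude records
   with |E<sub>declared</sub> − E<sub>computed</sub>| / E<sub>declared</sub> > 20%,
   with SFA:TF or TS:CHO ratios > 1, or with out-of-range values.
2. **Name-based grouping** — partition products by food-ontology position
   (category / subcategory / group / subgroup) plus descriptors parsed
   deterministically from the long name (origin, processing, fat level,
   flavor, …); multipacks of different foods are excluded.
3. **Homogeneity testing and refinement** — per group and nutrient compute
   mean, sample SD and CV = SD/mean; a CV > 20% in any of energy, protein,
   total fat, SFA, carbohydrate, total sugars or sodium marks the group
   heterogeneous, and such groups are split on descriptors mined from
   ingredient lists and claims (sweetener type, fortification, …) until
   homogeneous — or flagged as inherently heterogeneous when no descriptor
   helps. Aggregated values are emitted only for groups of ≥ 3 complete
   products; CVs are graded <20% / 20–40% / ≥40%.

A synthetic-data module generates BFCDs with planted ground truth (groups,
hidden formulation splits, label violations, multipacks), so the whole
pipeline is testable without access to any proprietary database.

## Worked example

The package ships a hand-written 38-product database spanning dairy,
grains, vegetables and fats (see `examples/03_full_pipeline.py`):

```python
from foodagg import aggregate_pipeline, default_vocabulary, generate_worked_fixture

records = generate_worked_fixture()
result = aggregate_pipeline(records, default_vocabulary())
print(result.counts)
for step in result.refinement_log:
    print(step.parent_name, "->", step.dimension)
```

prints

```
record accounting: {'input': 38, 'excluded': 0, 'multipack': 2, 'grouped': 36, 'groups': 14}

refined 'Yogurt, cow, classic, full fat, strawberry'
  on 'sweetener': worst CV 0.64 -> 0.06
  -> 'Yogurt, cow, classic, full fat, strawberry, with sugar' (n=2)
  -> 'Yogurt, cow, classic, full fat, strawberry, with sweeteners' (n=2)
```

All 38 labels pass the quality screen, two combo products are excluded as
multipacks, and the 36 remaining products fall into 14 generic foods. The
strawberry-yogurt group is heterogeneous (carbohydrate CV 58%: sugar-based
and stevia-based recipes mixed) until the sweetener descriptor found in the
ingredient lists splits it into two homogeneous foods. Eight generic foods
reach the ≥ 3-complete-products minimum and receive aggregated values, e.g.

```
n=4  Yogurt, cow, strained, 0% fat, plain: energy 57.8 kcal (CV 4.9%, grade lt20)
n=5  Bread, multigrain, wholegrain, sliced: energy 248.9 kcal (CV 2.6%, grade lt20)
```

and the report tables show 75.0% overall aggregation capacity (share of
products inside generic foods of ≥ 3 products) with a 61.1% reduction from
products to names.

## Command line

```bash
foodagg simulate --seed 42 --out db/            # synthetic BFCD + truth table
foodagg qc        --in db/ --out qc_report.csv  # per-record verdicts
foodagg classify  --in db/ --out classes.csv    # descriptor assignments
foodagg run       --in db/ --out results/       # full pipeline + reports
```

Inputs are plain CSV: `description.csv` (id, long name, 4-level category
path, per-100g/100mL basis), `nutrients.csv`, `claims.csv`,
`ingredients.csv`. The vocabulary is a YAML file mapping categories to
descriptor dimensions with regex patterns (`foodagg.io.load_vocabulary`);
`default_vocabulary()` provides one matching the synthetic templates. Every
exclusion and refinement decision is logged as one JSON object per line.

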