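# Methods

## The problem

Branded food composition databases (BFCDs) record what packaged products
declare on their labels: energy, macronutrients and sodium per 100 g or
100 mL, plus long marketing names, ingredient lists and on-pack claims.
Nutritional epidemiology and mHealth applications instead need *generic*
foods — "yogurt, cow milk, strained, 0% fat, plain" — whose nutrient values
are averages over the similar branded products on the market. `foodagg`
turns the former into the latter with a three-step procedure:

1. **Quality screen.** Label declarations are audited, never corrected.
2. **Name-based grouping.** Products are partitioned by their position in a
   LanguaL-style hierarchy (category → subcategory → group → subgroup) plus
   descriptor values parsed from the long name.
3. **Homogeneity testing and refinement.** Each candidate group's
   compositional spread is measured; heterogeneous groups are split on
   descriptors mined from ingredient lists and claims until they are
   homogeneous or the heterogeneity is declared inherent.

## Quality screen

Three formula checks per record, all strict inequalities:

- **Energy reconciliation.** Energy is recomputed with Atwater-type factors
  — protein and carbohydrate 4 kcal/g, fat 9, fiber 2, polyols 2.4 — and a
  record fails when |E_declared − E_computed| / E_declared > 0.20. The
  declared energy is the denominator: it is the label claim being audited.
  Carbohydrate is taken as inclusive of polyols (EU labeling convention),
  so polyols are subtracted from the 4 kcal/g term and re-added at
  2.4 kcal/g; `QCConfig.polyols_within_carbohydrate=False` switches to the
  additive reading. If polyols exceed carbohydrate the available-carbohydrate
  term clamps at zero with a warning.
- **Ratio checks.** SFA : total fat > 1 or total sugars : carbohydrate > 1
  fails the record (a part cannot exceed its whole).
- **Range checks.** "Improbable values" are operationalized as configurable
  ceilings: every gram-denominated nutrient ≤ 100 g/100 g, sodium
  ≤ 40 000 mg/100 g.

A check whose inputs are missing (undeclared nutrient, zero denominator) is
skipped, never failed — completeness is not plausibility. Records exactly at
a boundary (relative difference 0.20, ratio 1.0) are included. Image
completeness is an upstream curation flag passed through from the
description file, never computed here.

## Descriptor parsing

A vocabulary defines, per category, an ordered list of dimensions (animal
of origin, processing, fat content, flavor, …). *Primary* dimensions match
the long name; *secondary* dimensions match ingredient lists and claims.
Matching is deterministic on normalized text (lowercased, accent-folded,
punctuation collapsed; `%` and `&` preserved): within a dimension the first
matching value in vocabulary order wins, longer patterns are tried first
inside a value, and multi-matches are logged as conflicts — the machine
analogue of a disagreement between human classifiers. Unmatched dimensions
take their configured default or are omitted.

The generic name is canonical: the deepest hierarchy level (base food term)
followed by descriptor values in vocabulary dimension order, comma-joined,
so identical assignments always produce identical names. The step-1 group
key is (category path, declaration basis, primary assignment); including
the per-100 g / per-100 mL basis keeps units coherent within every group.
Multipacks of different foods are detected from the long name with
dedicated patterns and excluded from aggregation entirely.

## Homogeneity and refinement

For each group, every trigger nutrient (energy, protein, total fat, SFA,
carbohydrate, total sugars, sodium) gets mean, sample SD (n − 1 — the
standard inferential estimator for small groups; the population SD is a
one-line config away in spirit but deliberately not offered) and
CV = SD/mean, computed over the members that declare *all* trigger
nutrients (`n_complete`). Fiber is summarized for description but never
graded or triggered on; polyols only feed the energy audit. Sodium is part
of the trigger set by default (it is graded throughout the result surfaces)
and removable via `AggregationConfig.trigger_nutrients`.

CV conventions for degenerate groups:

- mean > 0: CV = SD/mean;
- mean = 0, SD = 0: CV = 0 (all members identically zero — homogeneous);
- mean = 0, SD > 0: CV undefined, graded `undefined`, treated as
  heterogeneous;
- fewer than two complete members: SD and CV undefined, graded `undefined`,
  but *not* treated as heterogeneous — a singleton provides no evidence of
  spread, and flagging every singleton as heterogeneous would be
  meaningless.

A group is heterogeneous when any trigger nutrient's CV strictly exceeds
0.20 (so CV = 20% exactly is homogeneous). Grades use the half-open bands
[0, 0.20), [0.20, 0.40), [0.40, ∞): the complement of the strict >20%
trigger fixes the left boundary, and the same convention is applied at 40%.

Heterogeneous groups are refined recursively. Every unused secondary
dimension is evaluated: members are partitioned by their matched value
(unmatched members take the dimension's default, or the sentinel
`unspecified`, so a child's assignment always strictly extends its
parent's). A candidate split is **accepted** iff

1. every subgroup keeps ≥ 2 members, and
2. the member-weighted mean of the subgroups' worst trigger-nutrient CV is
   strictly below the parent's worst CV.

Among accepted candidates the greatest improvement is applied (vocabulary
order breaks ties), and still-heterogeneous children are refined with the
remaining dimensions. When no candidate is accepted the group is kept intact
and flagged `inherent_heterogeneity` — residual variability that no
available descriptor explains. The acceptance rule is deliberately
conservative: no quantitative rule is standard for "reduced heterogeneity",
so the engine demands a strict improvement of the worst CV while forbidding
splinter groups of one.

Aggregated values are emitted only for groups with `n_complete` ≥ 3
(configurable). Size-1 and size-2 groups are still counted in the yield
surfaces but carry no values: averages of two labels are dominated by
formulation noise.

## Report surfaces

Four tables, all pure functions of the final groups and profiles: the
per-category yield of generic names by population size (1 / 2 / ≥ 3
products), aggregation capacity (share of products inside names with ≥ 3
products, plus the names-per-products reduction), the per-nutrient CV-grade
distribution over groups with emitted values, and the category × nutrient
contingency of highly heterogeneous (CV ≥ 40%) values. Percentages are
printed to one decimal with raw counts alongside; marginals are mutually
consistent by construction. Plotting is left to downstream tools.

## The synthetic-data generator

No public branded database ships with ground truth, so the generator
produces the same four-file layout the reader consumes plus a truth table
(product → planted group, latent descriptor side, violation, multipack,
boundary flag). What it emulates, and the default study conditions:

- **Category templates** for dairy, grains, vegetables and fats mirror
  realistic products: subgroup baseline compositions, primary descriptors
  with compositional effects (e.g. "0% fat" sets fat to 0.2 g, "chocolate"
  adds 8 g carbohydrate), and parseable long names built from the same
  tokens the default vocabulary matches.
- **Group structure.** Planted groups draw distinct descriptor
  combinations; sizes are skewed small (sizes 1–12, 28% singletons),
  matching how branded markets populate generic names.
- **Within-group spread** is truncated normal — at zero, and at
  100 g/100 g for gram-denominated nutrients, since a label cannot declare
  more — with an 8% CV target per nutrient (configurable per nutrient). SFA
  and sugars are drawn as subgroup-specific ratios of fat and carbohydrate,
  which keeps ratio checks clean by construction and ties their CVs to the
  parent nutrient's.
- **Latent splits.** A configurable fraction of groups (30% by default) of
  size ≥ 4 hides a binary secondary descriptor (sugar- vs.
  sweetener-based recipe, protein fortification, drained vs. non-drained,
  salted vs. unsalted) whose token appears only in the ingredient list and
  which shifts one nutrient's mean by `latent_shift_sd` within-group SDs
  (default 12). Sides are planted at 25–75% balance with ≥ 2 members each.
  The shift and balance are chosen together so the planted mixture's CV
  exceeds the 20% trigger for *every* admissible balance (worst case
  ≈ 0.25): a shift that cannot raise the CV above the trigger would plant a
  split that is undetectable in principle, by any method that only sees the
  grouped data.
- **Violations.** Planted per-record with configured rates, each corrupting
  exactly the targeted check: energy offsets of 25–50% relative (clean
  records get ≤ 12%), SFA set above fat, sugars above carbohydrate, a
  120–200 g protein for the range check, a cleared image flag. Declared
  energy is always generated consistent with the *declared* composition —
  missingness is decided first, and the label's energy anchors on what the
  label shows — so planted-clean records never fail the screen by
  construction. Boundary records (relative difference exactly 0.20, ratios
  exactly 1.0) use fixed exact-decimal compositions so the equalities are
  exact in binary floating point.
- **Multipacks and missingness.** Combo products with multipack name tokens
  (5% of records); per-nutrient missing-declaration rates (fiber 25%,
  polyols 70%, macros 1–4%).

What the generator does **not** emulate: real marketing language (names are
token concatenations), category proportions of any real market, lognormal
or multimodal within-group spreads beyond the planted binary splits,
kJ-only or salt-vs-sodium labeling variants, and fortification/micronutrient
declarations. Passing tests therefore demonstrate that the machinery
recovers structure of the planted kinds at the stated effect sizes — not
that any particular real market is this well-behaved.

## Numerical and formatting choices

- Sample statistics via numpy in float64; no tolerance is applied to the
  strict QC and trigger inequalities — boundary behavior is exact.
- CSV cells for absent statistics use the sentinel `NA` (never an empty
  cell); floats are written with Python's shortest round-trip
  representation, so the generic FCD round-trips losslessly and output
  files are byte-stable across runs and platforms.
- The multi-file reader is strict where corruption would silently bias
  results (duplicate ids, non-numeric nutrient cells, missing mandatory
  columns are hard errors) and lenient where data is merely incomplete
  (orphan auxiliary rows are logged and dropped; a missing `basis` column
  defaults to per-100 g with a warning).
- Sodium is standardized in mg per 100 g/mL; salt→sodium conversion is
  upstream curation. kcal is the only energy unit.

## Known limitations

- Descriptor extraction is vocabulary-driven: a descriptor nobody wrote a
  pattern for cannot be discovered, and statistically driven descriptor
  generation (splitting on composition alone, without on-pack evidence) is
  deliberately out of scope.
- The refinement search is greedy over single dimensions at each level; a
  pair of descriptors that only helps jointly would be found one step at a
  time or not at all. On small groups (≤ 6 members, ≤ 2 dimensions) an
  exhaustive-search oracle confirms the greedy verdicts in the test suite.
- The worked fixture and generator cover four categories; vocabularies for
  a real market are a curation effort the package only provides the
  machinery for.
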