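"""Derive candidate generic food names from product long names.

Loads the built-in worked database (38 branded products across four
categories), flags multipacks, and shows how descriptor parsing turns each
long name into a canonical generic name: base food term plus descriptor
values in vocabulary order.
"""

from foodagg import (
    build_generic_name,
    default_vocabulary,
    flag_multipacks,
    generate_worked_fixture,
    group_step1,
    parse_descriptors,
)

records = generate_worked_fixture()
vocabulary = default_vocabulary()

eligible, multipacks = flag_multipacks(records, vocabulary)
print(f"{len(records)} products, {len(multipacks)} multipacks excluded: {multipacks}\n")

for record in eligible[:4]:
    assignment = parse_descriptors(record, vocabulary)
    name = build_generic_name(record.category_path, assignment, vocabulary)
    print(f"  {record.long_name!r}")
    print(f"    -> {assignment}")
    print(f"    -> {name!r}\n")

groups = group_step1(eligible, vocabulary)
print(f"{len(eligible)} eligible products fall into {len(groups)} candidate generic foods:")
for group in groups:
    print(f"  n={group.n}  {group.generic_name}")

# Identical descriptor assignments always produce identical names, so the
# grouping is a deterministic partition of the eligible products.
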