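category,products,generic_names,products_in_ge3,capacity_pct,reduction_pct
Fat or fat product,4,2,3,75.0,50.0
Grain or grain product,12,4,11,91.7,66.7
"Milk, milk product or milk substitute",14,5,10,71.4,64.3
Vegetable or vegetable product,6,3,3,50.0,50.0
Total,36,14,27,75.0,61.1
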