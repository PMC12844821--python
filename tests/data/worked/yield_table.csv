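category,products,generic_names,names_from_1,names_from_2,names_from_ge3
Fat or fat product,4,2,1,0,1
Grain or grain product,12,4,1,0,3
"Milk, milk product or milk substitute",14,5,0,2,3
Vegetable or vegetable product,6,3,1,1,1
Total,36,14,3,3,8
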