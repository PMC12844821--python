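category,energy,protein,total_fat,sfa,carbohydrate,total_sugars,sodium
Fat or fat product,0,0,0,0,0,0,0
Grain or grain product,0,0,0,0,0,0,0
"Milk, milk product or milk substitute",0,0,0,0,0,0,0
Vegetable or vegetable product,0,0,0,0,0,0,0
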