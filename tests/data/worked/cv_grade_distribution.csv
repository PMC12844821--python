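nutrient,n_graded,n_lt20,n_20_40,n_ge40,n_undefined,pct_lt20,pct_20_40,pct_ge40
energy,8,8,0,0,0,100.0,0.0,0.0
protein,8,8,0,0,0,100.0,0.0,0.0
total_fat,8,8,0,0,0,100.0,0.0,0.0
sfa,8,8,0,0,0,100.0,0.0,0.0
carbohydrate,8,8,0,0,0,100.0,0.0,0.0
total_sugars,8,8,0,0,0,100.0,0.0,0.0
sodium,8,8,0,0,0,100.0,0.0,0.0
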