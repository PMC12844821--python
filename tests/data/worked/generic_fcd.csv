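generic_name,category,subcategory,group,subgroup,basis,n,provenance,inherent_heterogeneity,descriptors,member_ids,n_complete,energy_mean,energy_sd,energy_cv,energy_grade,protein_mean,protein_sd,protein_cv,protein_grade,total_fat_mean,total_fat_sd,total_fat_cv,total_fat_grade,sfa_mean,sfa_sd,sfa_cv,sfa_grade,carbohydrate_mean,carbohydrate_sd,carbohydrate_cv,carbohydrate_grade,total_sugars_mean,total_sugars_sd,total_sugars_cv,total_sugars_grade,sodium_mean,sodium_sd,sodium_cv,sodium_grade,fiber_mean,fiber_sd,fiber_cv,fiber_grade
"Butter, cow, spreadable, unsalted",Fat or fat product,Fats,Animal fats,Butter,per_100g,3,step1,False,origin=cow;form=spreadable;salt_level=unsalted,F01;F02;F03,3,743.6,9.0,0.012103281334050564,lt20,0.6999999999999998,1.3597399555105182e-16,1.9424856507293121e-16,lt20,82.0,1.0,0.012195121951219513,lt20,53.0,1.0,0.018867924528301886,lt20,0.6999999999999998,1.3597399555105182e-16,1.9424856507293121e-16,lt20,0.6,0.0,0.0,lt20,15.0,0.0,0.0,lt20,0.0,0.0,0.0,NA
"Margarine, sunflower, spreadable",Fat or fat product,Fats,Plant fats,Margarine,per_100g,1,step1,False,origin=sunflower;form=spreadable,F04,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
"Bread, multigrain, wholegrain, sliced",Grain or grain product,Cereal products,Breads,Bread,per_100g,5,step1,False,main_grain=multigrain;processing=wholegrain;format=sliced,B01;B02;B03;B04;B05,5,248.9,6.500384604006137,0.026116450799542536,lt20,9.6,0.6519202405202649,0.0679083583875276,lt20,1.5,0.07071067811865482,0.047140452079103216,lt20,0.3,0.0,0.0,lt20,46.0,1.5811388300841898,0.03437258326269978,lt20,3.1,0.15811388300841897,0.05100447838981257,lt20,460.0,15.811388300841896,0.03437258326269978,lt20,6.5,0.5,0.07692307692307693,NA
"Bread, wheat, white, sliced",Grain or grain product,Cereal products,Breads,Bread,per_100g,3,step1,False,main_grain=wheat;processing=white;format=sliced,B06;B07;B08,3,250.39999999999998,10.499999999999986,0.04193290734824276,lt20,8.5,0.3000000000000007,0.035294117647058906,lt20,1.2,0.09999999999999998,0.08333333333333331,lt20,0.25,0.0,0.0,lt20,50.0,2.0,0.04,lt20,2.5,0.10000000000000009,0.040000000000000036,lt20,480.0,20.0,0.041666666666666664,lt20,2.8000000000000003,0.19999999999999996,0.07142857142857141,NA
"Biscuits, wheat, chocolate coating",Grain or grain product,Cereal products,Sweet bakery,Biscuits,per_100g,3,step1,False,main_grain=wheat;coating=chocolate coating,B09;B10;B11,3,479.06666666666666,17.42450381885618,0.036371772513615744,lt20,6.766666666666667,0.2516611478423583,0.037191302636801725,lt20,22.0,1.0,0.045454545454545456,lt20,11.0,0.5,0.045454545454545456,lt20,62.0,2.0,0.03225806451612903,lt20,28.0,2.0,0.07142857142857142,lt20,300.0,20.0,0.06666666666666667,lt20,3.0,0.0,0.0,NA
"Biscuits, wheat, plain",Grain or grain product,Cereal products,Sweet bakery,Biscuits,per_100g,1,step1,False,main_grain=wheat;coating=plain,B12,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
"Yogurt, cow, classic, full fat, strawberry, with sugar","Milk, milk product or milk substitute",Dairy,Fermented milks,Yogurt,per_100g,2,step3_refined,False,animal_of_origin=cow;processing=classic;fat_content=full fat;flavor=strawberry;sweetener=with sugar,M05;M06,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
"Yogurt, cow, classic, full fat, strawberry, with sweeteners","Milk, milk product or milk substitute",Dairy,Fermented milks,Yogurt,per_100g,2,step3_refined,False,animal_of_origin=cow;processing=classic;fat_content=full fat;flavor=strawberry;sweetener=with sweeteners,M07;M08,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
"Yogurt, cow, strained, 0% fat, plain","Milk, milk product or milk substitute",Dairy,Fermented milks,Yogurt,per_100g,4,step1,False,animal_of_origin=cow;processing=strained;fat_content=0% fat;flavor=plain,M01;M02;M03;M04,4,57.8,2.8472208672083497,0.04925987659530017,lt20,10.0,0.816496580927726,0.08164965809277261,lt20,0.2,0.0,0.0,lt20,0.1,0.0,0.0,lt20,4.0,0.3265986323710905,0.08164965809277262,lt20,3.5999999999999996,0.3265986323710903,0.09072184232530288,lt20,60.0,4.08248290463863,0.06804138174397717,lt20,0.0,0.0,0.0,NA
"Milk, cow, pasteurized, 2% fat, plain","Milk, milk product or milk substitute",Dairy,Liquid milks,Milk,per_100mL,3,step1,False,animal_of_origin=cow;processing=pasteurized;fat_content=2% fat;flavor=plain,M09;M10;M11,3,50.4,1.1999999999999993,0.023809523809523798,lt20,3.2999999999999994,0.09999999999999987,0.03030303030303027,lt20,2.0,0.0,0.0,lt20,1.3,0.0,0.0,lt20,4.8,0.20000000000000018,0.041666666666666706,lt20,4.8,0.20000000000000018,0.041666666666666706,lt20,45.0,1.0,0.022222222222222223,lt20,0.0,0.0,0.0,NA
"Milk, cow, pasteurized, full fat, chocolate","Milk, milk product or milk substitute",Dairy,Liquid milks,Milk,per_100mL,3,step1,False,animal_of_origin=cow;processing=pasteurized;fat_content=full fat;flavor=chocolate,M12;M13;M14,3,85.7,1.6000000000000014,0.018669778296382746,lt20,3.3000000000000003,0.09999999999999987,0.03030303030303026,lt20,3.5,0.0,0.0,lt20,2.3,0.0,0.0,lt20,10.0,0.5,0.05,lt20,9.5,0.5,0.05263157894736842,lt20,60.0,2.0,0.03333333333333333,lt20,0.5,0.0,0.0,NA
"Asparagus, in brine",Vegetable or vegetable product,Vegetables,Canned vegetables,Asparagus,per_100g,3,step1,False,liquid_matrix=in brine,V01;V02;V03,3,24.899999999999995,1.3999999999999986,0.05622489959839353,lt20,1.8,0.09999999999999998,0.05555555555555554,lt20,0.3,0.0,0.0,lt20,0.10000000000000002,1.6996749443881478e-17,1.6996749443881474e-16,lt20,3.0,0.20000000000000018,0.06666666666666672,lt20,1.5,0.10000000000000009,0.06666666666666672,lt20,280.0,20.0,0.07142857142857142,lt20,1.5,0.10000000000000009,0.06666666666666672,NA
"Mushrooms, dried, with spices",Vegetable or vegetable product,Vegetables,Canned vegetables,Mushrooms,per_100g,1,step1,False,processing=dried;additions=with spices,V06,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
"Spinach, frozen",Vegetable or vegetable product,Vegetables,Frozen vegetables,Spinach,per_100g,2,step1,False,processing=frozen,V04;V05,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
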