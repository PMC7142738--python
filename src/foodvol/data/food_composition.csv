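food_id,name,density_g_per_ml,cho_g_per_100g,protein_g_per_100g,fat_g_per_100g,kcal_per_100g
rice_cooked,"Rice, white, cooked",0.85,28.0,2.7,0.3,130
mashed_potato,"Potato, mashed, with milk",1.00,15.0,2.0,3.2,100
pasta_cooked,"Pasta, cooked",0.70,25.0,5.0,1.1,131
bread_white,"Bread, white, sliced",0.28,49.0,8.5,3.0,265
bread_whole,"Bread, wholegrain",0.35,41.0,9.0,3.5,230
cheese_hard,"Cheese, hard (Gruyere-type)",1.10,0.4,27.0,32.0,400
cake_sponge,"Cake, sponge",0.30,53.0,6.0,15.0,370
beef_patty,"Beef patty, grilled",0.95,0.0,26.0,15.0,240
pancake,"Pancake, plain",0.55,28.0,6.0,10.0,230
chicken_breast,"Chicken breast, roasted",1.05,0.0,31.0,3.6,165
potato_boiled,"Potato, boiled",1.05,17.0,1.9,0.1,78
apple_half,"Apple, raw",0.80,14.0,0.3,0.2,55
banana,"Banana, raw",0.95,23.0,1.1,0.3,95
yogurt_plain,"Yogurt, plain, whole milk",1.03,4.7,3.5,3.3,62
muesli,"Muesli with fruit",0.45,66.0,9.0,6.0,360
butter,"Butter",0.91,0.6,0.7,81.0,735
jam_strawberry,"Jam, strawberry",1.30,60.0,0.4,0.1,240
salmon_fillet,"Salmon fillet, baked",1.00,0.0,22.0,12.0,200
peas_cooked,"Peas, green, cooked",0.90,9.0,5.4,0.4,62
carrots_cooked,"Carrots, cooked",0.95,5.0,0.8,0.2,27
broccoli_cooked,"Broccoli, cooked",0.60,4.0,2.8,0.4,30
omelette,"Omelette, plain",0.95,1.0,11.0,12.0,155
oatmeal,"Oatmeal porridge",1.00,12.0,2.5,2.1,75
tofu_firm,"Tofu, firm",1.05,2.0,8.0,4.8,76
lentils_cooked,"Lentils, cooked",0.85,20.0,9.0,0.4,116
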