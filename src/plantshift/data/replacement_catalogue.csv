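# Replacement catalogue: alternatives offered per food group for the
# vegetarian-family scenarios (used by flexitarian, pescetarian, vegetarian)
# and for the vegan scenario. Protein and kcal per 100 g are the NEVO label
# (nitrogen-based) values; they are metadata only and never enter the
# amino-acid arithmetic. At most 12 alternatives per group.
scenario_family,food_group,name,label_protein_g,kcal
vegetarian,meat_or_fish,Chicken egg,12.3,128
vegetarian,meat_or_fish,Mozzarella cheese,18.7,253
vegetarian,meat_or_fish,Vegetarian hamburger,17.7,192
vegetarian,meat_or_fish,Vegetarian schnitzel,15.2,226
vegetarian,meat_or_fish,Plant based burger beyond meat,15.0,252
vegetarian,meat_or_fish,Vegetarian meatballs,17.1,169
vegetarian,meat_or_fish,Vegetarian burger with cheese,15.9,231
vegetarian,meat_or_fish,Vegetarian meatball,16.9,243
vegetarian,meat_or_fish,Valess schnitzel,12.3,188
vegetarian,meat_or_fish,Gouda cheese 48+,22.9,369
vegetarian,meat_or_fish,Vegetarian sausage,13.3,259
vegetarian,meat_or_fish,Vegetarian burger,11.0,210
vegetarian,sandwich_filling_meat_or_fish,Egg salad,7.3,255
vegetarian,sandwich_filling_meat_or_fish,Gouda cheese 48+,22.9,369
vegetarian,sandwich_filling_meat_or_fish,Peanut butter,20.0,651
vegetarian,sandwich_filling_meat_or_fish,Spread sweet average,2.7,393
vegetarian,sandwich_filling_meat_or_fish,Hummus,7.7,322
vegetarian,sandwich_filling_meat_or_fish,Vegan luncheon,8.2,156
vegetarian,sandwich_filling_meat_or_fish,Cheese salad,9.0,422
vegetarian,sandwich_filling_meat_or_fish,Cream cheese,5.3,291
vegetarian,sandwich_filling_meat_or_fish,Chicken egg,12.3,128
vegetarian,sandwich_filling_meat_or_fish,Cheese 30+,31.9,306
vegetarian,sandwich_filling_meat_or_fish,Cheese spread,14.3,231
vegetarian,sandwich_filling_meat_or_fish,Chocolate sprinkles,5.8,446
vegetarian,bread_with_meat,Cheese pastry,9.2,579
vegetarian,bread_with_meat,Baguette cheese-onion,10.0,242
vegetarian,bread_with_meat,Bread currant,7.8,273
vegetarian,bread_with_meat,Roll white soft,9.7,262
vegetarian,soup,Soup clear w vegetables and noodles,0.7,17
vegetarian,soup,Soup clear vegetables,0.4,10
vegetarian,soup,Soup thickened vegetables,0.7,36
vegetarian,soup,Soup thickened no filling,0.6,40
vegetarian,savoury_snack,Crisp potato,6.3,538
vegetarian,savoury_snack,Cocktail snacks nibb-it,3.3,482
vegetarian,savoury_snack,Cassava crackers,1.4,474
vegetarian,savoury_snack,Falafel unprepared,6.8,208
vegetarian,minced_meat,Lentils green/brown boiled,21.0,306
vegetarian,minced_meat,Quorn minced,13.0,97
vegetarian,minced_meat,Vegetarian minced meat,24.3,124
vegetarian,minced_meat,Quorn pieces,14.0,114
vegetarian,minced_meat,Mincemeat beyond meat,17.0,252
vegetarian,minced_meat,Vegan mincemeat beans,17.0,182
vegan,meat_fish_dinner,Lentils green/brown boiled,21.0,306
vegan,meat_fish_dinner,Plant based burger beyond meat,17.0,252
vegan,meat_fish_dinner,Falafel,6.8,208
vegan,meat_fish_dinner,Vegan bean burger,16.0,191
vegan,meat_fish_dinner,Sausage beyond meat,17.0,233
vegan,meat_fish_dinner,Tahoe soya curd,11.6,113
vegan,meat_fish_dinner,Vegan chicken burger,13.0,220
vegan,meat_fish_dinner,Plant based chicken vivera,15.0,166
vegan,meat_fish_dinner,Vegan chicken,21.0,142
vegan,meat_fish_dinner,Vegan swedish balls,9.6,158
vegan,meat_fish_dinner,Vegan vegetable burger,11.0,116
vegan,meat_fish_dinner,Plant based chicken tenders,15.0,202
vegan,sandwich_filling_animal,Peanut butter,20.0,651
vegan,sandwich_filling_animal,Luncheon meat quorn,7.1,89
vegan,sandwich_filling_animal,Hummus natural,7.7,322
vegan,sandwich_filling_animal,Vegan bacon,5.5,140
vegan,sandwich_filling_animal,Vegan luncheon meat,8.2,156
vegan,sandwich_filling_animal,Vegan grill sausage,8.3,163
vegan,sandwich_filling_animal,Sesame paste tahin,21.9,602
vegan,sandwich_filling_animal,Melt me smoky cheese,8.3,270
vegan,sandwich_filling_animal,Vegan bacon strips,5.0,170
vegan,sandwich_filling_animal,Vegan chicken filet,8.3,165
vegan,sandwich_filling_animal,Vegan sausage,7.0,244
vegan,sandwich_filling_animal,Spread sweet averaged,2.7,393
vegan,bread_with_dairy_or_meat,Roll white soft,9.7,262
vegan,bread_with_dairy_or_meat,Bread currant,7.8,273
vegan,bread_with_dairy_or_meat,Bread brown/wholemeal,10.5,235
vegan,bread_with_dairy_or_meat,Bread rye dark,5.6,193
vegan,drink_with_dairy,Tea,0.0,0
vegan,drink_with_dairy,Coffee,0.0,0
vegan,drink_with_dairy,Drink soya original alpro,3.0,39
vegan,drink_with_dairy,Water,0.0,0
vegan,dairy_dessert,Plant based alternative quark,2.7,119
vegan,dairy_dessert,Plant based alternative quark soya,5.7,54
vegan,dairy_dessert,Yoghurt soybased fruit,3.7,134
vegan,dairy_dessert,Havergurt greek style,3.3,145
vegan,dairy_dessert,Yoghurt soybased,4.0,47
vegan,dairy_dessert,Havergurt blue berry,1.3,101
vegan,dairy_dessert,Drink soya original alpro,3.0,39
vegan,dairy_dessert,Original plant-based not milk,2.2,34
vegan,dairy_dessert,Yoghurt soybased vanilla,3.7,134
vegan,dairy_dessert,Dessert soya alpro,3.1,85
vegan,dairy_dessert,Vly unsweated,2.5,34
vegan,dairy_dessert,Ice cream coconutmilk,1.2,85
vegan,minced_meat,Lentils green/brown boiled,21.0,306
vegan,minced_meat,Quorn minced,13.0,97
vegan,minced_meat,Vegetarian minced meat,24.3,124
vegan,minced_meat,Quorn pieces,14.0,114
vegan,minced_meat,Mincemeat beyond meat,17.0,252
vegan,minced_meat,Vegan mincemeat beans,17.0,182
vegan,savoury_snack,Crisp potato,6.3,538
vegan,savoury_snack,Cocktail snacks nibb-it,3.3,482
vegan,savoury_snack,Cassava crackers,1.4,474
vegan,savoury_snack,Falafel unprepared,6.8,208
vegan,sweet_snack,Turkish delight,0.0,370
vegan,sweet_snack,"Popcorn sweet, popped wo oil",9.9,389
vegan,sweet_snack,Chocolate dark w hazelnuts,9.0,565
vegan,sweet_snack,Wafer galette,6.9,480
vegan,soup,Soup clear w vegetables and noodles,0.7,17
vegan,soup,Soup clear vegetables,0.4,10
vegan,soup,Soup thickened vegetables,0.7,36
vegan,soup,Soup thickened no filling,0.6,40
vegan,cream,Cream based on veg oil alpro cuisine,2.0,166
vegan,cream,Cream based on veg oil alpro cuisine light,2.0,63
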