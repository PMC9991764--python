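item_id,label,na_mg_per_100g,is_cooked_meal_or_salad,food_group,naffq_addition
bread_white,White bread and rusks,500,0,cereals,0
breakfast_cereal,Breakfast cereals,600,0,cereals,0
pasta,"Pasta, cooked",5,1,cereals,0
rice,"Rice, cooked",5,1,cereals,0
potatoes,"Potatoes, boiled or baked",10,1,starchy,0
milk,Milk,45,0,dairy,0
yogurt,Yogurt,60,0,dairy,0
cheese_feta,Feta and white brined cheeses,1100,0,dairy,0
red_meat,Red meat dishes,70,1,meat,0
poultry,Poultry dishes,80,1,meat,0
fish_fresh,Fresh fish and seafood dishes,90,1,fish,0
legumes,Legume dishes,10,1,legumes,0
vegetables_raw,"Vegetables, raw (salads)",30,1,vegetables,0
vegetables_boiled,"Vegetables, boiled (salads)",25,1,vegetables,0
fruits,Fruits,2,0,fruits,0
olive_oil,Olive oil and added fats,2,0,added_fats,0
sweets,Sweets and desserts,150,0,sweets,0
traditional_pies,Traditional dishes and home-made pies,450,1,composite,0
cured_meat,Cured and processed meat,1000,0,meat,0
olives_pickles,Olives and pickled vegetables,1600,0,vegetables,0
salted_butter,Salted butter and margarine,700,0,added_fats,1
cheese_rich_na,"Na-rich cheeses (roquefort, parmesan, edam, gouda, gruyere)",1400,0,dairy,1
salty_crackers,Salty crackers and biscuits,900,0,cereals,1
canned_fish,Canned fish and seafood,400,0,fish,1
tomato_juice,Refined tomato juice,250,0,beverages,1
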