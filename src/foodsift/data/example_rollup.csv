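subcategory,category
Baby food,Baby food
Dairy,Dairy
Ready meals,Ready meals and soup
Soup,Ready meals and soup
"Sauces, dressings, and condiments","Sauces, dressings, spreads, and dips"
Sweet spreads,"Sauces, dressings, spreads, and dips"
Confectionery,Sweet snacks
Ice cream and frozen desserts,Sweet snacks
"Sweet biscuits, snack bars, and fruit snacks",Sweet snacks
Savory snacks,Savory snacks
Baked goods,Baked goods
Breakfast cereals,Cereal and grain products
"Rice, pasta, and noodles",Cereal and grain products
Processed fruit and vegetables,Processed fruit and vegetables
Processed meat,Processed meat
Meat substitutes,Meat substitutes
Processed seafood,Processed seafood
Carbonates,Soft drinks and juice
Concentrates,Soft drinks and juice
Energy drinks,Soft drinks and juice
Juice,Soft drinks and juice
Sports drinks,Soft drinks and juice
Ready-to-drink coffee,Coffee and tea
Ready-to-drink tea,Coffee and tea
Bottled water,Water and functional beverages
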