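# Product category taxonomy and keyword classification rules.
#
# Food categories follow food groups extended with processed/packaged
# categories (breakfast cereals, packaged snacks, condiments and cooking
# staples), prepared-food categories (mixed dishes, desserts) and a dedicated
# restaurant category. Beverage categories follow the Rudd Center children's
# drinks taxonomy extended with alcoholic beverages and plain water, with
# sweetened and unsweetened coffee and tea combined into one category.
#
# Rules are applied in order; the first rule whose keyword list matches the
# product name (case-insensitive substring) assigns the category. Foods
# flagged as restaurant items always map to the restaurant category before
# any keyword rule runs. Unmatched items fall into the type-appropriate
# "other" bucket.
taxonomy:
  food:
    - fast-food/restaurant
    - breakfast cereals
    - packaged snacks
    - condiments and cooking staples
    - mixed dishes
    - desserts
    - fruits and vegetables
    - protein
    - other food
  beverage:
    - alcoholic beverages
    - energy drinks
    - coffee/tea
    - plain water
    - fruit drinks
    - flavored water
    - sweetened milk
    - 100% juice
    - other beverage
  supplement:
    - dietary supplement

rules:
  food:
    - category: breakfast cereals
      keywords: [cereal, granola, oatmeal, muesli, porridge]
    - category: desserts
      keywords: [cake, cookie, brownie, ice cream, pie, donut, doughnut,
                 cupcake, pudding, cheesecake, dessert, macaron, pastry]
    - category: packaged snacks
      keywords: [chips, crisps, crackers, popcorn, pretzel, candy, chocolate bar,
                 gummy, snack, jerky, trail mix, granola bar, protein bar]
    - category: condiments and cooking staples
      keywords: [sauce, ketchup, mustard, mayonnaise, dressing, seasoning,
                 spice, oil, vinegar, flour, syrup, honey, condiment, salsa]
    - category: mixed dishes
      keywords: [lasagna, casserole, pasta, pizza, stir fry, stir-fry, curry,
                 soup, stew, sandwich, taco, burrito, bowl, ramen, salad,
                 noodles, mac and cheese, sushi, mixed dish]
    - category: fruits and vegetables
      keywords: [apple, banana, berries, strawberr, mango, avocado, grape,
                 watermelon, orange, fruit, vegetable, broccoli, carrot,
                 cucumber, salad greens, pineapple]
    - category: protein
      keywords: [chicken, beef, steak, pork, fish, salmon, shrimp, egg, tofu,
                 turkey, bacon, sausage, meat, protein]
  beverage:
    - category: alcoholic beverages
      keywords: [beer, wine, vodka, whiskey, tequila, cocktail, champagne,
                 seltzer hard, hard seltzer, rum, gin, liqueur, alcohol]
    - category: energy drinks
      keywords: [energy drink, energy, prime energy, red bull, monster]
    - category: coffee/tea
      keywords: [coffee, latte, espresso, cold-brew, cold brew, cappuccino,
                 tea, matcha, chai]
    - category: plain water
      keywords: [plain water, still water, spring water, sparkling water]
    - category: flavored water
      keywords: [flavored water, flavoured water, vitamin water]
    - category: 100% juice
      keywords: ["100% juice", "100 % juice", orange juice, apple juice]
    - category: fruit drinks
      keywords: [fruit drink, fruit punch, lemonade, juice drink]
    - category: sweetened milk
      keywords: [chocolate milk, strawberry milk, sweetened milk, milkshake,
                 flavored milk]
  supplement:
    - category: dietary supplement
      keywords: []
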