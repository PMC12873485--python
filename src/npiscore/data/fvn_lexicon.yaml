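# Fruit / vegetable / nut ingredient lexicon used by the first-five-ingredients
# assumption: if any of a food's first five ingredients matches an entry below
# (case-insensitive substring match), the food is assumed to contain at least
# 50 % fruit, vegetables or nuts.
# Human-editable; both singular and plural forms are listed where they differ
# beyond a trailing "s".
terms:
  - apple
  - apricot
  - avocado
  - banana
  - blackberr
  - blueberr
  - carrot
  - cashew
  - cherr
  - chickpea
  - coconut
  - cranberr
  - date
  - fig
  - grape
  - hazelnut
  - kale
  - lentil
  - mango
  - mushroom
  - onion
  - orange
  - pea
  - peach
  - peanut
  - pecan
  - pepper
  - pineapple
  - pistachio
  - raisin
  - raspberr
  - spinach
  - strawberr
  - tomato
  - walnut
  - almond
  - broccoli
  - cauliflower
  - celery
  - cucumber
  - garlic
  - lemon
  - lime
  - lettuce
  - squash
  - sweet potato
  - zucchini
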