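# Default Chinese Preschooler Dietary Index (CPDI) scoring standard.
#
# All cutoffs are densities: amount per 1000 kcal of energy intake.
# Two age groups (completed years): young = 2-3, old = 4-5.
# Categories:
#   adequacy   - full score at/above `recommended`, proportional below
#   moderation - full score inside [lower, upper]; 0 at intake 0 and
#                strictly above `zero_above` (= 2 x upper); linear between
#   limitation - full score at 0 intake, 0 at/above `limit`
name: CPDI
age_groups:
  young:
    ages: [2, 3]
    energy_range_kcal: [1000, 1200]
  old:
    ages: [4, 5]
    energy_range_kcal: [1200, 1400]
components:
  - id: vegetables
    name: Vegetables
    category: adequacy
    unit: g
    max_score: 10
    cutoffs:
      young: {recommended: 167}
      old: {recommended: 179}
  - id: fruits
    name: Fruits
    category: adequacy
    unit: g
    max_score: 10
    cutoffs:
      young: {recommended: 83}
      old: {recommended: 107}
  - id: dairy
    name: Dairy and dairy products
    category: adequacy
    unit: g
    max_score: 10
    cutoffs:
      young: {recommended: 417}
      old: {recommended: 250}
  - id: soybeans
    name: Soybeans and its products
    category: adequacy
    unit: g
    max_score: 10
    cutoffs:
      young: {recommended: 4}
      old: {recommended: 11}
  - id: aquatic_products
    name: Aquatic products
    category: adequacy
    unit: g
    max_score: 10
    cutoffs:
      young: {recommended: 12.5}
      old: {recommended: 14}
  - id: cereals
    name: Cereals
    category: moderation
    unit: g
    max_score: 10
    cutoffs:
      young: {lower: 71, upper: 100, zero_above: 200}
      old: {lower: 71, upper: 125, zero_above: 250}
  - id: eggs
    name: Eggs
    category: moderation
    unit: g
    max_score: 10
    cutoffs:
      young: {lower: 17, upper: 25, zero_above: 50}
      old: {lower: 18, upper: 21, zero_above: 42}
  - id: red_meat_poultry
    name: Red meat and poultry
    category: moderation
    unit: g
    max_score: 10
    cutoffs:
      young: {lower: 12.5, upper: 25, zero_above: 50}
      old: {lower: 18, upper: 33, zero_above: 66}
  - id: vitamin_a
    name: Vitamin A
    category: moderation
    unit: ug_rae
    max_score: 2.5
    cutoffs:
      young: {lower: 258, upper: 700, zero_above: 1400}
      old: {lower: 257, upper: 750, zero_above: 1500}
  - id: iron
    name: Iron
    category: moderation
    unit: mg
    max_score: 2.5
    cutoffs:
      young: {lower: 7.5, upper: 25, zero_above: 50}
      old: {lower: 7.1, upper: 25, zero_above: 50}
  - id: snacks
    name: High-sugar and high-fat snacks
    category: limitation
    unit: g
    max_score: 5
    cutoffs:
      young: {limit: 100}
      old: {limit: 100}
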