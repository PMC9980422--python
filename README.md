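# foodsift

Semi-automated record linkage between a table of **branded food products**
(name, energy, and seven nutrients) and a **reference food-composition
table** of generic foods — the kind of harmonization needed before a market
dataset of packaged foods can be used in nutritional epidemiology. The
toolkit suggests and ranks candidate matches; the final judgment is left to
dietetics experts, for whom it keeps decision logs and computes agreement
and accuracy statistics.

## The matching algorithm

For a product *E* and candidate reference food *C* (both per 100 g), define
for each caloric nutrient *X* the **proportion-of-calories difference**

    d_X = | 100·g_X(E)·k_X / kcal(E) − 100·g_X(C)·k_X / kcal(C) |   [pp]

where `k_X` is the kcal-per-gram factor of nutrient *X*, and the **relative
sodium difference**

    d_Na = | Na(E) − Na(C) | / Na(E)      (only when Na(E) > 0).

One **sift** restricts candidates to foods sharing the product's blocking
group (a common food-classification label) and then applies up to five
filters:

1. `d_X < t_macro` simultaneously for carbohydrate, protein, total fat;
2. `d_X < t_secondary` simultaneously for fiber, saturated fat, sugar;
3. `d_Na < t_sodium` (skipped when the product has zero sodium);
4. *(optional)* name similarity ≥ a minimum fuzzy score;
5. *(optional)* keep only the food(s) with the maximum fuzzy score among
   the survivors ("fuzzy match optimization").

Name similarity is the **partial token sort ratio** (0–100): normalize,
sort tokens, slide the shorter token string over the longer and take the
best Ratcliff/Obershelp matching-blocks ratio. Four named presets ship with
the package (`first` 20/10/0.5, `first_plus` 60/60/0.5 with fuzzy floor 50,
`second` 40/40/0.5, `third` all ∞) and compose into the default
**schedule**: zero-match products fall through `second` then `third`;
`first`'s single-match products are re-run through `first_plus`, whose
output *replaces* the original suggestion — so a lone match with a weak
name score is deliberately dropped back to manual matching. Surviving
candidates are ranked by their **maximal nutritional difference** (the
largest entry of the difference vector on a percent scale), smallest first.

## Worked example

```python
from foodsift import (
    NutrientProfile, ProductRecord, ReferenceFoodRecord, LinkageDataset,
    run_schedule, default_schedule, flow_summary,
)

product = ProductRecord(
    product_id="EM001",
    subcategory="Children's Breakfast Cereals",
    brand="Maple Crest",
    blocking_group="breakfast_cereals",
    profile=NutrientProfile(energy=380, carbohydrate=82, protein=7,
                            total_fat=3, saturated_fat=0.6, sugar=30,
                            fiber=6, sodium=500),
)
reference = [
    ReferenceFoodRecord(
        "CNF100", "Cereal, ready to eat, toasted oat rings",
        "breakfast_cereals",
        NutrientProfile(energy=390, carbohydrate=78, protein=9, total_fat=5,
                        saturated_fat=1.0, sugar=22, fiber=7, sodium=620)),
    ReferenceFoodRecord(
        "CNF101", "Cereal, ready to eat, children's, sweetened corn",
        "breakfast_cereals",
        NutrientProfile(energy=385, carbohydrate=86, protein=5, total_fat=2,
                        saturated_fat=0.5, sugar=41, fiber=3, sodium=480)),
    ReferenceFoodRecord(
        "CNF200", "Cheese, blue", "dairy",
        NutrientProfile(energy=353, carbohydrate=2.3, protein=21, total_fat=29,
                        saturated_fat=19, sugar=0.5, fiber=0, sodium=1400)),
]
report = run_schedule(LinkageDataset([product], reference), default_schedule())
outcome = report.outcomes["EM001"]
print("level:", outcome.level, "| produced by sift:", outcome.provenance)
for c in outcome.suggestions:
    print(f"  {c.food_id}  max_diff={c.max_diff:.2f}  fuzzy={c.fuzzy_score}")
print(flow_summary(report).to_string(index=False))
```

prints

```
level: 1 | produced by sift: first_plus
  CNF101  max_diff=11.02  fuzzy=60
 sift_name  entered  out_zero  out_single  out_many
     first        1         0           1         0
first_plus        1         0           1         0
```

Blue cheese is never considered (different blocking group). Both cereals
pass the nutrient filters of `first`, but fuzzy-match optimization keeps
only the children's cereal, whose name scores 60 against the product's.
As a single match it is re-run through `first_plus`, where it clears the
fuzzy floor of 50 and survives with a worst-case nutritional error of
11 pp (the sugar proportion-of-calories difference).

## Command line

```sh
foodsift simulate --seed 7 --out-dir sim/        # synthetic dataset + truth
foodsift sift     --products sim/products.csv --reference sim/reference.csv \
                  --preset first --out-dir out/  # one sift
foodsift pipeline --products sim/products.csv --reference sim/reference.csv \
                  --out-dir out/                 # full default schedule
foodsift report   --decisions decisions.csv --out-dir out/  # agreement rates
```

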