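"""Synthetic linkage datasets with known ground truth.

The generator emulates the statistical shape of a branded-product table
linked against a national food-composition table: blocking groups play the
role of a shared food-classification scheme, reference foods carry
category-structured nutrient profiles per 100 g, and products are noisy
clones of reference foods with marketing-style names (corrupted food-name
tokens plus a brand token).

Design choices that make recovery analyzable rather than merely plausible:

* Nutrient noise is multiplicative and bounded: each caloric nutrient of a
  cloned product is scaled by an independent uniform factor in
  ``[1 - amplitude, 1 + amplitude]``.
* A profile's energy is always recomputed from its caloric nutrients via
  the energy factors, so nutrient proportions of calories sum to exactly
  100 and the proportion-of-calories deviation of a clone from its source
  is bounded by ``100 * 2a / (1 - a)`` percentage points for amplitude
  ``a`` — choosing ``a`` below a sift's thresholds *guarantees* the true
  food survives the nutrient filters.
* Name corruption acts on whole tokens (shuffle, drop, insert), the
  operations the partial token sort ratio is designed to absorb.

With a fixed seed the generator is byte-deterministic (NumPy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigError, ValidationError
from .metrics import DEFAULT_FACTORS, EnergyFactors
from .model import (
    CALORIC_NUTRIENTS,
    LinkageDataset,
    NutrientProfile,
    ProductRecord,
    ReferenceFoodRecord,
)
from .schedule import MatchReport, ROUTE_ALGORITHM

_VOCABULARY = [
    "almond", "apple", "bar", "bean", "berry", "biscuit", "bread", "broth",
    "butter", "cake", "cereal", "cheese", "cherry", "chicken", "chip",
    "chocolate", "cocoa", "cookie", "corn", "cracker", "cream", "crisp",
    "crunch", "curd", "dark", "dip", "dried", "drink", "fig", "fish",
    "flake", "fresh", "fruit", "garlic", "golden", "grain", "granola",
    "ham", "honey", "instant", "juice", "lemon", "light", "loaf", "maple",
    "milk", "mix", "nut", "oat", "onion", "orange", "pasta", "peanut",
    "pepper", "plain", "pork", "potato", "pudding", "raisin", "rice",
    "roasted", "salted", "sauce", "seed", "slice", "smoked", "snack",
    "soda", "soup", "sour", "spread", "sweet", "syrup", "toasted",
    "tomato", "vanilla", "wafer", "wheat", "white", "whole", "yogurt",
]

# Brand tokens sort after every vocabulary token, so an uncorrupted clone's
# token-sorted name keeps its source food's sorted tokens as a contiguous
# prefix and the name matcher scores the pair 100 exactly.
_BRANDS = [
    "zenith", "zephyr", "zeta", "zigzag", "zinnia", "zircon", "zodiac",
    "zoom", "zorro", "zulu",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic linkage generator.

    Defaults describe a desk-scale analogue of a national linkage exercise:
    a dozen blocking groups averaging eight reference foods and four
    products each, 5% multiplicative nutrient noise on cloned products,
    mild token-level name corruption, a tenth of products with no true
    counterpart, and small fractions of zero-energy and missing-field
    products that must be screened out before matching.
    """

    seed: int = 0
    n_groups: int = 12
    mean_foods_per_group: float = 8.0
    mean_products_per_group: float = 4.0
    perturbation: float = 0.05  # relative noise amplitude on caloric nutrients
    sodium_perturbation: Optional[float] = None  # defaults to `perturbation`
    name_shuffle: bool = True
    token_drop_prob: float = 0.2
    token_insert_prob: float = 0.2
    unmatchable_fraction: float = 0.1
    zero_energy_fraction: float = 0.03
    missing_field_fraction: float = 0.03
    factors: EnergyFactors = field(default_factory=EnergyFactors)

    def __post_init__(self) -> None:
        probs = {
            "token_drop_prob": self.token_drop_prob,
            "token_insert_prob": self.token_insert_prob,
            "unmatchable_fraction": self.unmatchable_fraction,
            "zero_energy_fraction": self.zero_energy_fraction,
            "missing_field_fraction": self.missing_field_fraction,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.zero_energy_fraction + self.missing_field_fraction > 1:
            raise ConfigError("exclusion fractions must sum to at most 1")
        if not 0 <= self.perturbation < 1:
            raise ConfigError("perturbation must be in [0, 1)")
        if self.n_groups < 1 or self.mean_foods_per_group <= 0:
            raise ConfigError("need at least one group with a positive food count")
        if self.mean_products_per_group > 0 and self.mean_foods_per_group <= 0:
            raise ConfigError("cannot place products in groups without foods")


def _group_means(rng: np.random.Generator) -> dict[str, float]:
    """Draw plausible per-100 g nutrient means for one food category."""
    carb = rng.uniform(5.0, 70.0)
    protein = rng.uniform(2.0, 30.0)
    fat = rng.uniform(1.0, 40.0)
    return {
        "carbohydrate": carb,
        "protein": protein,
        "total_fat": fat,
        "saturated_fat": fat * rng.uniform(0.2, 0.6),
        "sugar": carb * rng.uniform(0.1, 0.8),
        "fiber": rng.uniform(0.2, 10.0),
        "sodium": rng.uniform(10.0, 1500.0),
    }


def _profile_from_grams(
    grams: dict[str, float], sodium: float, factors: EnergyFactors
) -> NutrientProfile:
    energy = sum(grams[n] * factors.factor(n) for n in CALORIC_NUTRIENTS)
    return NutrientProfile(energy=energy, sodium=sodium, **grams)


def _draw_food_grams(
    means: dict[str, float], rng: np.random.Generator
) -> tuple[dict[str, float], float]:
    grams = {
        n: means[n] * float(np.exp(rng.normal(0.0, 0.3)))
        for n in CALORIC_NUTRIENTS
    }
    sodium = means["sodium"] * float(np.exp(rng.normal(0.0, 0.3)))
    return grams, sodium


def _corrupt_name(
    tokens: list[str],
    config: GeneratorConfig,
    group_vocab: list[str],
    rng: np.random.Generator,
) -> list[str]:
    kept = [t for t in tokens if rng.random() >= config.token_drop_prob]
    if not kept:
        kept = [tokens[int(rng.integers(len(tokens)))]]
    if rng.random() < config.token_insert_prob:
        kept.append(group_vocab[int(rng.integers(len(group_vocab)))])
    if config.name_shuffle:
        kept = [kept[i] for i in rng.permutation(len(kept))]
    return kept


def generate(config: GeneratorConfig) -> tuple[LinkageDataset, dict[str, Optional[str]]]:
    """Generate a dataset and its ground-truth map ``product_id -> food_id``
    (``None`` for products with no true counterpart)."""
    rng = np.random.default_rng(config.seed)
    sodium_amp = (
        config.perturbation
        if config.sodium_perturbation is None
        else config.sodium_perturbation
    )

    reference: list[ReferenceFoodRecord] = []
    products: list[ProductRecord] = []
    truth: dict[str, Optional[str]] = {}
    foods_by_group: dict[str, list[ReferenceFoodRecord]] = {}
    group_vocabs: dict[str, list[str]] = {}
    group_means: dict[str, dict[str, float]] = {}

    for g in range(config.n_groups):
        group = f"G{g:02d}"
        vocab_idx = rng.choice(len(_VOCABULARY), size=10, replace=False)
        group_vocabs[group] = [_VOCABULARY[i] for i in vocab_idx]
        group_means[group] = _group_means(rng)
        n_foods = max(1, int(rng.poisson(config.mean_foods_per_group)))
        foods_by_group[group] = []
        for k in range(n_foods):
            grams, sodium = _draw_food_grams(group_means[group], rng)
            n_tokens = int(rng.integers(2, 5))
            tokens = [
                group_vocabs[group][int(i)]
                for i in rng.choice(len(group_vocabs[group]), size=n_tokens, replace=False)
            ]
            food = ReferenceFoodRecord(
                food_id=f"F{g:02d}{k:03d}",
                name=", ".join(tokens),
                blocking_group=group,
                profile=_profile_from_grams(grams, sodium, config.factors),
            )
            reference.append(food)
            foods_by_group[group].append(food)

    pid = 0
    for g in range(config.n_groups):
        group = f"G{g:02d}"
        n_products = int(rng.poisson(config.mean_products_per_group))
        for _ in range(n_products):
            pid += 1
            product_id = f"P{pid:04d}"
            brand = _BRANDS[int(rng.integers(len(_BRANDS)))]
            if rng.random() < config.unmatchable_fraction:
                grams, sodium = _draw_food_grams(group_means[group], rng)
                vocab = group_vocabs[group]
                n_tokens = int(rng.integers(2, 5))
                tokens = [
                    vocab[int(i)]
                    for i in rng.choice(len(vocab), size=n_tokens, replace=False)
                ]
                profile = _profile_from_grams(grams, sodium, config.factors)
                truth[product_id] = None
            else:
                source = foods_by_group[group][
                    int(rng.integers(len(foods_by_group[group])))
                ]
                a = config.perturbation
                grams = {
                    n: source.profile.get(n) * float(rng.uniform(1 - a, 1 + a))
                    for n in CALORIC_NUTRIENTS
                }
                sodium = source.profile.sodium * float(
                    rng.uniform(1 - sodium_amp, 1 + sodium_amp)
                )
                tokens = _corrupt_name(
                    [t.strip() for t in source.name.split(",")],
                    config,
                    group_vocabs[group],
                    rng,
                )
                profile = _profile_from_grams(grams, sodium, config.factors)
                truth[product_id] = source.food_id
            u = rng.random()
            if u < config.zero_energy_fraction:
                profile = replace(
                    profile,
                    energy=0.0,
                    **{n: 0.0 for n in CALORIC_NUTRIENTS},
                )
            elif u < config.zero_energy_fraction + config.missing_field_fraction:
                victim = CALORIC_NUTRIENTS[int(rng.integers(len(CALORIC_NUTRIENTS)))]
                profile = replace(profile, **{victim: None})
            products.append(
                ProductRecord(
                    product_id=product_id,
                    subcategory=" ".join(tokens),
                    brand=brand,
                    blocking_group=group,
                    profile=profile,
                )
            )

    dataset = LinkageDataset(
        products=products,
        reference=reference,
        group_vocabulary={f"G{g:02d}" for g in range(config.n_groups)},
    )
    return dataset, truth


@dataclass
class RecoveryMetrics:
    """How well a match report recovers the known linkage.

    ``suggestion_recall``: fraction of eligible, truly-matched products
    whose true food appears in the final suggestion set.
    ``top_rank_recall``: fraction where the true food ranks first.
    ``None`` when no product qualifies for evaluation.
    """

    n_evaluated: int
    suggestion_recall: Optional[float]
    top_rank_recall: Optional[float]
    by_level: dict[int, tuple[int, int]]  # level -> (n, n_recovered)


def evaluate_recovery(
    report: MatchReport, truth: dict[str, Optional[str]]
) -> RecoveryMetrics:
    """Score a schedule run against the generator's ground truth.

    Only products that ran the algorithm (eligible) and have a true
    counterpart are evaluated; the report and truth map must cover the same
    product ids.
    """
    unknown = set(report.outcomes) - set(truth)
    if unknown:
        raise ValidationError(f"report contains unknown products: {sorted(unknown)[:5]}")
    n = 0
    hit = 0
    top = 0
    by_level: dict[int, list[int]] = {}
    for pid, outcome in report.outcomes.items():
        true_food = truth.get(pid)
        if outcome.route != ROUTE_ALGORITHM or true_food is None:
            continue
        n += 1
        suggested = [c.food_id for c in outcome.suggestions]
        recovered = true_food in suggested
        hit += recovered
        top += bool(suggested) and suggested[0] == true_food
        slot = by_level.setdefault(outcome.level, [0, 0])
        slot[0] += 1
        slot[1] += recovered
    return RecoveryMetrics(
        n_evaluated=n,
        suggestion_recall=(hit / n) if n else None,
        top_rank_recall=(top / n) if n else None,
        by_level={lvl: (a, b) for lvl, (a, b) in sorted(by_level.items())},
    )
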