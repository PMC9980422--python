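"""One sift: the five-filter cascade matching a product against the
reference table.

A *sift* evaluates every reference food sharing the product's blocking
group against up to five filters, in a fixed order:

1. macronutrient filter — carbohydrate, protein and total fat
   proportion-of-calories differences must all fall below a threshold;
2. secondary filter — the same rule for fiber, saturated fat and sugar;
3. sodium filter — relative sodium difference below a threshold, applied
   only when the product's sodium is non-zero;
4. (optional) minimum fuzzy score — the name similarity must meet a floor;
5. (optional) fuzzy-match optimization — keep only the food(s) achieving
   the maximum fuzzy score among the survivors of filters 1-4.

Filters 1-4 commute as set operations, but filter 5 depends on the
surviving pool, so the order is normative. Nutrient thresholds use strict
inequality ("falling below"); the fuzzy floor is met-or-exceeded so that a
printed floor of 50 admits a score of 50. Both comparisons are switchable
on :class:`SiftParameters`. A missing nutrient on the food side fails any
filter that needs it; an infinite threshold disables its filter entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import ConfigError, UsageError
from .fuzzy import partial_token_sort_ratio
from .metrics import (
    DEFAULT_FACTORS,
    EnergyFactors,
    NutrientDifferenceVector,
    difference_vector,
    max_nutritional_difference,
    proportion_difference,
    proportion_of_calories,
    relative_sodium_difference,
)
from .model import (
    MACRO_NUTRIENTS,
    SECONDARY_NUTRIENTS,
    ProductRecord,
    ReferenceFoodRecord,
)

logger = logging.getLogger(__name__)

INF = math.inf


def _parse_threshold(value: object) -> float:
    """Parse a threshold from config; the string ``"inf"`` is the no-maximum
    sentinel."""
    if isinstance(value, str):
        if value.strip().lower() in {"inf", "infinity", "∞"}:
            return INF
        value = float(value)
    v = float(value)
    if v < 0 or math.isnan(v):
        raise ConfigError(f"threshold must be >= 0 or 'inf', got {value!r}")
    return v


@dataclass(frozen=True)
class SiftParameters:
    """One named set of sift parameters.

    ``macro_threshold`` and ``secondary_threshold`` are in percentage
    points of proportion-of-calories difference; ``sodium_threshold`` is a
    relative-difference fraction. ``math.inf`` disables a filter.
    """

    name: str
    macro_threshold: float
    secondary_threshold: float
    sodium_threshold: float
    min_fuzzy_score: int = 0
    use_min_fuzzy: bool = False
    use_fuzzy_optimization: bool = True
    nutrient_strict: bool = True  # strict "<" for nutrient thresholds
    min_fuzzy_strict: bool = False  # ">=" (meets-or-exceeds) for the fuzzy floor

    def __post_init__(self) -> None:
        for attr in ("macro_threshold", "secondary_threshold", "sodium_threshold"):
            v = getattr(self, attr)
            if v < 0 or math.isnan(v):
                raise ConfigError(f"{attr} must be >= 0 or inf, got {v!r}")
        if not 0 <= self.min_fuzzy_score <= 100:
            raise ConfigError(
                f"min_fuzzy_score must be in [0, 100], got {self.min_fuzzy_score}"
            )

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SiftParameters":
        d = dict(d)
        for key in ("macro_threshold", "secondary_threshold", "sodium_threshold"):
            if key in d:
                d[key] = _parse_threshold(d[key])
        try:
            return cls(**d)  # type: ignore[arg-type]
        except TypeError as exc:
            raise ConfigError(f"bad sift parameters: {exc}") from exc

    def required_fields(self) -> tuple[str, ...]:
        """Profile fields a product must carry to pass through this sift."""
        fields = ["energy"]
        if math.isfinite(self.macro_threshold):
            fields += list(MACRO_NUTRIENTS)
        if math.isfinite(self.secondary_threshold):
            fields += list(SECONDARY_NUTRIENTS)
        if math.isfinite(self.sodium_threshold):
            fields.append("sodium")
        return tuple(fields)


#: Named presets for the four sifts of the reference protocol: an initial
#: strict pass, a looser augmentation pass with a fuzzy floor for
#: single-match products, and two fallback passes for unmatched products.
PRESETS: dict[str, SiftParameters] = {
    "first": SiftParameters(
        name="first",
        macro_threshold=20.0,
        secondary_threshold=10.0,
        sodium_threshold=0.5,
        min_fuzzy_score=0,
        use_min_fuzzy=False,
        use_fuzzy_optimization=True,
    ),
    "first_plus": SiftParameters(
        name="first_plus",
        macro_threshold=60.0,
        secondary_threshold=60.0,
        sodium_threshold=0.5,
        min_fuzzy_score=50,
        use_min_fuzzy=True,
        use_fuzzy_optimization=False,
    ),
    "second": SiftParameters(
        name="second",
        macro_threshold=40.0,
        secondary_threshold=40.0,
        sodium_threshold=0.5,
        min_fuzzy_score=0,
        use_min_fuzzy=False,
        use_fuzzy_optimization=True,
    ),
    "third": SiftParameters(
        name="third",
        macro_threshold=INF,
        secondary_threshold=INF,
        sodium_threshold=INF,
        min_fuzzy_score=0,
        use_min_fuzzy=False,
        use_fuzzy_optimization=True,
    ),
}


def get_preset(name: str) -> SiftParameters:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown sift preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class CandidateMatch:
    """A surviving (product, reference food) pair with its evidence."""

    product_id: str
    food_id: str
    food_name: str
    differences: NutrientDifferenceVector
    max_diff: float
    fuzzy_score: int
    sift_name: str


def candidate_pool(
    product: ProductRecord,
    reference: Sequence[ReferenceFoodRecord],
    blocking: bool = True,
) -> list[ReferenceFoodRecord]:
    """Reference foods sharing the product's blocking group (or all foods
    with blocking disabled). An unknown group yields an empty pool with a
    warning, not an error."""
    if not blocking:
        return list(reference)
    pool = [f for f in reference if f.blocking_group == product.blocking_group]
    if not pool:
        logger.warning(
            "product %s: blocking group %r has no reference foods",
            product.product_id,
            product.blocking_group,
        )
    return pool


def _passes_nutrients(
    product: ProductRecord,
    food: ReferenceFoodRecord,
    nutrients: Sequence[str],
    threshold: float,
    factors: EnergyFactors,
    strict: bool,
) -> bool:
    if math.isinf(threshold):
        return True
    pe = product.profile.energy
    fe = food.profile.energy
    if fe is None or fe <= 0:
        return False
    for nutrient in nutrients:
        pg = product.profile.get(nutrient)
        fg = food.profile.get(nutrient)
        if pg is None or fg is None:
            return False
        diff = proportion_difference(
            proportion_of_calories(pg, nutrient, pe, factors),
            proportion_of_calories(fg, nutrient, fe, factors),
        )
        if not (diff < threshold if strict else diff <= threshold):
            return False
    return True


def filter_macros(
    product: ProductRecord,
    pool: Iterable[ReferenceFoodRecord],
    macro_threshold: float,
    factors: EnergyFactors = DEFAULT_FACTORS,
    strict: bool = True,
) -> list[ReferenceFoodRecord]:
    """Filter 1: carbohydrate, protein and total-fat proportion-of-calories
    differences must all fall below the threshold simultaneously."""
    return [
        f
        for f in pool
        if _passes_nutrients(product, f, MACRO_NUTRIENTS, macro_threshold, factors, strict)
    ]


def filter_secondary(
    product: ProductRecord,
    pool: Iterable[ReferenceFoodRecord],
    secondary_threshold: float,
    factors: EnergyFactors = DEFAULT_FACTORS,
    strict: bool = True,
) -> list[ReferenceFoodRecord]:
    """Filter 2: the same simultaneous rule for fiber, saturated fat, sugar."""
    return [
        f
        for f in pool
        if _passes_nutrients(
            product, f, SECONDARY_NUTRIENTS, secondary_threshold, factors, strict
        )
    ]


def filter_sodium(
    product: ProductRecord,
    pool: Iterable[ReferenceFoodRecord],
    sodium_threshold: float,
    strict: bool = True,
) -> list[ReferenceFoodRecord]:
    """Filter 3: relative sodium difference below the threshold; skipped
    entirely when the product's sodium content is zero or missing."""
    if math.isinf(sodium_threshold):
        return list(pool)
    ps = product.profile.sodium
    if ps is None or ps == 0:
        return list(pool)
    kept = []
    for f in pool:
        fs = f.profile.sodium
        if fs is None:
            continue
        diff = relative_sodium_difference(ps, fs)
        if diff < sodium_threshold if strict else diff <= sodium_threshold:
            kept.append(f)
    return kept


def _fuzzy_scores(
    product: ProductRecord, pool: Sequence[ReferenceFoodRecord]
) -> dict[str, int]:
    return {f.food_id: partial_token_sort_ratio(product.name, f.name) for f in pool}


def filter_min_fuzzy(
    product: ProductRecord,
    pool: Sequence[ReferenceFoodRecord],
    min_score: int,
    strict: bool = False,
    scores: Optional[Mapping[str, int]] = None,
) -> list[ReferenceFoodRecord]:
    """Filter 4: name similarity must meet the floor (``>=`` by default)."""
    scores = scores or _fuzzy_scores(product, pool)
    if strict:
        return [f for f in pool if scores[f.food_id] > min_score]
    return [f for f in pool if scores[f.food_id] >= min_score]


def filter_fuzzy_optimization(
    product: ProductRecord,
    pool: Sequence[ReferenceFoodRecord],
    scores: Optional[Mapping[str, int]] = None,
) -> list[ReferenceFoodRecord]:
    """Filter 5: keep every food achieving the maximum fuzzy score in the
    incoming pool (ties all kept); an empty pool stays empty."""
    if not pool:
        return []
    scores = scores or _fuzzy_scores(product, pool)
    best = max(scores[f.food_id] for f in pool)
    return [f for f in pool if scores[f.food_id] == best]


def run_sift(
    product: ProductRecord,
    reference: Sequence[ReferenceFoodRecord],
    params: SiftParameters,
    factors: EnergyFactors = DEFAULT_FACTORS,
    blocking: bool = True,
) -> list[CandidateMatch]:
    """Run the full five-filter cascade for one product.

    Returns one :class:`CandidateMatch` per surviving reference food, each
    carrying its difference vector, maximal nutritional difference, fuzzy
    score and the sift's name. The product must be eligible (positive
    energy and every field the sift's filters need).
    """
    if product.eligible is False:
        raise UsageError(
            f"product {product.product_id} is ineligible ({product.exclusion_reason})"
        )
    pe = product.profile.energy
    if pe is None or pe <= 0 or product.profile.missing_fields(params.required_fields()):
        raise UsageError(
            f"product {product.product_id} lacks fields required by sift "
            f"{params.name!r}; screen eligibility first"
        )
    pool = candidate_pool(product, reference, blocking)
    pool = filter_macros(product, pool, params.macro_threshold, factors, params.nutrient_strict)
    pool = filter_secondary(
        product, pool, params.secondary_threshold, factors, params.nutrient_strict
    )
    pool = filter_sodium(product, pool, params.sodium_threshold, params.nutrient_strict)
    scores = _fuzzy_scores(product, pool)
    if params.use_min_fuzzy:
        pool = filter_min_fuzzy(
            product, pool, params.min_fuzzy_score, params.min_fuzzy_strict, scores
        )
    if params.use_fuzzy_optimization:
        pool = filter_fuzzy_optimization(product, pool, scores)
    matches = []
    for f in pool:
        diffs = difference_vector(product.profile, f.profile, factors)
        matches.append(
            CandidateMatch(
                product_id=product.product_id,
                food_id=f.food_id,
                food_name=f.name,
                differences=diffs,
                max_diff=max_nutritional_difference(diffs),
                fuzzy_score=scores[f.food_id],
                sift_name=params.name,
            )
        )
    return matches
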