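"""Nutrient-difference algebra and candidate ranking.

Nutrient distances between a product and a reference food are measured as
differences in each nutrient *as a proportion of calories* — the share of a
food's energy contributed by the nutrient — rather than absolute or relative
gram differences. Proportions of calories are robust across foods spanning a
wide caloric range: scaling every mass-based field of both profiles by the
same factor leaves every proportion difference unchanged.

Sodium contributes no energy, so it is compared by relative difference
instead, normalized by the product's sodium content and applied only when
that content is non-zero.

For ranking, the candidate's *maximal nutritional difference* is the largest
entry of its difference vector on a common percent scale (percentage points
for the six caloric nutrients; relative fraction x 100 for sodium), and
candidates are listed ascending so the smallest worst-case nutritional error
comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

from .exceptions import DomainError, UsageError, ValidationError
from .model import CALORIC_NUTRIENTS, NutrientProfile

if TYPE_CHECKING:  # pragma: no cover
    from .sift import CandidateMatch


@dataclass(frozen=True)
class EnergyFactors:
    """kcal-per-gram conversion factors for the six caloric nutrients.

    Defaults are Atwater-style general factors (carbohydrate and protein
    4 kcal/g, fats 9 kcal/g, sugar 4 kcal/g as a carbohydrate, fiber 2 kcal/g
    reflecting partial fermentability). Fully configurable via the
    ``energy_factors`` config key.
    """

    carbohydrate: float = 4.0
    protein: float = 4.0
    total_fat: float = 9.0
    saturated_fat: float = 9.0
    sugar: float = 4.0
    fiber: float = 2.0

    def __post_init__(self) -> None:
        for name in CALORIC_NUTRIENTS:
            if getattr(self, name) <= 0:
                raise ValidationError(f"energy factor {name} must be > 0")

    def factor(self, nutrient: str) -> float:
        if nutrient not in CALORIC_NUTRIENTS:
            raise KeyError(nutrient)
        return getattr(self, nutrient)


DEFAULT_FACTORS = EnergyFactors()


def proportion_of_calories(
    nutrient_g: float,
    nutrient: str,
    energy_kcal: float,
    factors: EnergyFactors = DEFAULT_FACTORS,
) -> float:
    """Percent of a food's energy contributed by one nutrient.

    ``100 * nutrient_g * factor / energy_kcal``. May exceed 100 for rounded
    labels or fiber conventions; not clamped. Requires ``energy_kcal > 0``.
    """
    if energy_kcal <= 0:
        raise DomainError(
            f"proportion of calories requires energy > 0, got {energy_kcal}"
        )
    if nutrient_g < 0:
        raise DomainError(f"nutrient mass must be >= 0, got {nutrient_g}")
    return 100.0 * nutrient_g * factors.factor(nutrient) / energy_kcal


def proportion_difference(p_e: float, p_c: float) -> float:
    """Absolute difference of two proportion-of-calories values, in pp."""
    return abs(p_e - p_c)


def relative_sodium_difference(sod_e: float, sod_c: float) -> float:
    """|sodium_E - sodium_C| / sodium_E, as a fraction.

    Defined only for products with non-zero sodium; callers must skip the
    sodium comparison otherwise.
    """
    if sod_e <= 0:
        raise DomainError(f"relative sodium difference requires sodium > 0, got {sod_e}")
    return abs(sod_e - sod_c) / sod_e


@dataclass(frozen=True)
class NutrientDifferenceVector:
    """Per-nutrient distances between one product and one reference food.

    The six caloric entries are absolute proportion-of-calories differences
    in percentage points; ``sodium_rel`` is the absolute relative sodium
    difference as a fraction. An entry is ``None`` when it could not be
    computed (a missing nutrient on either side, or a reference food without
    positive energy); ``sodium_skipped`` is set when the product's sodium is
    zero or missing, mirroring the filter's non-zero-sodium precondition.
    """

    carbohydrate: Optional[float] = None
    protein: Optional[float] = None
    total_fat: Optional[float] = None
    fiber: Optional[float] = None
    saturated_fat: Optional[float] = None
    sugar: Optional[float] = None
    sodium_rel: Optional[float] = None
    sodium_skipped: bool = False

    def __post_init__(self) -> None:
        for name in CALORIC_NUTRIENTS + ("sodium_rel",):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"difference {name} must be >= 0")

    def get(self, nutrient: str) -> Optional[float]:
        return getattr(self, nutrient)


def difference_vector(
    product_profile: NutrientProfile,
    food_profile: NutrientProfile,
    factors: EnergyFactors = DEFAULT_FACTORS,
) -> NutrientDifferenceVector:
    """Tabulate all per-nutrient distances for one candidate pair.

    Requires the product's energy to be positive (screened upstream); a
    reference food without positive energy yields ``None`` caloric entries.
    """
    pe = product_profile.energy
    if pe is None or pe <= 0:
        raise DomainError("product must have positive energy (screen first)")
    fe = food_profile.energy
    values: dict[str, Optional[float]] = {}
    for nutrient in CALORIC_NUTRIENTS:
        pg = product_profile.get(nutrient)
        fg = food_profile.get(nutrient)
        if pg is None or fg is None or fe is None or fe <= 0:
            values[nutrient] = None
        else:
            values[nutrient] = proportion_difference(
                proportion_of_calories(pg, nutrient, pe, factors),
                proportion_of_calories(fg, nutrient, fe, factors),
            )
    ps = product_profile.sodium
    fs = food_profile.sodium
    if ps is None or ps == 0:
        return NutrientDifferenceVector(**values, sodium_rel=None, sodium_skipped=True)
    if fs is None:
        return NutrientDifferenceVector(**values, sodium_rel=None, sodium_skipped=False)
    return NutrientDifferenceVector(
        **values, sodium_rel=relative_sodium_difference(ps, fs), sodium_skipped=False
    )


def max_nutritional_difference(
    v: NutrientDifferenceVector, include_sodium: bool = True
) -> float:
    """Largest entry of the difference vector on a common percent scale.

    The six caloric entries are already percentage points; sodium enters as
    relative fraction x 100. Entries that are ``None`` (uncomputable) are
    ignored; a vector with no computable entries scores ``inf`` so that such
    candidates rank last. ``include_sodium=False`` excludes sodium from the
    ranking scale (see docs on the unit-mixing caveat).
    """
    entries = [v.get(n) for n in CALORIC_NUTRIENTS]
    if include_sodium and not v.sodium_skipped and v.sodium_rel is not None:
        entries.append(100.0 * v.sodium_rel)
    known = [e for e in entries if e is not None]
    if not known:
        return math.inf
    return max(known)


def rank_candidates(
    candidates: Sequence["CandidateMatch"],
) -> list["CandidateMatch"]:
    """Order one product's candidates by ascending maximal nutritional
    difference, ties broken by ``food_id`` ascending (deterministic)."""
    products = {c.product_id for c in candidates}
    if len(products) > 1:
        raise UsageError(
            f"rank_candidates expects one product, got {sorted(products)}"
        )
    return sorted(candidates, key=lambda c: (c.max_diff, c.food_id))
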