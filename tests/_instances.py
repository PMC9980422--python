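"""Random small linkage instances used by the brute-force equivalence and
monotonicity suites. Each instance is produced in two parallel forms: plain
dicts for the oracle and domain records for the implementation."""

from __future__ import annotations

import math

import numpy as np

from foodsift.model import NutrientProfile, ProductRecord, ReferenceFoodRecord
from foodsift.sift import SiftParameters

_WORDS = [
    "oat", "milk", "bar", "dark", "rice", "corn", "nut", "plain", "sweet",
    "salted", "berry", "cocoa",
]

_FIELDS = ("carbohydrate", "protein", "total_fat", "fiber", "saturated_fat", "sugar")


def _random_name(rng: np.random.Generator) -> str:
    n = int(rng.integers(1, 4))
    idx = rng.choice(len(_WORDS), size=n, replace=False)
    return " ".join(_WORDS[i] for i in idx)


def _random_profile_dict(rng: np.random.Generator, allow_missing: bool) -> dict:
    d = {
        "energy": float(rng.uniform(20, 600)),
        "sodium": float(rng.choice([0.0, rng.uniform(1, 2000)])),
    }
    for f in _FIELDS:
        if allow_missing and rng.random() < 0.1:
            d[f] = None
        else:
            d[f] = float(rng.uniform(0, 60))
    return d


def _to_profile(d: dict) -> NutrientProfile:
    return NutrientProfile(
        energy=d["energy"], sodium=d["sodium"],
        **{f: d[f] for f in _FIELDS},
    )


def random_instance(rng: np.random.Generator, max_foods: int = 20):
    """One product, a pool of foods across two groups, and random sift
    parameters. Returns (product_dict, pool_dicts, params_dict,
    product_record, food_records, sift_params)."""
    product_d = _random_profile_dict(rng, allow_missing=False)
    product_d["name"] = _random_name(rng)
    product_d["group"] = "G1"
    pool_d = []
    for i in range(int(rng.integers(0, max_foods + 1))):
        food = _random_profile_dict(rng, allow_missing=True)
        food["name"] = _random_name(rng)
        food["group"] = "G1" if rng.random() < 0.8 else "G2"
        food["id"] = f"F{i:03d}"
        pool_d.append(food)

    def threshold(finite_hi: float) -> float:
        return math.inf if rng.random() < 0.2 else float(rng.uniform(0, finite_hi))

    params_d = {
        "macro": threshold(60.0),
        "secondary": threshold(60.0),
        "sodium": math.inf if rng.random() < 0.2 else float(rng.uniform(0, 1.5)),
        "min_fuzzy_score": int(rng.integers(0, 101)),
        "use_min_fuzzy": bool(rng.random() < 0.5),
        "use_fuzzy_optimization": bool(rng.random() < 0.5),
    }

    product = ProductRecord(
        product_id="P1", subcategory=product_d["name"], brand="",
        blocking_group="G1", profile=_to_profile(product_d),
        name=product_d["name"], eligible=True,
    )
    foods = [
        ReferenceFoodRecord(
            food_id=f["id"], name=f["name"], blocking_group=f["group"],
            profile=_to_profile(f),
        )
        for f in pool_d
    ]
    params = SiftParameters(
        name="random",
        macro_threshold=params_d["macro"],
        secondary_threshold=params_d["secondary"],
        sodium_threshold=params_d["sodium"],
        min_fuzzy_score=params_d["min_fuzzy_score"],
        use_min_fuzzy=params_d["use_min_fuzzy"],
        use_fuzzy_optimization=params_d["use_fuzzy_optimization"],
    )
    return product_d, pool_d, params_d, product, foods, params
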