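import dataclasses
import math

import numpy as np
import pytest

from foodsift.exceptions import ConfigError, UsageError
from foodsift.metrics import DEFAULT_FACTORS
from foodsift.model import screen_eligibility
from foodsift.sift import (
    PRESETS,
    SiftParameters,
    candidate_pool,
    filter_fuzzy_optimization,
    filter_macros,
    filter_min_fuzzy,
    filter_secondary,
    filter_sodium,
    get_preset,
    run_sift,
)

from _instances import random_instance
from _oracles import oracle_sift


class TestPresets:
    def test_table_of_presets(self):
        first = PRESETS["first"]
        assert (first.macro_threshold, first.secondary_threshold) == (20.0, 10.0)
        assert first.sodium_threshold == 0.5
        assert not first.use_min_fuzzy and first.use_fuzzy_optimization

        plus = PRESETS["first_plus"]
        assert (plus.macro_threshold, plus.secondary_threshold) == (60.0, 60.0)
        assert plus.min_fuzzy_score == 50 and plus.use_min_fuzzy
        assert not plus.use_fuzzy_optimization

        second = PRESETS["second"]
        assert (second.macro_threshold, second.secondary_threshold) == (40.0, 40.0)

        third = PRESETS["third"]
        assert math.isinf(third.macro_threshold)
        assert math.isinf(third.secondary_threshold)
        assert math.isinf(third.sodium_threshold)
        assert third.use_fuzzy_optimization

    def test_inf_sentinel_parsed_from_config(self):
        p = SiftParameters.from_dict(
            {"name": "x", "macro_threshold": "inf", "secondary_threshold": 10,
             "sodium_threshold": "0.5"}
        )
        assert math.isinf(p.macro_threshold)
        assert p.sodium_threshold == 0.5

    def test_unknown_preset_is_config_error(self):
        with pytest.raises(ConfigError):
            get_preset("fourth")

    def test_required_fields_follow_thresholds(self):
        assert set(PRESETS["third"].required_fields()) == {"energy"}
        assert set(PRESETS["first"].required_fields()) == {
            "energy", "carbohydrate", "protein", "total_fat", "fiber",
            "saturated_fat", "sugar", "sodium",
        }


class TestBlocking:
    def test_pool_is_shared_group_only(self, toy_product, toy_reference):
        pool = candidate_pool(toy_product, toy_reference)
        assert {f.food_id for f in pool} == {"X", "Y"}

    def test_unknown_group_gives_empty_pool(self, toy_product, toy_reference):
        lonely = dataclasses.replace(toy_product, blocking_group="G9")
        assert candidate_pool(lonely, toy_reference) == []

    def test_blocking_disabled_returns_everything(self, toy_product, toy_reference):
        pool = candidate_pool(toy_product, toy_reference, blocking=False)
        assert len(pool) == 3


class TestFilters:
    def test_infinite_threshold_keeps_all(self, toy_product, toy_reference):
        assert filter_macros(toy_product, toy_reference, math.inf) == toy_reference
        assert filter_secondary(toy_product, toy_reference, math.inf) == toy_reference
        assert filter_sodium(toy_product, toy_reference, math.inf) == toy_reference

    def test_macro_filter_removes_breaching_food(self, toy_product, toy_reference):
        # food Y: carb 75 g at 400 kcal -> 75 pp vs the product's 50 pp
        kept = filter_macros(toy_product, toy_reference[:2], 20.0)
        assert [f.food_id for f in kept] == ["X"]

    def test_boundary_is_strict(self, toy_product, toy_reference):
        # exact 25 pp carbohydrate difference removed at threshold 25
        kept = filter_macros(toy_product, toy_reference[:2], 25.0)
        assert [f.food_id for f in kept] == ["X"]
        kept = filter_macros(toy_product, toy_reference[:2], 25.0 + 1e-9)
        assert [f.food_id for f in kept] == ["X", "Y"]

    def test_sodium_filter(self, toy_product, toy_reference):
        import dataclasses as dc

        from foodsift.model import NutrientProfile

        def with_sodium(food, mg):
            return dc.replace(
                food, profile=dc.replace(food.profile, sodium=mg)
            )

        near = with_sodium(toy_reference[0], 300 * 1.4)  # rel diff 0.4
        far = with_sodium(toy_reference[1], 300 * 3.0)  # rel diff 2.0
        kept = filter_sodium(toy_product, [near, far], 0.5)
        assert [f.food_id for f in kept] == ["X"]

    def test_zero_sodium_product_skips_filter(self, toy_product, toy_reference):
        import dataclasses as dc

        zero = dc.replace(
            toy_product, profile=dc.replace(toy_product.profile, sodium=0.0)
        )
        assert filter_sodium(zero, toy_reference, 0.5) == toy_reference

    def test_min_fuzzy_meets_or_exceeds(self, toy_product, toy_reference):
        scores = {"X": 50, "Y": 49, "Z": 100}
        kept = filter_min_fuzzy(toy_product, toy_reference, 50, scores=scores)
        assert {f.food_id for f in kept} == {"X", "Z"}
        kept = filter_min_fuzzy(
            toy_product, toy_reference, 50, strict=True, scores=scores
        )
        assert {f.food_id for f in kept} == {"Z"}

    def test_fuzzy_optimization_keeps_all_ties(self, toy_product, toy_reference):
        scores = {"X": 80, "Y": 80, "Z": 40}
        kept = filter_fuzzy_optimization(toy_product, toy_reference, scores=scores)
        assert {f.food_id for f in kept} == {"X", "Y"}
        assert filter_fuzzy_optimization(toy_product, []) == []


class TestRunSift:
    def test_toy_fixture_first_preset(self, toy_product, toy_reference):
        matches = run_sift(toy_product, toy_reference, PRESETS["first"])
        assert [m.food_id for m in matches] == ["X"]
        assert matches[0].max_diff == pytest.approx(0.0)
        assert matches[0].fuzzy_score == 100
        assert matches[0].sift_name == "first"

    def test_all_inf_no_optimization_returns_whole_pool(
        self, toy_product, toy_reference
    ):
        params = SiftParameters(
            name="open", macro_threshold=math.inf, secondary_threshold=math.inf,
            sodium_threshold=math.inf, use_fuzzy_optimization=False,
        )
        matches = run_sift(toy_product, toy_reference, params)
        assert {m.food_id for m in matches} == {"X", "Y"}

    def test_third_preset_keeps_fuzzy_argmax_only(self, toy_product, toy_reference):
        matches = run_sift(toy_product, toy_reference, PRESETS["third"])
        # X's name token-sorts to the product's tokens; Y shares one token
        assert {m.food_id for m in matches} == {"X"}

    def test_ineligible_product_is_usage_error(self, toy_product, toy_reference):
        import dataclasses as dc

        bad = dc.replace(
            toy_product,
            profile=dc.replace(toy_product.profile, energy=0.0),
            eligible=False,
        )
        with pytest.raises(UsageError):
            run_sift(bad, toy_reference, PRESETS["first"])

    def test_self_match_guarantee(self, toy_product, toy_reference):
        """A same-group food with the product's exact profile and name
        always survives any preset with positive thresholds."""
        import dataclasses as dc

        twin = dc.replace(
            toy_reference[0], name=toy_product.name
        )
        reference = [twin] + toy_reference[1:]
        for preset in PRESETS.values():
            matches = run_sift(toy_product, reference, preset)
            assert "X" in {m.food_id for m in matches}, preset.name


class TestOracleEquivalence:
    def test_run_sift_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(400):
            product_d, pool_d, params_d, product, foods, params = random_instance(rng)
            expected = oracle_sift(
                product_d, pool_d, params_d,
                dataclasses.asdict(DEFAULT_FACTORS),
            )
            got = {m.food_id for m in run_sift(product, foods, params)}
            assert got == expected


class TestMonotonicity:
    def test_larger_thresholds_never_shrink_output(self):
        """With fuzzy optimization off, raising any threshold (or lowering
        the fuzzy floor) can only grow the suggestion set."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            *_, product, foods, params = random_instance(rng)
            params = dataclasses.replace(params, use_fuzzy_optimization=False)
            base = {m.food_id for m in run_sift(product, foods, params)}
            widened = dataclasses.replace(
                params,
                macro_threshold=params.macro_threshold * 2 + 1,
                secondary_threshold=params.secondary_threshold * 2 + 1,
                sodium_threshold=params.sodium_threshold * 2 + 1,
                min_fuzzy_score=params.min_fuzzy_score // 2,
            )
            grown = {m.food_id for m in run_sift(product, foods, widened)}
            assert base <= grown

    def test_each_filter_returns_subset(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            *_, product, foods, params = random_instance(rng)
            out = {m.food_id for m in run_sift(product, foods, params)}
            pool = {f.food_id for f in candidate_pool(product, foods)}
            assert out <= pool
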