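import dataclasses
import math

import pytest

from foodsift.exceptions import ConfigError
from foodsift.model import (
    LinkageDataset,
    NutrientProfile,
    ProductRecord,
    ReferenceFoodRecord,
)
from foodsift.schedule import (
    LEVEL_MANY,
    LEVEL_SINGLE,
    LEVEL_ZERO,
    ROUTE_ALGORITHM,
    ROUTE_DIRECT_MANUAL,
    SiftSchedule,
    default_schedule,
    flow_summary,
    match_level,
    run_schedule,
)
from foodsift.sift import PRESETS, SiftParameters
from foodsift.simulate import GeneratorConfig, generate


class TestMatchLevel:
    @pytest.mark.parametrize(
        "n, level", [(0, LEVEL_ZERO), (1, LEVEL_SINGLE), (2, LEVEL_MANY), (7, LEVEL_MANY)]
    )
    def test_by_count(self, n, level):
        assert match_level(list(range(n))) == level


class TestScheduleConfig:
    def test_default_schedule_shape(self):
        s = default_schedule()
        assert s.initial.name == "first"
        assert [p.name for p in s.zero_match_chain] == ["second", "third"]
        assert s.augmentation.name == "first_plus"
        assert s.augmentation_mode == "replace"

    def test_from_dict_with_preset_names(self):
        s = SiftSchedule.from_dict(
            {"initial": "first", "zero_match_chain": ["second"], "augmentation": None}
        )
        assert s.initial == PRESETS["first"]
        assert s.augmentation is None

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError):
            SiftSchedule.from_dict({"initial": "first", "zero_match_chain": ["first"]})

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            SiftSchedule.from_dict({"initial": "zeroth"})


def _identity_dataset(n=4):
    """Every product equals the sole reference food of its blocking group,
    by name and by profile (name overridden to match exactly)."""
    products, reference = [], []
    for i in range(n):
        profile = NutrientProfile(
            energy=300.0 + 10 * i, carbohydrate=30.0 + i, protein=10.0,
            total_fat=12.0, saturated_fat=4.0, sugar=15.0, fiber=3.0,
            sodium=200.0 + 50 * i,
        )
        name = f"food number {i}"
        reference.append(ReferenceFoodRecord(f"F{i}", name, f"G{i}", profile))
        products.append(
            ProductRecord(
                product_id=f"P{i}", subcategory="x", brand="y",
                blocking_group=f"G{i}", profile=profile, name=name,
            )
        )
    return LinkageDataset(products=products, reference=reference)


class TestRunSchedule:
    def test_identity_dataset_all_level_one(self):
        """Exact twins survive the initial sift, and the augmentation sift
        retains them (zero differences, fuzzy 100 >= 50)."""
        report = run_schedule(_identity_dataset(), default_schedule())
        for pid, outcome in report.outcomes.items():
            assert outcome.route == ROUTE_ALGORITHM
            assert outcome.level == LEVEL_SINGLE
            assert outcome.provenance == "first_plus"
            assert outcome.suggestions[0].food_id == "F" + pid[1:]

    def test_augmentation_only_loss(self):
        """A product whose sole initial suggestion fails the augmentation
        fuzzy floor ends at level zero despite once having had a match."""
        profile = NutrientProfile(
            energy=300.0, carbohydrate=30.0, protein=10.0, total_fat=12.0,
            saturated_fat=4.0, sugar=15.0, fiber=3.0, sodium=200.0,
        )
        dataset = LinkageDataset(
            products=[
                ProductRecord(
                    product_id="P1", subcategory="qqqq", brand="wwww",
                    blocking_group="G1", profile=profile,
                )
            ],
            reference=[ReferenceFoodRecord("F1", "xyzzy", "G1", profile)],
        )
        schedule = SiftSchedule(
            initial=PRESETS["first"], augmentation=PRESETS["first_plus"]
        )
        report = run_schedule(dataset, schedule)
        outcome = report.outcomes["P1"]
        assert outcome.level == LEVEL_ZERO
        assert outcome.provenance == "first_plus"
        assert outcome.suggestions == []

    def test_retain_fallback_keeps_original_single_match(self):
        profile = NutrientProfile(
            energy=300.0, carbohydrate=30.0, protein=10.0, total_fat=12.0,
            saturated_fat=4.0, sugar=15.0, fiber=3.0, sodium=200.0,
        )
        dataset = LinkageDataset(
            products=[
                ProductRecord(
                    product_id="P1", subcategory="qqqq", brand="wwww",
                    blocking_group="G1", profile=profile,
                )
            ],
            reference=[ReferenceFoodRecord("F1", "xyzzy", "G1", profile)],
        )
        schedule = SiftSchedule(
            initial=PRESETS["first"],
            augmentation=PRESETS["first_plus"],
            augmentation_mode="retain_fallback",
        )
        outcome = run_schedule(dataset, schedule).outcomes["P1"]
        assert outcome.level == LEVEL_SINGLE
        assert outcome.suggestions[0].food_id == "F1"

    def test_degenerate_all_inf_single_sift(self):
        """With every filter disabled the level is just the blocking-pool
        size classification."""
        dataset = _identity_dataset(4)
        open_params = SiftParameters(
            name="open", macro_threshold=math.inf, secondary_threshold=math.inf,
            sodium_threshold=math.inf, use_fuzzy_optimization=False,
        )
        report = run_schedule(dataset, SiftSchedule(initial=open_params))
        for pid, outcome in report.outcomes.items():
            pool = sum(
                1
                for f in dataset.reference
                if f.blocking_group
                == next(
                    p.blocking_group
                    for p in dataset.products
                    if p.product_id == pid
                )
            )
            assert outcome.level == match_level(range(pool))

    def test_ineligible_products_routed_direct_to_manual(self):
        dataset = _identity_dataset(3)
        zero_energy = dataclasses.replace(
            dataset.products[0],
            profile=dataclasses.replace(dataset.products[0].profile, energy=0.0),
        )
        dataset = LinkageDataset(
            products=[zero_energy] + dataset.products[1:],
            reference=dataset.reference,
        )
        report = run_schedule(dataset, default_schedule())
        outcome = report.outcomes["P0"]
        assert outcome.route == ROUTE_DIRECT_MANUAL
        assert outcome.level is None
        assert outcome.exclusion_reason == "zero_energy"

    def test_conservation_and_partition_on_synthetic_run(self):
        dataset, _ = generate(GeneratorConfig(seed=11, perturbation=0.15))
        report = run_schedule(dataset, default_schedule())
        for flow in report.flows:
            assert flow.entered == flow.out_zero + flow.out_single + flow.out_many
        n_algo = sum(
            1 for o in report.outcomes.values() if o.route == ROUTE_ALGORITHM
        )
        n_manual = sum(
            1 for o in report.outcomes.values() if o.route == ROUTE_DIRECT_MANUAL
        )
        assert n_algo + n_manual == len(dataset.products)
        assert set(report.outcomes) == {p.product_id for p in dataset.products}

    def test_determinism(self):
        dataset, _ = generate(GeneratorConfig(seed=5))
        r1 = run_schedule(dataset, default_schedule())
        r2 = run_schedule(dataset, default_schedule())
        assert r1.to_frame().equals(r2.to_frame())
        assert flow_summary(r1).equals(flow_summary(r2))


class TestFlowSummary:
    def test_empty_dataset(self):
        report = run_schedule(
            LinkageDataset(products=[], reference=[]), default_schedule()
        )
        df = flow_summary(report)
        assert (df[["out_zero", "out_single", "out_many"]].sum().sum()) == 0

    def test_single_product_visits(self):
        dataset = _identity_dataset(1)
        report = run_schedule(dataset, default_schedule())
        df = flow_summary(report)
        assert df.loc[df.sift_name == "first", "entered"].item() == 1
        assert df.loc[df.sift_name == "first_plus", "entered"].item() == 1
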