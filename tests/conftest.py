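import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from foodsift.metrics import EnergyFactors
from foodsift.model import (
    LinkageDataset,
    NutrientProfile,
    ProductRecord,
    ReferenceFoodRecord,
)


@pytest.fixture
def factors():
    return EnergyFactors()


@pytest.fixture
def toy_product():
    """A 400 kcal product; proportions of calories: carb 50, protein 10,
    fat 33.75, satfat 11.25, sugar 20, fiber 2.5 (default factors)."""
    return ProductRecord(
        product_id="P1",
        subcategory="crunchy oat cereal",
        brand="zenith",
        blocking_group="G1",
        profile=NutrientProfile(
            energy=400.0,
            carbohydrate=50.0,
            protein=10.0,
            total_fat=15.0,
            saturated_fat=5.0,
            sugar=20.0,
            fiber=5.0,
            sodium=300.0,
        ),
        eligible=True,
    )


@pytest.fixture
def toy_reference(toy_product):
    """Food X mirrors the product exactly; food Y shifts carbohydrate to
    75 g (a 25 pp proportion-of-calories difference at equal energy -- no,
    energy differs too, see test for the exact value); food Z lives in
    another blocking group."""
    identical = toy_product.profile
    return [
        ReferenceFoodRecord("X", "cereal, oat, crunchy", "G1", identical),
        ReferenceFoodRecord(
            "Y",
            "cereal, wheat",
            "G1",
            NutrientProfile(
                energy=400.0,
                carbohydrate=75.0,
                protein=10.0,
                total_fat=15.0,
                saturated_fat=5.0,
                sugar=20.0,
                fiber=5.0,
                sodium=300.0,
            ),
        ),
        ReferenceFoodRecord("Z", "soup, tomato", "G2", identical),
    ]


@pytest.fixture
def toy_dataset(toy_product, toy_reference):
    return LinkageDataset(products=[toy_product], reference=toy_reference)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_profile(energy=100.0, carb=10.0, protein=5.0, fat=3.0, satfat=1.0,
                 sugar=4.0, fiber=2.0, sodium=100.0):
    return NutrientProfile(
        energy=energy, carbohydrate=carb, protein=protein, total_fat=fat,
        saturated_fat=satfat, sugar=sugar, fiber=fiber, sodium=sodium,
    )
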