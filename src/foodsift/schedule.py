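"""Multi-sift routing: the sift schedule and the match report.

Products flow through an ordered plan of sifts. Every eligible product
enters the *initial* sift and lands at one of three match levels by
suggestion count: zero, single, or multiple (>= 2). Products at level zero
are re-run through a *zero-match chain* of successively looser sifts until
they gain a suggestion or the chain is exhausted. Products that the initial
sift left with exactly one suggestion may be re-run through an optional
*augmentation* sift (looser nutrient thresholds plus a minimum fuzzy
score): its output **replaces** the original single suggestion, even when it
is empty — so a product can end at level zero despite once having had a
match, whenever its lone suggestion's name similarity fails the fuzzy
floor. Single-match products of chain sifts are final and are not
augmented. Ineligible products are routed directly to manual matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import ConfigError, ValidationError
from .metrics import DEFAULT_FACTORS, EnergyFactors, rank_candidates
from .model import LinkageDataset, ProductRecord, screen_eligibility
from .sift import PRESETS, CandidateMatch, SiftParameters, get_preset, run_sift

#: Match levels: 0, 1, and "many" (>= 2), encoded as 0 / 1 / 2.
LEVEL_ZERO = 0
LEVEL_SINGLE = 1
LEVEL_MANY = 2

#: Eligibility routes.
ROUTE_ALGORITHM = "algorithm"
ROUTE_DIRECT_MANUAL = "direct_manual"


def match_level(suggestions: Sequence) -> int:
    """Classify a suggestion set by count: 0, 1, or many (encoded 2)."""
    n = len(suggestions)
    return LEVEL_MANY if n >= 2 else n


@dataclass(frozen=True)
class SiftSchedule:
    """An ordered routing plan across sifts."""

    initial: SiftParameters
    zero_match_chain: tuple[SiftParameters, ...] = ()
    augmentation: Optional[SiftParameters] = None
    augmentation_mode: str = "replace"  # "replace" | "retain_fallback"

    def __post_init__(self) -> None:
        names = [self.initial.name] + [p.name for p in self.zero_match_chain]
        if self.augmentation is not None:
            names.append(self.augmentation.name)
        if len(names) != len(set(names)):
            raise ConfigError(f"sift names must be unique in a schedule: {names}")
        if self.augmentation_mode not in {"replace", "retain_fallback"}:
            raise ConfigError(
                f"augmentation_mode must be 'replace' or 'retain_fallback', "
                f"got {self.augmentation_mode!r}"
            )

    def all_sifts(self) -> tuple[SiftParameters, ...]:
        sifts = (self.initial,) + self.zero_match_chain
        if self.augmentation is not None:
            sifts += (self.augmentation,)
        return sifts

    def required_fields(self) -> tuple[str, ...]:
        """Union of profile fields any sift in the schedule needs."""
        fields: list[str] = []
        for p in self.all_sifts():
            for f in p.required_fields():
                if f not in fields:
                    fields.append(f)
        return tuple(fields)

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SiftSchedule":
        def resolve(entry: object) -> SiftParameters:
            if isinstance(entry, str):
                return get_preset(entry)
            if isinstance(entry, Mapping):
                return SiftParameters.from_dict(entry)
            raise ConfigError(f"sift entry must be a preset name or mapping: {entry!r}")

        if "initial" not in d:
            raise ConfigError("schedule requires an 'initial' sift")
        chain = tuple(resolve(e) for e in d.get("zero_match_chain", []))  # type: ignore[union-attr]
        aug = d.get("augmentation")
        return cls(
            initial=resolve(d["initial"]),
            zero_match_chain=chain,
            augmentation=resolve(aug) if aug is not None else None,
            augmentation_mode=str(d.get("augmentation_mode", "replace")),
        )

    @classmethod
    def from_yaml(cls, path) -> "SiftSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_schedule() -> SiftSchedule:
    """The reference four-sift plan: first -> (second, third) for
    zero-match products, first_plus augmentation for first's single
    matches."""
    return SiftSchedule(
        initial=PRESETS["first"],
        zero_match_chain=(PRESETS["second"], PRESETS["third"]),
        augmentation=PRESETS["first_plus"],
    )


@dataclass(frozen=True)
class SiftFlow:
    """Per-sift bookkeeping: how many products entered and at which level
    they left. Conservation: entered == out_zero + out_single + out_many."""

    sift_name: str
    entered: int
    out_zero: int
    out_single: int
    out_many: int


@dataclass
class ProductOutcome:
    """Final state of one product after the whole schedule."""

    product_id: str
    route: str  # ROUTE_ALGORITHM | ROUTE_DIRECT_MANUAL
    level: Optional[int]  # None for direct-to-manual products
    suggestions: list[CandidateMatch] = field(default_factory=list)
    provenance: Optional[str] = None  # sift that produced the final set
    exclusion_reason: Optional[str] = None


@dataclass
class MatchReport:
    """Outcome of a schedule run: per-product results plus per-sift flows."""

    outcomes: dict[str, ProductOutcome]
    flows: list[SiftFlow]
    schedule: SiftSchedule

    def products_at_level(self, level: int) -> list[str]:
        return [
            pid
            for pid, o in self.outcomes.items()
            if o.route == ROUTE_ALGORITHM and o.level == level
        ]

    def to_frame(self) -> pd.DataFrame:
        """One row per (product, ranked candidate); suggestion-less and
        direct-to-manual products appear as single rows with empty food_id."""
        rows = []
        for pid in sorted(self.outcomes):
            o = self.outcomes[pid]
            if not o.suggestions:
                rows.append(
                    {
                        "product_id": pid,
                        "route": o.route,
                        "level": o.level if o.level is not None else "",
                        "rank": "",
                        "food_id": "",
                        "food_name": "",
                        "sift_name": o.provenance or "",
                        "max_diff": "",
                        "fuzzy_score": "",
                        "exclusion_reason": o.exclusion_reason or "",
                    }
                )
                continue
            for rank, c in enumerate(o.suggestions, start=1):
                d = c.differences
                rows.append(
                    {
                        "product_id": pid,
                        "route": o.route,
                        "level": o.level,
                        "rank": rank,
                        "food_id": c.food_id,
                        "food_name": c.food_name,
                        "sift_name": c.sift_name,
                        "max_diff": c.max_diff,
                        "fuzzy_score": c.fuzzy_score,
                        "exclusion_reason": "",
                        "d_carb_pp": d.carbohydrate,
                        "d_prot_pp": d.protein,
                        "d_fat_pp": d.total_fat,
                        "d_fiber_pp": d.fiber,
                        "d_satfat_pp": d.saturated_fat,
                        "d_sugar_pp": d.sugar,
                        "d_sodium_rel": d.sodium_rel,
                    }
                )
        return pd.DataFrame(rows)


def run_schedule(
    dataset: LinkageDataset,
    schedule: Optional[SiftSchedule] = None,
    factors: EnergyFactors = DEFAULT_FACTORS,
    blocking: bool = True,
) -> MatchReport:
    """Route every product of the dataset through the schedule.

    Ineligible products (zero energy, or missing any field the schedule's
    sifts need) go directly to manual. Eligible products run the initial
    sift; zero-match products walk the chain; the initial sift's
    single-match products run the augmentation sift, whose output replaces
    the prior suggestion (in ``retain_fallback`` mode an empty augmentation
    result falls back to the original single match instead). Final
    suggestion sets are ranked by ascending maximal nutritional difference.
    """
    schedule = schedule or default_schedule()
    eligible, excluded, reasons = screen_eligibility(
        dataset.products, schedule.required_fields()
    )
    outcomes: dict[str, ProductOutcome] = {}
    for p in excluded:
        outcomes[p.product_id] = ProductOutcome(
            product_id=p.product_id,
            route=ROUTE_DIRECT_MANUAL,
            level=None,
            exclusion_reason=p.exclusion_reason,
        )

    flows: list[SiftFlow] = []

    def _run_batch(
        batch: list[ProductRecord], params: SiftParameters
    ) -> dict[str, list[CandidateMatch]]:
        results = {}
        counts = {LEVEL_ZERO: 0, LEVEL_SINGLE: 0, LEVEL_MANY: 0}
        for p in batch:
            matches = run_sift(p, dataset.reference, params, factors, blocking)
            results[p.product_id] = matches
            counts[match_level(matches)] += 1
        flows.append(
            SiftFlow(
                sift_name=params.name,
                entered=len(batch),
                out_zero=counts[LEVEL_ZERO],
                out_single=counts[LEVEL_SINGLE],
                out_many=counts[LEVEL_MANY],
            )
        )
        return results

    by_id = {p.product_id: p for p in eligible}
    initial_results = _run_batch(eligible, schedule.initial)

    final: dict[str, list[CandidateMatch]] = {}
    provenance: dict[str, str] = {}
    zero_pool: list[ProductRecord] = []
    augment_pool: list[ProductRecord] = []
    for pid, matches in initial_results.items():
        level = match_level(matches)
        if level == LEVEL_ZERO:
            zero_pool.append(by_id[pid])
        elif level == LEVEL_SINGLE and schedule.augmentation is not None:
            augment_pool.append(by_id[pid])
        else:
            final[pid] = matches
            provenance[pid] = schedule.initial.name
    for params in schedule.zero_match_chain:
        if not zero_pool:
            break
        results = _run_batch(zero_pool, params)
        still_zero = []
        for p in zero_pool:
            matches = results[p.product_id]
            if match_level(matches) == LEVEL_ZERO:
                still_zero.append(p)
            else:
                final[p.product_id] = matches
                provenance[p.product_id] = params.name
        zero_pool = still_zero
    for p in zero_pool:  # chain exhausted without a match
        final[p.product_id] = []
        provenance[p.product_id] = (
            schedule.zero_match_chain[-1].name
            if schedule.zero_match_chain
            else schedule.initial.name
        )

    if schedule.augmentation is not None and augment_pool:
        results = _run_batch(augment_pool, schedule.augmentation)
        for p in augment_pool:
            matches = results[p.product_id]
            if not matches and schedule.augmentation_mode == "retain_fallback":
                matches = initial_results[p.product_id]
                provenance[p.product_id] = schedule.initial.name
            else:
                provenance[p.product_id] = schedule.augmentation.name
            final[p.product_id] = matches

    for pid, matches in final.items():
        ranked = rank_candidates(matches)
        outcomes[pid] = ProductOutcome(
            product_id=pid,
            route=ROUTE_ALGORITHM,
            level=match_level(ranked),
            suggestions=ranked,
            provenance=provenance[pid],
        )

    missing = set(p.product_id for p in dataset.products) - set(outcomes)
    if missing:  # defensive: partition must be exhaustive
        raise ValidationError(f"products lost in routing: {sorted(missing)}")
    return MatchReport(outcomes=outcomes, flows=flows, schedule=schedule)


def flow_summary(report: MatchReport) -> pd.DataFrame:
    """Per-sift table of entered / level-0 / level-1 / level-many counts."""
    return pd.DataFrame(
        [
            {
                "sift_name": f.sift_name,
                "entered": f.entered,
                "out_zero": f.out_zero,
                "out_single": f.out_single,
                "out_many": f.out_many,
            }
            for f in report.flows
        ],
        columns=["sift_name", "entered", "out_zero", "out_single", "out_many"],
    )
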