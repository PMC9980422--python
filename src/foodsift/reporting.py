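"""Adjudication bookkeeping and agreement / accuracy statistics.

The toolkit never chooses a final match itself — that judgment belongs to
human experts — but it keeps the books: decision logs for two independent
raters at the algorithm and manual stages, plain percent inter-rater
agreement rates, algorithm accuracy by reporting category and match level,
whole-process accuracy, and the threshold-sweep diagnostic used to choose
nutrient thresholds.

Two agreement rates are computed at the algorithm stage:

* *selection agreement* — both raters returned the identical verdict
  (same food chosen, or both refused every suggestion);
* *manual-needed agreement* — both raters agreed on the refuse-vs-select
  dichotomy, regardless of which food each selected.

Identical verdicts imply dichotomy agreement, so the second rate always
dominates the first; this inequality is a structural property of the
definitions, not an empirical finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, ValidationError
from .metrics import DEFAULT_FACTORS, EnergyFactors
from .model import LinkageDataset, screen_eligibility
from .schedule import LEVEL_MANY, LEVEL_SINGLE, MatchReport, ROUTE_ALGORITHM
from .sift import (
    SiftParameters,
    candidate_pool,
    filter_macros,
    filter_secondary,
    filter_sodium,
)

#: Verdict sentinels.
REFUSE = "REFUSE"  # algorithm stage: reject all suggested matches
UNMATCHABLE = "UNMATCHABLE"  # manual stage: no reference equivalent exists

STAGE_ALGORITHM = "algorithm"
STAGE_MANUAL = "manual"


@dataclass(frozen=True)
class RaterDecision:
    """One expert's verdict on one product at one stage.

    ``verdict`` is a food id, or :data:`REFUSE` (algorithm stage) /
    :data:`UNMATCHABLE` (manual stage). ``resolution_round`` 0 is the
    independent pass; higher rounds record third-rater / consensus
    resolution without automating it.
    """

    product_id: str
    rater_id: str
    stage: str
    verdict: str
    resolution_round: int = 0

    def __post_init__(self) -> None:
        if self.stage not in {STAGE_ALGORITHM, STAGE_MANUAL}:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.stage == STAGE_ALGORITHM and self.verdict == UNMATCHABLE:
            raise ValidationError("UNMATCHABLE is a manual-stage verdict")
        if self.stage == STAGE_MANUAL and self.verdict == REFUSE:
            raise ValidationError("REFUSE is an algorithm-stage verdict")


def load_decisions(path: str | Path) -> list[RaterDecision]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"product_id", "rater_id", "stage", "verdict"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"decision log missing columns {sorted(missing)}")
    return [
        RaterDecision(
            product_id=row["product_id"],
            rater_id=row["rater_id"],
            stage=row["stage"],
            verdict=row["verdict"],
            resolution_round=int(row.get("resolution_round", "0") or 0),
        )
        for _, row in df.iterrows()
    ]


def write_decisions(decisions: Iterable[RaterDecision], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "product_id": d.product_id,
                "rater_id": d.rater_id,
                "stage": d.stage,
                "verdict": d.verdict,
                "resolution_round": d.resolution_round,
            }
            for d in decisions
        ]
    ).to_csv(path, index=False)


def round1(x: float) -> float:
    """Round half-up to one decimal place (report-table convention)."""
    return math.floor(x * 10 + 0.5) / 10


def _paired_verdicts(
    decisions: Iterable[RaterDecision], stage: str
) -> list[tuple[str, str]]:
    staged = [d for d in decisions if d.stage == stage and d.resolution_round == 0]
    raters = sorted({d.rater_id for d in staged})
    if len(raters) != 2:
        raise ValidationError(
            f"agreement rates need exactly two raters at stage {stage!r}, "
            f"got {raters}"
        )
    by_product: dict[str, dict[str, str]] = {}
    for d in staged:
        slot = by_product.setdefault(d.product_id, {})
        if d.rater_id in slot:
            raise ValidationError(
                f"product {d.product_id}: multiple round-0 decisions by "
                f"rater {d.rater_id}"
            )
        slot[d.rater_id] = d.verdict
    if not by_product:
        raise ValidationError(f"no decisions at stage {stage!r}")
    pairs = []
    for pid in sorted(by_product):
        slot = by_product[pid]
        if set(slot) != set(raters):
            raise ValidationError(f"product {pid}: missing a rater's decision")
        pairs.append((slot[raters[0]], slot[raters[1]]))
    return pairs


def agreement_selection(decisions: Iterable[RaterDecision]) -> float:
    """Percent of products where both raters' algorithm-stage verdicts are
    identical (same food, or both refusing)."""
    pairs = _paired_verdicts(decisions, STAGE_ALGORITHM)
    agree = sum(1 for a, b in pairs if a == b)
    return 100.0 * agree / len(pairs)


def agreement_manual_needed(decisions: Iterable[RaterDecision]) -> float:
    """Percent of products where both raters agreed on refuse-vs-select."""
    pairs = _paired_verdicts(decisions, STAGE_ALGORITHM)
    agree = sum(1 for a, b in pairs if (a == REFUSE) == (b == REFUSE))
    return 100.0 * agree / len(pairs)


def agreement_manual_selection(decisions: Iterable[RaterDecision]) -> float:
    """Percent of products where both raters picked the same manual-stage
    equivalent (UNMATCHABLE counts as a verdict)."""
    pairs = _paired_verdicts(decisions, STAGE_MANUAL)
    agree = sum(1 for a, b in pairs if a == b)
    return 100.0 * agree / len(pairs)


def cohens_kappa(decisions: Iterable[RaterDecision], stage: str) -> float:
    """Chance-corrected agreement (optional extra; the primary statistics
    are the plain percent rates above)."""
    pairs = _paired_verdicts(decisions, stage)
    n = len(pairs)
    po = sum(1 for a, b in pairs if a == b) / n
    labels = sorted({v for pair in pairs for v in pair})
    pa = {v: sum(1 for a, _ in pairs if a == v) / n for v in labels}
    pb = {v: sum(1 for _, b in pairs if b == v) / n for v in labels}
    pe = sum(pa[v] * pb[v] for v in labels)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


@dataclass(frozen=True)
class CategoryRollup:
    """Total mapping from product subcategory to a reporting category."""

    mapping: Mapping[str, str]

    def category(self, subcategory: str) -> str:
        try:
            return self.mapping[subcategory]
        except KeyError:
            raise ValidationError(
                f"subcategory {subcategory!r} has no reporting category"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryRollup":
        df = pd.read_csv(path, dtype=str)
        if not {"subcategory", "category"} <= set(df.columns):
            raise ValidationError("rollup CSV needs 'subcategory' and 'category'")
        return cls(mapping=dict(zip(df["subcategory"], df["category"])))

    @classmethod
    def identity(cls, subcategories: Iterable[str]) -> "CategoryRollup":
        return cls(mapping={s: s for s in subcategories})


def algorithm_accuracy(
    report: MatchReport,
    adjudications: Mapping[str, str],
    rollup: CategoryRollup,
    subcategories: Mapping[str, str],
) -> pd.DataFrame:
    """Accuracy of the algorithm's suggestions, by category and match level.

    ``adjudications`` maps every product with at least one suggestion to the
    expert-accepted food id or :data:`REFUSE`; a product counts as accurate
    when the accepted food is among its suggestions (an accepted food *not*
    among them is an integrity error). ``subcategories`` maps product ids to
    their subcategory for the rollup. Returns per-(category, level) rows
    plus per-category and overall totals; rates are percentages rounded to
    one decimal.
    """
    rows = []
    for pid, outcome in report.outcomes.items():
        if outcome.route != ROUTE_ALGORITHM or not outcome.suggestions:
            continue
        if pid not in adjudications:
            raise ValidationError(f"product {pid} lacks a final adjudication")
        verdict = adjudications[pid]
        suggested = {c.food_id for c in outcome.suggestions}
        if verdict != REFUSE and verdict not in suggested:
            raise IntegrityError(
                f"product {pid}: adjudicated food {verdict!r} is not among "
                f"its suggestions"
            )
        rows.append(
            {
                "category": rollup.category(subcategories[pid]),
                "level": "many" if outcome.level == LEVEL_MANY else "single",
                "accurate": verdict != REFUSE,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["category", "level", "n", "n_accurate", "accuracy_pct"]
        )
    df = pd.DataFrame(rows)
    out = []
    for (category, level), grp in df.groupby(["category", "level"], sort=True):
        out.append(
            {
                "category": category,
                "level": level,
                "n": len(grp),
                "n_accurate": int(grp["accurate"].sum()),
            }
        )
    for category, grp in df.groupby("category", sort=True):
        out.append(
            {
                "category": category,
                "level": "all",
                "n": len(grp),
                "n_accurate": int(grp["accurate"].sum()),
            }
        )
    for level_label in ("single", "many"):
        grp = df[df["level"] == level_label]
        if len(grp):
            out.append(
                {
                    "category": "OVERALL",
                    "level": level_label,
                    "n": len(grp),
                    "n_accurate": int(grp["accurate"].sum()),
                }
            )
    out.append(
        {
            "category": "OVERALL",
            "level": "all",
            "n": len(df),
            "n_accurate": int(df["accurate"].sum()),
        }
    )
    result = pd.DataFrame(out)
    result["accuracy_pct"] = [
        round1(100.0 * a / n) for a, n in zip(result["n_accurate"], result["n"])
    ]
    return result


def process_accuracy(
    outcomes: Mapping[str, str],
    subcategories: Mapping[str, str],
    rollup: CategoryRollup,
) -> pd.DataFrame:
    """Whole-process accuracy: per category, how many products ended with a
    reference match (by algorithm or manual selection) vs. unmatchable.

    ``outcomes`` maps every product id to a terminal outcome: a matched
    food id or :data:`UNMATCHABLE`.
    """
    missing = set(subcategories) - set(outcomes)
    if missing:
        raise ValidationError(
            f"products without terminal outcome: {sorted(missing)[:5]}..."
        )
    rows = [
        {
            "category": rollup.category(subcategories[pid]),
            "matched": outcomes[pid] != UNMATCHABLE,
        }
        for pid in subcategories
    ]
    df = pd.DataFrame(rows)
    out = []
    for category, grp in df.groupby("category", sort=True):
        out.append(
            {
                "category": category,
                "n": len(grp),
                "n_matched": int(grp["matched"].sum()),
                "n_unmatchable": int((~grp["matched"]).sum()),
            }
        )
    out.append(
        {
            "category": "OVERALL",
            "n": len(df),
            "n_matched": int(df["matched"].sum()),
            "n_unmatchable": int((~df["matched"]).sum()),
        }
    )
    result = pd.DataFrame(out)
    result["matched_pct"] = [
        round1(100.0 * m / n) for m, n in zip(result["n_matched"], result["n"])
    ]
    return result


def threshold_sweep(
    dataset: LinkageDataset,
    grid: Sequence[float],
    base: SiftParameters,
    vary: str = "macro",
    factors: EnergyFactors = DEFAULT_FACTORS,
    blocking: bool = True,
) -> pd.DataFrame:
    """Suggested-match count distribution as a function of one threshold.

    For each grid value the three nutrient filters (fuzzy matching off, per
    the diagnostic's design) are run for every eligible product with the
    varied threshold (``vary`` is ``"macro"``, ``"secondary"`` or
    ``"sodium"``) replacing the corresponding entry of ``base``. Rows give
    the 0/25/50/75/100th percentiles of the square roots of the per-product
    match counts — square roots because counts under loose thresholds span
    orders of magnitude.
    """
    if not len(grid):
        raise ValidationError("threshold grid must be nonempty")
    if vary not in {"macro", "secondary", "sodium"}:
        raise ValidationError(f"vary must be macro|secondary|sodium, got {vary!r}")
    eligible, _, _ = screen_eligibility(dataset.products, base.required_fields())
    out = []
    for value in grid:
        macro = value if vary == "macro" else base.macro_threshold
        secondary = value if vary == "secondary" else base.secondary_threshold
        sodium = value if vary == "sodium" else base.sodium_threshold
        counts = []
        for p in eligible:
            pool = candidate_pool(p, dataset.reference, blocking)
            pool = filter_macros(p, pool, macro, factors, base.nutrient_strict)
            pool = filter_secondary(p, pool, secondary, factors, base.nutrient_strict)
            pool = filter_sodium(p, pool, sodium, base.nutrient_strict)
            counts.append(len(pool))
        sqrt_counts = np.sqrt(np.asarray(counts, dtype=float))
        if len(sqrt_counts):
            pcts = np.percentile(sqrt_counts, [0, 25, 50, 75, 100])
        else:
            pcts = [np.nan] * 5
        out.append(
            {
                "threshold": value,
                "n_products": len(counts),
                "p0": pcts[0],
                "p25": pcts[1],
                "p50": pcts[2],
                "p75": pcts[3],
                "p100": pcts[4],
            }
        )
    return pd.DataFrame(out)
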