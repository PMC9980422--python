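"""Domain types, table I/O, unit conversion, and eligibility screening.

The linkage runs between two tables that must share a common per-mass basis
(per 100 g or per 100 mL; the toolkit never rescales):

* a *product* table of branded items, each named by subcategory + brand and
  carrying energy (kcal) plus seven nutrients, and
* a *reference* table of generic foods from a food-composition database.

Both sides carry a *blocking group* — a shared food-classification label
that restricts candidate matches to foods of the same kind, in the manner
of blocking keys in classical record linkage.

Missing nutrient values are tracked explicitly as ``None`` and are never
coerced to zero; downstream filters treat a missing value conservatively
(the record fails any filter that needs the field).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import (
    IntegrityError,
    RowParseError,
    SchemaError,
    ValidationError,
)

# Canonical nutrient field names, in reporting order.
MACRO_NUTRIENTS = ("carbohydrate", "protein", "total_fat")
SECONDARY_NUTRIENTS = ("fiber", "saturated_fat", "sugar")
CALORIC_NUTRIENTS = MACRO_NUTRIENTS + SECONDARY_NUTRIENTS
PROFILE_FIELDS = ("energy",) + CALORIC_NUTRIENTS + ("sodium",)

#: mg of sodium per g of salt (NaCl is ~39.3% sodium by mass).
SALT_TO_SODIUM_MG_PER_G = 393.0

_NUMERIC_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def salt_to_sodium(salt_g: float) -> float:
    """Convert grams of salt to milligrams of sodium (g salt x 393 = mg sodium).

    Raises :class:`ValidationError` for negative or non-finite input.
    """
    if not math.isfinite(salt_g) or salt_g < 0:
        raise ValidationError(f"salt mass must be finite and >= 0, got {salt_g!r}")
    return salt_g * SALT_TO_SODIUM_MG_PER_G


@dataclass(frozen=True)
class NutrientProfile:
    """Energy plus seven nutrient quantities on a common per-mass basis.

    Units: ``energy`` in kcal; ``sodium`` in mg; every other field in g,
    all per the table's reference mass (conventionally per 100 g).
    ``None`` marks an explicitly missing value.
    """

    energy: Optional[float] = None
    carbohydrate: Optional[float] = None
    protein: Optional[float] = None
    total_fat: Optional[float] = None
    fiber: Optional[float] = None
    saturated_fat: Optional[float] = None
    sugar: Optional[float] = None
    sodium: Optional[float] = None

    def __post_init__(self) -> None:
        for name in PROFILE_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value!r}")

    def get(self, name: str) -> Optional[float]:
        if name not in PROFILE_FIELDS:
            raise KeyError(name)
        return getattr(self, name)

    def missing_fields(self, required: Sequence[str] = PROFILE_FIELDS) -> tuple[str, ...]:
        """Names of required fields that are missing from this profile."""
        return tuple(n for n in required if getattr(self, n) is None)


@dataclass(frozen=True)
class ProductRecord:
    """One branded product: the query side of the linkage."""

    product_id: str
    subcategory: str
    brand: str
    blocking_group: str
    profile: NutrientProfile
    name: str = ""
    eligible: Optional[bool] = None
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", f"{self.subcategory}, {self.brand}")


@dataclass(frozen=True)
class ReferenceFoodRecord:
    """One generic reference food: the target side of the linkage."""

    food_id: str
    name: str
    blocking_group: str
    profile: NutrientProfile


@dataclass
class LinkageDataset:
    """The two tables plus the vocabulary of blocking-group labels."""

    products: list[ProductRecord]
    reference: list[ReferenceFoodRecord]
    group_vocabulary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        used = {p.blocking_group for p in self.products} | {
            f.blocking_group for f in self.reference
        }
        if not self.group_vocabulary:
            self.group_vocabulary = used
        else:
            unknown = used - self.group_vocabulary
            if unknown:
                raise ValidationError(
                    f"blocking groups not in vocabulary: {sorted(unknown)}"
                )


def parse_number(raw: object) -> Optional[float]:
    """Parse a cell into a float, locale-independently.

    Empty cells and the common NA spellings map to ``None``. The decimal
    separator is the period; thousands separators are rejected.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NULL", "NONE"}:
        return None
    if not _NUMERIC_RE.match(s):
        raise ValueError(f"unparseable numeric value {s!r}")
    return float(s)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _resolve_columns(
    df: pd.DataFrame, column_map: Mapping[str, str], required: Iterable[str]
) -> dict[str, str]:
    resolved = {}
    for canonical in required:
        source = column_map.get(canonical, canonical)
        if source not in df.columns:
            raise SchemaError(
                f"required column {canonical!r} (file column {source!r}) not found; "
                f"file has columns {list(df.columns)}"
            )
        resolved[canonical] = source
    return resolved


def _profile_from_row(
    row: pd.Series, cols: Mapping[str, str], idx: int, salt_column: bool
) -> NutrientProfile:
    values: dict[str, Optional[float]] = {}
    for name in ("energy",) + CALORIC_NUTRIENTS:
        try:
            values[name] = parse_number(row[cols[name]])
        except ValueError as exc:
            raise RowParseError(idx, f"column {cols[name]!r}: {exc}") from exc
    sodium_key = "salt" if salt_column else "sodium"
    try:
        raw = parse_number(row[cols[sodium_key]])
    except ValueError as exc:
        raise RowParseError(idx, f"column {cols[sodium_key]!r}: {exc}") from exc
    if raw is None:
        values["sodium"] = None
    elif salt_column:
        values["sodium"] = salt_to_sodium(raw)
    else:
        values["sodium"] = raw
    try:
        return NutrientProfile(**values)
    except ValidationError as exc:
        raise RowParseError(idx, str(exc)) from exc


def load_products(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    salt_column: bool = False,
    required_fields: Sequence[str] = PROFILE_FIELDS,
) -> list[ProductRecord]:
    """Read a product table from CSV/TSV.

    ``column_map`` maps canonical column names (``product_id``,
    ``subcategory``, ``brand``, ``blocking_group``, ``energy``,
    ``carbohydrate``, ``protein``, ``total_fat``, ``saturated_fat``,
    ``sugar``, ``fiber`` and ``sodium`` or ``salt``) to the file's column
    names; identity is assumed for names not in the map. With
    ``salt_column=True`` the sodium field is derived from a grams-of-salt
    column via :func:`salt_to_sodium`. Eligibility is computed against
    ``required_fields`` (see :func:`screen_eligibility`).
    """
    column_map = dict(column_map or {})
    df = _read_table(path)
    sodium_key = "salt" if salt_column else "sodium"
    cols = _resolve_columns(
        df,
        column_map,
        ["product_id", "subcategory", "brand", "blocking_group", "energy"]
        + list(CALORIC_NUTRIENTS)
        + [sodium_key],
    )
    name_col = column_map.get("name", "name") if (
        "name" in column_map or "name" in df.columns
    ) else None
    records: list[ProductRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = str(row[cols["product_id"]]).strip()
        if pid in seen:
            raise IntegrityError(f"duplicate product_id {pid!r}")
        seen.add(pid)
        profile = _profile_from_row(row, cols, int(idx), salt_column)
        rec = ProductRecord(
            product_id=pid,
            subcategory=str(row[cols["subcategory"]]).strip(),
            brand=str(row[cols["brand"]]).strip(),
            blocking_group=str(row[cols["blocking_group"]]).strip(),
            profile=profile,
            name=str(row[name_col]).strip() if name_col else "",
        )
        records.append(rec)
    eligible, excluded, reasons = screen_eligibility(records, required_fields)
    by_id = {p.product_id: p for p in eligible + excluded}
    return [by_id[p.product_id] for p in records]


def load_reference(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    group_vocabulary: Optional[set[str]] = None,
) -> list[ReferenceFoodRecord]:
    """Read a reference-food table from CSV/TSV (see :func:`load_products`).

    Reference rows need ``food_id``, ``name``, ``blocking_group`` and the
    nutrient columns; no salt conversion and no eligibility screening. If a
    ``group_vocabulary`` is supplied, rows using a group outside it raise
    :class:`ValidationError`.
    """
    column_map = dict(column_map or {})
    df = _read_table(path)
    cols = _resolve_columns(
        df,
        column_map,
        ["food_id", "name", "blocking_group", "energy"]
        + list(CALORIC_NUTRIENTS)
        + ["sodium"],
    )
    records: list[ReferenceFoodRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        fid = str(row[cols["food_id"]]).strip()
        if fid in seen:
            raise IntegrityError(f"duplicate food_id {fid!r}")
        seen.add(fid)
        group = str(row[cols["blocking_group"]]).strip()
        if group_vocabulary is not None and group not in group_vocabulary:
            raise ValidationError(
                f"row {idx}: blocking group {group!r} not in vocabulary"
            )
        records.append(
            ReferenceFoodRecord(
                food_id=fid,
                name=str(row[cols["name"]]).strip(),
                blocking_group=group,
                profile=_profile_from_row(row, cols, int(idx), salt_column=False),
            )
        )
    return records


#: Exclusion reason labels.
REASON_ZERO_ENERGY = "zero_energy"
REASON_MISSING_NUTRIENT = "missing_nutrient"


def screen_eligibility(
    products: Iterable[ProductRecord],
    required_fields: Sequence[str] = PROFILE_FIELDS,
) -> tuple[list[ProductRecord], list[ProductRecord], dict[str, str]]:
    """Partition products into algorithm-eligible and excluded.

    A product is excluded when its energy is zero (the proportion-of-calories
    filters use energy as denominator) or when any field in
    ``required_fields`` is missing. Returns ``(eligible, excluded, reasons)``
    where ``reasons`` maps excluded product ids to ``zero_energy`` or
    ``missing_nutrient``. The partition is exhaustive and disjoint, and the
    operation is idempotent.
    """
    eligible: list[ProductRecord] = []
    excluded: list[ProductRecord] = []
    reasons: dict[str, str] = {}
    for p in products:
        energy = p.profile.energy
        if energy is not None and energy <= 0:
            reason: Optional[str] = REASON_ZERO_ENERGY
        elif p.profile.missing_fields(required_fields):
            reason = REASON_MISSING_NUTRIENT
        else:
            reason = None
        if reason is None:
            eligible.append(replace(p, eligible=True, exclusion_reason=None))
        else:
            excluded.append(replace(p, eligible=False, exclusion_reason=reason))
            reasons[p.product_id] = reason
    return eligible, excluded, reasons


def products_to_frame(products: Iterable[ProductRecord]) -> pd.DataFrame:
    rows = []
    for p in products:
        row = {
            "product_id": p.product_id,
            "subcategory": p.subcategory,
            "brand": p.brand,
            "name": p.name,
            "blocking_group": p.blocking_group,
            "eligible": p.eligible,
            "exclusion_reason": p.exclusion_reason or "",
        }
        row.update({n: p.profile.get(n) for n in PROFILE_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows)


def reference_to_frame(reference: Iterable[ReferenceFoodRecord]) -> pd.DataFrame:
    rows = []
    for f in reference:
        row = {
            "food_id": f.food_id,
            "name": f.name,
            "blocking_group": f.blocking_group,
        }
        row.update({n: f.profile.get(n) for n in PROFILE_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows)


def write_products(products: Iterable[ProductRecord], path: str | Path) -> None:
    products_to_frame(products).to_csv(path, index=False)


def write_reference(reference: Iterable[ReferenceFoodRecord], path: str | Path) -> None:
    reference_to_frame(reference).to_csv(path, index=False)
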