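"""Leftover volume to consumed nutrients.

The measured leftover volume V (cm^3) of each food item converts to
weight through its density factor D (g/cm^3),

    W = V * D,

then to per-component nutrient amounts through the food's per-gram
nutritional data,

    CN(i) = W * ND_g(i),

and finally the consumed amount is the kitchen-reported serving minus
the calculated leftover, per component:

    CoN(i) = RN(i) - CN(i).

Components tracked: calories (kcal/g) and the mass fractions
carbohydrate, protein, sugar, fat (g/g).  Density tables are plain CSV
so any source (institutional database, public nutrition sites with
per-100 g values divided by 100) can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "COMPONENTS",
    "FoodRecord",
    "MealAccount",
    "DensityTableError",
    "load_density_db",
    "volume_to_weight",
    "weight_to_nutrients",
    "consumed",
    "meal_report",
]

COMPONENTS = ("kcal", "carb_g", "protein_g", "sugar_g", "fat_g")

_DB_COLUMNS = [
    "food_id",
    "density_g_per_cm3",
    "kcal_per_g",
    "carb_g_per_g",
    "protein_g_per_g",
    "sugar_g_per_g",
    "fat_g_per_g",
]

_COL_TO_COMPONENT = dict(zip(_DB_COLUMNS[2:], COMPONENTS))


class DensityTableError(ValueError):
    """Malformed density/nutrient table."""


@dataclass(frozen=True)
class FoodRecord:
    """Density and per-gram nutrient content for one food."""

    food_id: str
    density: float  # g/cm^3
    nutrients_per_g: dict  # component -> per-gram amount

    def __post_init__(self):
        if self.density <= 0:
            raise DensityTableError(
                f"food {self.food_id!r}: density must be > 0, got {self.density}"
            )
        for comp, val in self.nutrients_per_g.items():
            if val < 0:
                raise DensityTableError(
                    f"food {self.food_id!r}: negative {comp} per gram"
                )
            if comp != "kcal" and val > 1.0:
                raise DensityTableError(
                    f"food {self.food_id!r}: mass fraction {comp} exceeds 1 g/g"
                )


@dataclass
class MealAccount:
    """Reported, leftover and consumed nutrients for one meal."""

    reported: dict  # RN(i)
    leftover: dict  # CN(i)
    consumed: dict  # CoN(i) = RN(i) - CN(i)
    warnings: list = field(default_factory=list)


def load_density_db(path) -> dict[str, FoodRecord]:
    """Load a density/nutrient CSV into records keyed by food id.

    Expected header: ``food_id,density_g_per_cm3,kcal_per_g,
    carb_g_per_g,protein_g_per_g,sugar_g_per_g,fat_g_per_g``.

    Raises
    ------
    DensityTableError
        For unknown/missing columns, a duplicate food id, a negative
        density or nutrient value — naming the row where possible.
    """
    df = pd.read_csv(path, dtype={"food_id": str}, comment="#")
    unknown = [c for c in df.columns if c not in _DB_COLUMNS]
    if unknown:
        raise DensityTableError(f"unknown column(s): {', '.join(unknown)}")
    missing = [c for c in _DB_COLUMNS if c not in df.columns]
    if missing:
        raise DensityTableError(f"missing column(s): {', '.join(missing)}")
    records: dict[str, FoodRecord] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.food_id in records:
            raise DensityTableError(
                f"row {row_no}: duplicate food id {row.food_id!r}"
            )
        try:
            rec = FoodRecord(
                food_id=row.food_id,
                density=float(row.density_g_per_cm3),
                nutrients_per_g={
                    comp: float(getattr(row, col))
                    for col, comp in _COL_TO_COMPONENT.items()
                },
            )
        except DensityTableError as exc:
            raise DensityTableError(f"row {row_no}: {exc}") from exc
        records[row.food_id] = rec
    return records


def volume_to_weight(volume_cm3: float, density: float) -> float:
    """W = V * D (grams)."""
    if volume_cm3 < 0:
        raise ValueError("volume must be >= 0")
    if density <= 0:
        raise ValueError("density must be > 0")
    return volume_cm3 * density


def weight_to_nutrients(weight_g: float, record: FoodRecord) -> dict:
    """CN(i) = W * ND_g(i) for every tracked component."""
    if weight_g < 0:
        raise ValueError("weight must be >= 0")
    return {
        comp: weight_g * record.nutrients_per_g.get(comp, 0.0)
        for comp in COMPONENTS
    }


def consumed(reported: dict, leftover: dict) -> MealAccount:
    """CoN = RN - CN elementwise.

    A component where the calculated leftover exceeds the serving keeps
    its negative consumed value but is flagged (it signals a volume
    over-estimate or a wrong density).

    Raises
    ------
    ValueError
        If the two dicts do not cover the same components.
    """
    if set(reported) != set(leftover):
        raise ValueError(
            f"component mismatch: reported {sorted(reported)} vs "
            f"leftover {sorted(leftover)}"
        )
    con = {c: reported[c] - leftover[c] for c in reported}
    warnings = [
        f"leftover {c} ({leftover[c]:.3g}) exceeds reported ({reported[c]:.3g})"
        for c in reported
        if leftover[c] > reported[c]
    ]
    return MealAccount(
        reported=dict(reported), leftover=dict(leftover), consumed=con,
        warnings=warnings,
    )


def meal_report(items, db: dict[str, FoodRecord], kitchen: dict) -> MealAccount:
    """Full chain for one meal: volumes -> weights -> nutrients -> consumed.

    Parameters
    ----------
    items : iterable of (volume_cm3, food_id)
        Measured leftover volume per food item.
    db : mapping food_id -> FoodRecord
    kitchen : dict component -> served amount (RN)

    Leftover nutrients are summed across items per component before the
    subtraction (the kitchen reports the meal as a whole).

    Raises
    ------
    KeyError
        Naming any food id absent from the database.
    """
    totals = {c: 0.0 for c in COMPONENTS}
    for volume, food_id in items:
        if food_id not in db:
            raise KeyError(f"food id {food_id!r} not in density database")
        rec = db[food_id]
        cn = weight_to_nutrients(volume_to_weight(volume, rec.density), rec)
        for c in COMPONENTS:
            totals[c] += cn[c]
    leftover = {c: totals[c] for c in kitchen}
    return consumed(kitchen, leftover)
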