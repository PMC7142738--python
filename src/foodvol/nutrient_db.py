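"""Volume -> weight -> macronutrient conversion.

Weight is volume times a per-food density; macronutrients scale per 100 g
from a composition table.  Energy uses the table's kcal column when
present, falling back to Atwater factors (4/4/9 kcal per gram of
carbohydrate/protein/fat).

A small bundled table (``data/food_composition.csv``) with representative
densities and compositions ships with the package; it is a synthetic
stand-in with the same schema as a national food-composition database, so
users can swap in a real one:

    food_id,name,density_g_per_ml,cho_g_per_100g,protein_g_per_100g,fat_g_per_100g,kcal_per_100g
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FoodLookupError, TableValidationError

__all__ = [
    "FoodRecord",
    "FoodTable",
    "ItemEstimate",
    "MealEstimate",
    "volume_to_weight",
    "weight_to_macros",
    "load_food_table",
    "FOOD_TABLE_COLUMNS",
]

FOOD_TABLE_COLUMNS = [
    "food_id",
    "name",
    "density_g_per_ml",
    "cho_g_per_100g",
    "protein_g_per_100g",
    "fat_g_per_100g",
    "kcal_per_100g",
]


@dataclass(frozen=True)
class FoodRecord:
    """Density and per-100 g composition of one food."""

    food_id: str
    name: str
    density_g_per_ml: float
    cho_g_per_100g: float
    protein_g_per_100g: float
    fat_g_per_100g: float
    kcal_per_100g: float | None = None

    def __post_init__(self) -> None:
        if self.density_g_per_ml <= 0:
            raise TableValidationError(f"{self.food_id}: density must be positive")
        macros = (self.cho_g_per_100g, self.protein_g_per_100g, self.fat_g_per_100g)
        if any(m < 0 for m in macros):
            raise TableValidationError(f"{self.food_id}: negative macro content")
        if sum(macros) > 100.0 + 1e-9:
            raise TableValidationError(
                f"{self.food_id}: macros exceed 100 g per 100 g"
            )
        if self.kcal_per_100g is not None and self.kcal_per_100g < 0:
            raise TableValidationError(f"{self.food_id}: negative energy")


class FoodTable:
    """Mapping of food_id -> :class:`FoodRecord`."""

    def __init__(self, records: list[FoodRecord]):
        self._records: dict[str, FoodRecord] = {}
        for rec in records:
            if rec.food_id in self._records:
                raise TableValidationError(f"duplicate food_id {rec.food_id!r}")
            self._records[rec.food_id] = rec

    def __getitem__(self, food_id: str) -> FoodRecord:
        try:
            return self._records[food_id]
        except KeyError:
            raise FoodLookupError(f"unknown food_id {food_id!r}") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())


def load_food_table(path: str | Path | None = None) -> FoodTable:
    """Load and validate a food table CSV (bundled table when path is None)."""
    if path is None:
        with resources.as_file(
            resources.files("foodvol.data").joinpath("food_composition.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in FOOD_TABLE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        kcal = row.get("kcal_per_100g")
        try:
            records.append(
                FoodRecord(
                    food_id=str(row["food_id"]),
                    name=str(row["name"]),
                    density_g_per_ml=float(row["density_g_per_ml"]),
                    cho_g_per_100g=float(row["cho_g_per_100g"]),
                    protein_g_per_100g=float(row["protein_g_per_100g"]),
                    fat_g_per_100g=float(row["fat_g_per_100g"]),
                    kcal_per_100g=None if kcal is None or pd.isna(kcal) else float(kcal),
                )
            )
        except TableValidationError as exc:
            raise TableValidationError(f"row {i + 2}: {exc}") from exc  # 1-based + header
    return FoodTable(records)


def volume_to_weight(volume_mL: float, record: FoodRecord) -> float:
    """Weight in grams = volume in mL x density in g/mL."""
    if volume_mL < 0:
        raise ValueError("volume must be >= 0")
    return volume_mL * record.density_g_per_ml


def weight_to_macros(
    weight_g: float, record: FoodRecord
) -> tuple[float, float, float, float]:
    """(carbohydrate g, protein g, fat g, energy kcal) for a given weight.

    Energy prefers the record's kcal column; Atwater 4/4/9 otherwise.
    """
    if weight_g < 0:
        raise ValueError("weight must be >= 0")
    cho = weight_g * record.cho_g_per_100g / 100.0
    protein = weight_g * record.protein_g_per_100g / 100.0
    fat = weight_g * record.fat_g_per_100g / 100.0
    if record.kcal_per_100g is not None:
        kcal = weight_g * record.kcal_per_100g / 100.0
    else:
        kcal = 4.0 * cho + 4.0 * protein + 9.0 * fat
    return cho, protein, fat, kcal


@dataclass
class ItemEstimate:
    """Per-item pipeline output."""

    label: int
    food_id: str
    volume_mL: float
    weight_g: float
    cho_g: float
    protein_g: float
    fat_g: float
    kcal: float


@dataclass
class MealEstimate:
    """Per-meal pipeline output; totals are sums over items."""

    meal_id: str
    items: list[ItemEstimate]
    excluded_labels: list[int] = field(default_factory=list)

    def total(self, column: str) -> float:
        return float(sum(getattr(it, column) for it in self.items))

    @property
    def weight_g(self) -> float:
        return self.total("weight_g")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "meal_id": self.meal_id,
                "item_label": it.label,
                "food_id": it.food_id,
                "volume_mL": it.volume_mL,
                "weight_g": it.weight_g,
                "cho_g": it.cho_g,
                "protein_g": it.protein_g,
                "fat_g": it.fat_g,
                "kcal": it.kcal,
            }
            for it in self.items
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "meal_id", "item_label", "food_id", "volume_mL", "weight_g",
                "cho_g", "protein_g", "fat_g", "kcal",
            ],
        )
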