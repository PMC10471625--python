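"""Domain types for farms and herds, livestock-unit arithmetic and CSV I/O.

A farm record describes one pasture-based cattle farm for one accounting
year: herd composition, private agricultural area, the grazing calendar
(days spent on valley meadows/forests versus communal mountain pastures),
the physical inventory of purchased inputs, and the economic account
(product income, CAP payments, taxes, variable costs).
"""

from __future__ import annotations

from typing import ClassVar, Iterator, Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "LU_COEFFICIENTS",
    "HerdComposition",
    "GrazingCalendar",
    "InputInventory",
    "EconomicAccount",
    "Farm",
    "compute_livestock_units",
    "read_farm_table",
    "write_farm_table",
]

#: Livestock-unit coefficients per animal category (cow/bull 1, heifer 0.7,
#: calf 0.4), the conventional conversion for suckler cattle herds.
LU_COEFFICIENTS: dict[str, float] = {
    "cows": 1.0,
    "bulls": 1.0,
    "heifers": 0.7,
    "calves": 0.4,
}

FarmType = Literal["weaner", "weaner_finisher"]


class HerdComposition(BaseModel):
    """Head counts by animal category."""

    cows: int = Field(0, ge=0)
    bulls: int = Field(0, ge=0)
    heifers: int = Field(0, ge=0)
    calves: int = Field(0, ge=0)

    def livestock_units(self) -> float:
        return compute_livestock_units(self)


def compute_livestock_units(herd: HerdComposition) -> float:
    """Herd size in livestock units: cows*1 + bulls*1 + heifers*0.7 + calves*0.4."""
    return sum(
        LU_COEFFICIENTS[category] * getattr(herd, category)
        for category in LU_COEFFICIENTS
    )


class GrazingCalendar(BaseModel):
    """Days per year grazed on each natural-pasture area, without external feed."""

    days_meadows_forests: float = Field(0.0, ge=0)
    days_mountain_pastures: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _total_within_year(self) -> "GrazingCalendar":
        if self.days_meadows_forests + self.days_mountain_pastures > 366:
            raise ValueError("total grazing days exceed 366")
        return self

    @property
    def total_days(self) -> float:
        return self.days_meadows_forests + self.days_mountain_pastures


class InputInventory(BaseModel):
    """Physical and monetary quantities of purchased inputs, one accounting year.

    Mass items are carried in grams and energy items in joules so that each
    quantity is already in the unit its UEV expects; monetary items
    (veterinary, depreciation) are carried in euro and converted with the
    em-euro ratio like services.
    """

    straw_g: float = Field(0.0, ge=0)
    corn_g: float = Field(0.0, ge=0)
    forage_g: float = Field(0.0, ge=0)
    concentrates_g: float = Field(0.0, ge=0)
    vitamin_mineral_supplements_g: float = Field(0.0, ge=0)
    fuel_j: float = Field(0.0, ge=0)
    electricity_j: float = Field(0.0, ge=0)
    fertiliser_g: float = Field(0.0, ge=0)
    seeds_g: float = Field(0.0, ge=0)
    phytochemicals_g: float = Field(0.0, ge=0)
    veterinary_medicines_eur: float = Field(0.0, ge=0)
    machinery_depreciation_eur: float = Field(0.0, ge=0)
    buildings_depreciation_eur: float = Field(0.0, ge=0)
    small_equipment_eur: float = Field(0.0, ge=0)

    #: Map resource name (as it appears in the UEV table) -> model field.
    RESOURCE_FIELDS: ClassVar[dict[str, str]] = {
        "straw": "straw_g",
        "corn": "corn_g",
        "forage": "forage_g",
        "concentrates": "concentrates_g",
        "vitamin_mineral_supplements": "vitamin_mineral_supplements_g",
        "fuel": "fuel_j",
        "electricity": "electricity_j",
        "fertiliser": "fertiliser_g",
        "seeds": "seeds_g",
        "phytochemicals": "phytochemicals_g",
        "veterinary_medicines": "veterinary_medicines_eur",
        "machinery_depreciation": "machinery_depreciation_eur",
        "buildings_depreciation": "buildings_depreciation_eur",
        "small_equipment": "small_equipment_eur",
    }

    def items(self) -> Iterator[tuple[str, float]]:
        """Yield ``(resource_name, quantity)`` pairs for every inventory entry."""
        for resource, field in self.RESOURCE_FIELDS.items():
            yield resource, getattr(self, field)


class EconomicAccount(BaseModel):
    """Monetary flows of the farm for the accounting year, euro."""

    total_income_eur: float = Field(0.0, ge=0)
    cap_payments_eur: float = Field(0.0, ge=0)
    taxes_paid_eur: float = Field(0.0, ge=0)
    variable_costs_eur: float = Field(0.0, ge=0)


class Farm(BaseModel):
    """One farm-year record.

    ``farm_type`` determines the output product (weaned calves versus
    finished animals); the two types are never pooled in cohort summaries.
    """

    farm_id: str
    farm_type: FarmType
    agricultural_area_ha: float = Field(gt=0)
    herd: HerdComposition
    calendar: GrazingCalendar
    inventory: InputInventory = Field(default_factory=InputInventory)
    economics: EconomicAccount = Field(default_factory=EconomicAccount)
    labour_wu: float = Field(0.0, ge=0)

    def livestock_units(self) -> float:
        return compute_livestock_units(self.herd)


# CSV schema: (column, model path, scale factor column->model units).
# Mass columns are kg (stored as g), energy columns MJ (stored as J).
_CSV_SCHEMA: list[tuple[str, tuple[str, ...], float]] = [
    ("farm_id", ("farm_id",), 1.0),
    ("farm_type", ("farm_type",), 1.0),
    ("agricultural_area_ha", ("agricultural_area_ha",), 1.0),
    ("cows", ("herd", "cows"), 1.0),
    ("bulls", ("herd", "bulls"), 1.0),
    ("heifers", ("herd", "heifers"), 1.0),
    ("calves", ("herd", "calves"), 1.0),
    ("days_meadows_forests", ("calendar", "days_meadows_forests"), 1.0),
    ("days_mountain_pastures", ("calendar", "days_mountain_pastures"), 1.0),
    ("straw_kg", ("inventory", "straw_g"), 1e3),
    ("corn_kg", ("inventory", "corn_g"), 1e3),
    ("forage_kg", ("inventory", "forage_g"), 1e3),
    ("concentrates_kg", ("inventory", "concentrates_g"), 1e3),
    ("vitamin_mineral_supplements_kg", ("inventory", "vitamin_mineral_supplements_g"), 1e3),
    ("fuel_mj", ("inventory", "fuel_j"), 1e6),
    ("electricity_mj", ("inventory", "electricity_j"), 1e6),
    ("fertiliser_kg", ("inventory", "fertiliser_g"), 1e3),
    ("seeds_kg", ("inventory", "seeds_g"), 1e3),
    ("phytochemicals_kg", ("inventory", "phytochemicals_g"), 1e3),
    ("veterinary_medicines_eur", ("inventory", "veterinary_medicines_eur"), 1.0),
    ("machinery_depreciation_eur", ("inventory", "machinery_depreciation_eur"), 1.0),
    ("buildings_depreciation_eur", ("inventory", "buildings_depreciation_eur"), 1.0),
    ("small_equipment_eur", ("inventory", "small_equipment_eur"), 1.0),
    ("labour_wu", ("labour_wu",), 1.0),
    ("total_income_eur", ("economics", "total_income_eur"), 1.0),
    ("cap_payments_eur", ("economics", "cap_payments_eur"), 1.0),
    ("taxes_paid_eur", ("economics", "taxes_paid_eur"), 1.0),
    ("variable_costs_eur", ("economics", "variable_costs_eur"), 1.0),
]

FARM_CSV_COLUMNS = [col for col, _, _ in _CSV_SCHEMA]

_INT_COLUMNS = {"cows", "bulls", "heifers", "calves"}
_STR_COLUMNS = {"farm_id", "farm_type"}


def _row_to_farm(row: pd.Series) -> Farm:
    nested: dict[str, dict] = {"herd": {}, "calendar": {}, "inventory": {}, "economics": {}}
    top: dict[str, object] = {}
    for col, path, scale in _CSV_SCHEMA:
        raw = row[col]
        if col in _STR_COLUMNS:
            value: object = str(raw)
        elif col in _INT_COLUMNS:
            value = int(raw)
        else:
            value = float(raw) * scale
        if len(path) == 1:
            top[path[0]] = value
        else:
            nested[path[0]][path[1]] = value
    return Farm(
        **top,
        herd=HerdComposition(**nested["herd"]),
        calendar=GrazingCalendar(**nested["calendar"]),
        inventory=InputInventory(**nested["inventory"]),
        economics=EconomicAccount(**nested["economics"]),
    )


def read_farm_table(path) -> list[Farm]:
    """Read a one-row-per-farm CSV into validated :class:`Farm` records.

    The CSV dialect is fixed (UTF-8, comma separated, mandatory header row).
    Rows failing validation are reported with their zero-based row index and
    the offending field; the whole read fails on any bad row.
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in FARM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"farm table is missing required columns: {missing}")
    farms: list[Farm] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            farms.append(_row_to_farm(row))
        except Exception as exc:  # pydantic ValidationError or cast failure
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError("invalid farm rows:\n" + "\n".join(errors))
    return farms


def write_farm_table(farms: list[Farm], path, include_livestock_units: bool = False) -> None:
    """Write farms to CSV with the fixed column schema.

    With ``include_livestock_units`` an extra ``livestock_units`` column is
    appended (the validated-echo output); :func:`read_farm_table` ignores
    extra columns, so the round trip stays lossless.
    """
    records = []
    for farm in farms:
        rec: dict[str, object] = {}
        for col, path_, scale in _CSV_SCHEMA:
            obj = farm
            for part in path_[:-1]:
                obj = getattr(obj, part)
            value = getattr(obj, path_[-1])
            rec[col] = value if col in _STR_COLUMNS or col in _INT_COLUMNS else value / scale
        if include_livestock_units:
            rec["livestock_units"] = farm.livestock_units()
        records.append(rec)
    columns = FARM_CSV_COLUMNS + (["livestock_units"] if include_livestock_units else [])
    # %.17g guarantees an exact float64 round trip through the text format
    pd.DataFrame.from_records(records, columns=columns).to_csv(
        path, index=False, encoding="utf-8", float_format="%.17g"
    )
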