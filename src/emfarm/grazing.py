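"""Consumption-based allocation of natural-pasture emergy to a farm.

Natural pastures (valley meadows/forests and communal mountain pastures)
lie outside the farm boundary and livestock consumes only part of the energy
those ecosystems receive.  The full annual emergy flow of a grazed area (E)
is therefore scaled down to the fraction the herd actually obtains:

    allocated = E * (grazing days / year length) * ANPP fraction
                  * fraction of ANPP consumed by livestock

summed over the two grazing areas.  The grazed area itself comes from the
herd size and an area-specific stocking rate.  The standard accounting
practice, kept here as the comparison baseline, allocates the full annual
flow E of every area the herd uses.

The consumption equation is also published in a divided form (E divided by
the product of the three factors).  That form is dimensionally inconsistent
and would award more emergy to farms that graze less, so the multiplicative
form above is the default; the divided form stays available behind an
explicit audit flag.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .core import EmergyFlow, UEVTable
from .farms import Farm
from .natural import ClimateRecord, solar_origin_emergy

__all__ = [
    "GrazingParameters",
    "PastureEmergy",
    "grazed_area",
    "grazing_emergy",
    "allocate_pastures",
    "natural_pastures_emergy",
    "standard_pastures_emergy",
    "pasture_flow",
]

AreaKind = Literal["meadows_forests", "mountain"]


class GrazingParameters(BaseModel):
    """Stocking rates, production and consumption fractions.

    Defaults are the study-area estimates: stocking 0.2 LU/ha on valley
    meadows and forests and 1.2 LU/ha on mountain pastures; aboveground net
    primary production is 50% of NPP on both areas; livestock consumes 65%
    of ANPP on meadows/forests and 40% on mountain pastures.
    """

    stocking_rate_meadows_forests: float = Field(0.2, gt=0, description="LU/ha")
    stocking_rate_mountain: float = Field(1.2, gt=0, description="LU/ha")
    anpp_fraction: float = Field(0.50, gt=0, le=1)
    consumed_fraction_meadows_forests: float = Field(0.65, gt=0, le=1)
    consumed_fraction_mountain: float = Field(0.40, gt=0, le=1)
    year_length_days: float = Field(365.0, gt=0)

    def stocking_rate(self, area_kind: AreaKind) -> float:
        if area_kind == "meadows_forests":
            return self.stocking_rate_meadows_forests
        return self.stocking_rate_mountain

    def consumed_fraction(self, area_kind: AreaKind) -> float:
        if area_kind == "meadows_forests":
            return self.consumed_fraction_meadows_forests
        return self.consumed_fraction_mountain


class PastureEmergy(BaseModel):
    """Full-NPP and allocated emergy of a farm's two grazing areas."""

    e_meadows_forests: float = Field(ge=0, description="full-NPP emergy, sej/yr")
    e_mountain: float = Field(ge=0)
    allocated_meadows_forests: float = Field(ge=0)
    allocated_mountain: float = Field(ge=0)

    @model_validator(mode="after")
    def _allocated_bounded(self) -> "PastureEmergy":
        if self.allocated_meadows_forests > self.e_meadows_forests * (1 + 1e-9):
            raise ValueError("meadows/forests allocation exceeds full-NPP emergy")
        if self.allocated_mountain > self.e_mountain * (1 + 1e-9):
            raise ValueError("mountain allocation exceeds full-NPP emergy")
        return self

    @property
    def total_allocated(self) -> float:
        return self.allocated_meadows_forests + self.allocated_mountain


def grazed_area(lu: float, stocking_rate: float) -> float:
    """Area (ha) a herd of ``lu`` livestock units uses at a stocking rate."""
    if lu < 0:
        raise ValueError("livestock units must be >= 0")
    if stocking_rate <= 0:
        raise ValueError("stocking rate must be > 0")
    return lu / stocking_rate


def grazing_emergy(
    e: float,
    grazing_days: float,
    params: GrazingParameters,
    area_kind: AreaKind,
    division_form: bool = False,
) -> float:
    """Emergy the herd obtains from one grazing area (sej/yr).

    Multiplicative consumption scaling of the area's full-NPP emergy ``e``
    by grazing-period length, ANPP fraction and consumed fraction.  With
    ``division_form`` the published divided form is computed instead (audit
    only; see module docstring).
    """
    if e < 0:
        raise ValueError("emergy flow must be >= 0")
    if not 0 <= grazing_days <= params.year_length_days:
        raise ValueError(
            f"grazing_days must lie in [0, {params.year_length_days}]"
        )
    factors = (
        (grazing_days / params.year_length_days)
        * params.anpp_fraction
        * params.consumed_fraction(area_kind)
    )
    if division_form:
        if factors == 0:
            raise ValueError("division form undefined for zero grazing days")
        return e / factors
    return e * factors


def allocate_pastures(
    lu: float,
    days_meadows_forests: float,
    days_mountain: float,
    climate: ClimateRecord,
    params: GrazingParameters,
    uev_table: UEVTable,
    division_form: bool = False,
) -> PastureEmergy:
    """Allocation for a herd with an explicit grazing calendar.

    For each area: grazed area from the stocking rate, full-NPP emergy E
    from the area's natural flows (same-origin resolved), then the
    consumption scaling for that area's grazing days.
    """
    result: dict[str, float] = {}
    for kind, days, e_key, a_key in (
        ("meadows_forests", days_meadows_forests,
         "e_meadows_forests", "allocated_meadows_forests"),
        ("mountain", days_mountain, "e_mountain", "allocated_mountain"),
    ):
        area = grazed_area(lu, params.stocking_rate(kind))
        e = solar_origin_emergy(area, climate, uev_table)
        result[e_key] = e
        if division_form and days == 0:
            result[a_key] = 0.0
        else:
            result[a_key] = grazing_emergy(e, days, params, kind, division_form)
    if division_form:
        # The audit form can exceed E, so the allocated<=E bound is not
        # enforced on its output.
        return PastureEmergy.model_construct(**result)
    return PastureEmergy(**result)


def natural_pastures_emergy(
    farm: Farm,
    climate: ClimateRecord,
    params: GrazingParameters,
    uev_table: UEVTable,
    division_form: bool = False,
) -> PastureEmergy:
    """Consumption-based natural-pasture emergy of a farm (both areas)."""
    return allocate_pastures(
        farm.livestock_units(),
        farm.calendar.days_meadows_forests,
        farm.calendar.days_mountain_pastures,
        climate,
        params,
        uev_table,
        division_form=division_form,
    )


def standard_pastures_emergy(
    farm: Farm,
    climate: ClimateRecord,
    params: GrazingParameters,
    uev_table: UEVTable,
) -> float:
    """Full-allocation baseline: the entire annual emergy flow of every
    grazing area the farm actually uses (calendar days > 0)."""
    pe = natural_pastures_emergy(farm, climate, params, uev_table)
    total = 0.0
    if farm.calendar.days_meadows_forests > 0:
        total += pe.e_meadows_forests
    if farm.calendar.days_mountain_pastures > 0:
        total += pe.e_mountain
    return total


def pasture_flow(total_sej: float) -> EmergyFlow:
    """Package allocated pasture emergy as a fully renewable R flow.

    The pasture emergy derives from the solar-origin natural flows, so its
    renewability factor is 1.
    """
    return EmergyFlow(
        resource_name="natural_pastures",
        total=total_sej,
        renewable=total_sej,
        nonrenewable=0.0,
        category="R",
    )
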