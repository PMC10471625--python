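"""Natural local emergy flows of a land area from climate parameters.

The renewable drivers (solar radiation, rain chemical potential, wind,
evapotranspiration) are computed as available energy over the area and
converted with their transformities; they share one solar origin, so only
the largest survives the double-counting rule.  Soil erosion is the natural
non-renewable flow: soil organic matter is used up faster than it renews.

Available-energy formulas (standard emergy-literature forms):

* solar:              area * insolation * (1 - albedo)
* rain chemical:      area * rainfall * water density * Gibbs energy of rain
* evapotranspiration: area * ET * water density * Gibbs energy of rain
* wind:               area * near-surface dissipated kinetic energy density
* soil erosion:       area * erosion rate * organic fraction * energy content
"""

from __future__ import annotations

import warnings
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .core import EmergyFlow, UEVTable, flow_emergy

__all__ = [
    "WATER_DENSITY_G_M3",
    "GIBBS_RAIN_J_G",
    "HA_TO_M2",
    "SOLAR_ORIGIN_TAG",
    "ClimateRecord",
    "natural_flows",
    "farm_natural_flows",
    "load_climate",
]

#: Density of rain water, g/m3.
WATER_DENSITY_G_M3 = 1.0e6
#: Gibbs free energy of rain relative to seawater, J/g.
GIBBS_RAIN_J_G = 4.94
HA_TO_M2 = 1.0e4
#: Origin tag shared by the four solar-derived renewable flows.
SOLAR_ORIGIN_TAG = "solar_derived"

#: Resource names the UEV table must provide for this module.
NATURAL_RESOURCES = (
    "sunlight",
    "rain_chemical_potential",
    "wind_kinetic",
    "evapotranspiration",
    "soil_erosion",
)


class ClimateRecord(BaseModel):
    """Climate and soil parameters of the study area, one record per run.

    A single record serves the whole area by default; per-valley records can
    be supplied through configuration.
    """

    insolation_j_m2: float = Field(ge=0, description="global radiation, J/m2/yr")
    albedo: float = Field(ge=0, le=1)
    rainfall_m: float = Field(ge=0, description="m/yr")
    evapotranspiration_m: float = Field(ge=0, description="m/yr")
    wind_energy_density_j_m2: float = Field(
        ge=0, description="dissipated near-surface kinetic energy, J/m2/yr"
    )
    erosion_rate_g_m2: float = Field(ge=0, description="soil loss, g/m2/yr")
    soil_organic_fraction: float = Field(ge=0, le=1)
    soil_energy_content_j_g: float = Field(ge=0, description="J per g organic matter")

    @model_validator(mode="after")
    def _flag_et_above_rainfall(self) -> "ClimateRecord":
        if self.evapotranspiration_m > self.rainfall_m:
            warnings.warn(
                "evapotranspiration exceeds rainfall in climate record",
                stacklevel=2,
            )
        return self


def load_climate(path: str | Path) -> ClimateRecord:
    """Load a climate record from a YAML mapping keyed by the field names."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ClimateRecord(**data)


def natural_flows(
    area_ha: float, climate: ClimateRecord, uev_table: UEVTable
) -> list[EmergyFlow]:
    """The five natural flows of an area, before same-origin resolution.

    Returns solar, rain chemical potential, wind and evapotranspiration
    (category R, shared solar origin) plus soil erosion (category N).
    Raises ``KeyError`` naming the resource if a UEV entry is missing.
    """
    if area_ha < 0:
        raise ValueError("area must be >= 0")
    for name in NATURAL_RESOURCES:
        if name not in uev_table:
            raise KeyError(f"no UEV entry for resource {name!r}")
    area_m2 = area_ha * HA_TO_M2
    energies = {
        "sunlight": area_m2 * climate.insolation_j_m2 * (1.0 - climate.albedo),
        "rain_chemical_potential": (
            area_m2 * climate.rainfall_m * WATER_DENSITY_G_M3 * GIBBS_RAIN_J_G
        ),
        "evapotranspiration": (
            area_m2
            * climate.evapotranspiration_m
            * WATER_DENSITY_G_M3
            * GIBBS_RAIN_J_G
        ),
        "wind_kinetic": area_m2 * climate.wind_energy_density_j_m2,
        "soil_erosion": (
            area_m2
            * climate.erosion_rate_g_m2
            * climate.soil_organic_fraction
            * climate.soil_energy_content_j_g
        ),
    }
    return [
        flow_emergy(energy, uev_table[name], quantity_unit="energy")
        for name, energy in energies.items()
    ]


def farm_natural_flows(
    area_ha: float, climate: ClimateRecord, uev_table: UEVTable
) -> list[EmergyFlow]:
    """Natural flows of an area after the same-origin maximum rule.

    Exactly one solar-origin renewable flow survives, alongside the soil
    erosion flow (N).
    """
    from .core import resolve_same_origin

    flows = natural_flows(area_ha, climate, uev_table)
    solar = [f for f in flows if f.origin_tag == SOLAR_ORIGIN_TAG]
    rest = [f for f in flows if f.origin_tag != SOLAR_ORIGIN_TAG]
    return resolve_same_origin(solar) + rest


def solar_origin_emergy(
    area_ha: float, climate: ClimateRecord, uev_table: UEVTable
) -> float:
    """Emergy of the winning solar-origin flow over an area (sej/yr).

    This is the renewable driver of the area's net primary production; a
    pasture's full-NPP emergy equals the emergy of the flows that drive it.
    """
    from .core import resolve_same_origin

    flows = natural_flows(area_ha, climate, uev_table)
    solar = [f for f in flows if f.origin_tag == SOLAR_ORIGIN_TAG]
    return resolve_same_origin(solar)[0].total
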