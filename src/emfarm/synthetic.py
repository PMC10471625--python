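"""Synthetic farm cohorts with the statistical structure of the study survey.

The generator draws each farm's structural and economic variables from
distributions calibrated to the survey's printed means and SDs (weaner and
weaner-finisher farm types), correlates the size variables (herd, area,
income, CAP payments) through a Gaussian copula, decomposes herd size into
integer head counts, and back-solves the purchased-input inventory so that
each item's share of the farm's total emergy flow matches a target
composition.

Distribution families: strictly positive right-skewed variables (areas,
herd, money, labour) are lognormal matched to the target mean/SD; grazing
days are normal truncated to [0, 366].  Both choices are generator design
decisions — the survey publishes only means and SDs.

Inventory back-solve
--------------------
For one farm, the natural-local emergy NL (farmland natural flows plus
consumption-allocated pastures plus soil erosion), the net services emergy
S and the labour emergy L are computed first from the drawn structure.  The
target composition assigns these three groups a combined share ``a`` of the
total and every inventory item i a share ``s_i`` (with a + sum(s_i) = 1).
The reference total is then Y_ref = (NL + S + L) / a and each item quantity
is ``q_i = s_i * Y_ref / UEV_i``, so that the assembled farm's total emergy
equals Y_ref exactly and every item lands exactly on its target share.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .core import Baseline, UEVTable, net_service_flow
from .farms import (
    EconomicAccount,
    Farm,
    GrazingCalendar,
    HerdComposition,
    InputInventory,
)
from .grazing import GrazingParameters, allocate_pastures
from .natural import ClimateRecord, farm_natural_flows

__all__ = [
    "VariableCalibration",
    "FarmTypeCalibration",
    "CohortCalibration",
    "generate_cohort",
    "generate_worked_farm",
]

#: Order of the copula-coupled variables; the first four are the size
#: variables sharing the rank-correlation target.
_VARIABLES = (
    "herd_lu",
    "agricultural_area_ha",
    "total_income_eur",
    "cap_payments_eur",
    "variable_costs_eur",
    "labour_wu",
    "grazing_days",
)
_N_CORRELATED = 4


class VariableCalibration(BaseModel):
    mean: float = Field(gt=0)
    sd: float = Field(ge=0)


class HerdRatios(BaseModel):
    """Herd composition per cow used to decompose livestock units."""

    bulls_per_cow: float = Field(0.02, ge=0)
    heifers_per_cow: float = Field(0.20, ge=0)
    calves_per_cow: float = Field(0.85, ge=0)

    @property
    def lu_per_cow(self) -> float:
        return (
            1.0
            + self.bulls_per_cow
            + 0.7 * self.heifers_per_cow
            + 0.4 * self.calves_per_cow
        )


class FarmTypeCalibration(BaseModel):
    variables: dict[str, VariableCalibration]
    #: Target share of total emergy for each purchased inventory item.
    emergy_shares: dict[str, float]
    #: Taxes paid as a fraction of CAP payments received.
    tax_to_cap_ratio: float = Field(ge=0, lt=1)

    @model_validator(mode="after")
    def _consistent(self) -> "FarmTypeCalibration":
        missing = [v for v in _VARIABLES if v not in self.variables]
        if missing:
            raise ValueError(f"calibration missing variables: {missing}")
        if any(s < 0 for s in self.emergy_shares.values()):
            raise ValueError("emergy shares must be >= 0")
        if sum(self.emergy_shares.values()) >= 1:
            raise ValueError("inventory emergy shares must sum to < 1")
        return self

    @property
    def anchor_share(self) -> float:
        """Combined target share of natural locals + services + labour."""
        return 1.0 - sum(self.emergy_shares.values())


class CohortCalibration(BaseModel):
    farm_types: dict[str, FarmTypeCalibration]
    rank_correlation: float = Field(0.6, ge=0, lt=1)
    mountain_day_fraction: float = Field(1.0 / 3.0, ge=0, le=1)
    herd_ratios: HerdRatios = Field(default_factory=HerdRatios)

    @classmethod
    def from_mapping(cls, data: dict) -> "CohortCalibration":
        return cls(**data)


def _lognormal_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(u, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return stats.lognorm.ppf(u, s=math.sqrt(sigma2), scale=math.exp(mu))


def _truncnorm_ppf(
    u: np.ndarray, mean: float, sd: float, lower: float = 0.0, upper: float = 366.0
) -> np.ndarray:
    if sd == 0:
        return np.full_like(u, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _copula_uniforms(
    n: int, rank_correlation: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-copula uniforms, shape (n, len(_VARIABLES)).

    The Spearman target converts to the Gaussian correlation via
    rho = 2 sin(pi * rho_s / 6).
    """
    k = len(_VARIABLES)
    rho = 2.0 * math.sin(math.pi * rank_correlation / 6.0)
    cov = np.eye(k)
    cov[:_N_CORRELATED, :_N_CORRELATED] = rho
    np.fill_diagonal(cov, 1.0)
    z = rng.standard_normal((n, k)) @ np.linalg.cholesky(cov).T
    return stats.norm.cdf(z)


def _decompose_herd(lu: float, ratios: HerdRatios) -> HerdComposition:
    """Integer head counts approximating a livestock-unit total."""
    if lu <= 0:
        return HerdComposition()
    cows = max(1, round(lu / ratios.lu_per_cow))
    return HerdComposition(
        cows=cows,
        bulls=round(ratios.bulls_per_cow * cows),
        heifers=round(ratios.heifers_per_cow * cows),
        calves=round(ratios.calves_per_cow * cows),
    )


def _natural_local_emergy(
    area_ha: float,
    lu: float,
    days_mf: float,
    days_mp: float,
    climate: ClimateRecord,
    params: GrazingParameters,
    uev: UEVTable,
) -> float:
    """Farmland natural flows (same-origin resolved + erosion) plus the
    consumption-allocated pasture emergy, sej/yr."""
    farmland = sum(f.total for f in farm_natural_flows(area_ha, climate, uev))
    pastures = allocate_pastures(lu, days_mf, days_mp, climate, params, uev)
    return farmland + pastures.total_allocated


def _build_farm(
    farm_id: str,
    farm_type: str,
    draws: dict[str, float],
    type_cal: FarmTypeCalibration,
    calibration: CohortCalibration,
    climate: ClimateRecord,
    params: GrazingParameters,
    uev: UEVTable,
) -> Farm:
    herd = _decompose_herd(draws["herd_lu"], calibration.herd_ratios)
    lu = herd.livestock_units()
    days = draws["grazing_days"]
    days_mp = days * calibration.mountain_day_fraction
    days_mf = days - days_mp
    cap = draws["cap_payments_eur"]
    taxes = cap * type_cal.tax_to_cap_ratio
    labour = draws["labour_wu"]

    nl = _natural_local_emergy(
        draws["agricultural_area_ha"], lu, days_mf, days_mp, climate, params, uev
    )
    services = net_service_flow(cap, taxes, uev["cap_payments"]).total
    labour_emergy = labour * uev["labour"].uev_value
    y_ref = (nl + services + labour_emergy) / type_cal.anchor_share

    inventory_fields: dict[str, float] = {}
    for resource, share in type_cal.emergy_shares.items():
        field = InputInventory.RESOURCE_FIELDS[resource]
        inventory_fields[field] = share * y_ref / uev[resource].uev_value

    return Farm(
        farm_id=farm_id,
        farm_type=farm_type,
        agricultural_area_ha=float(draws["agricultural_area_ha"]),
        herd=herd,
        calendar=GrazingCalendar(
            days_meadows_forests=float(days_mf),
            days_mountain_pastures=float(days_mp),
        ),
        inventory=InputInventory(**inventory_fields),
        economics=EconomicAccount(
            total_income_eur=float(draws["total_income_eur"]),
            cap_payments_eur=float(cap),
            taxes_paid_eur=float(taxes),
            variable_costs_eur=float(draws["variable_costs_eur"]),
        ),
        labour_wu=float(labour),
    )


def generate_cohort(
    n_weaner: int,
    n_finisher: int,
    calibration: Optional[CohortCalibration] = None,
    seed: int = 0,
    uev_table: Optional[UEVTable] = None,
    climate: Optional[ClimateRecord] = None,
    grazing_params: Optional[GrazingParameters] = None,
    working_baseline: Optional[Baseline] = None,
) -> list[Farm]:
    """Generate a mixed cohort of validated farms.

    Identical ``seed`` and calibration produce a bit-identical cohort.  The
    inventory back-solve evaluates natural flows and the consumption-based
    pasture allocation with the same defaults the assessment pipeline uses,
    so the generated cohort's emergy composition is consistent with the
    target shares when assessed under the default configuration.
    """
    from .defaults import (
        DEFAULT_WORKING_BASELINE,
        default_calibration,
        default_climate,
        default_grazing_params,
        default_uev_table,
    )

    if n_weaner < 0 or n_finisher < 0:
        raise ValueError("cohort counts must be >= 0")
    calibration = calibration or default_calibration()
    climate = climate or default_climate()
    grazing_params = grazing_params or default_grazing_params()
    baseline = working_baseline or DEFAULT_WORKING_BASELINE
    uev = (uev_table or default_uev_table()).rescaled(baseline)

    rng = np.random.default_rng(seed)
    farms: list[Farm] = []
    for farm_type, n, prefix in (
        ("weaner", n_weaner, "W"),
        ("weaner_finisher", n_finisher, "F"),
    ):
        if n == 0:
            continue
        type_cal = calibration.farm_types[farm_type]
        u = _copula_uniforms(n, calibration.rank_correlation, rng)
        columns: dict[str, np.ndarray] = {}
        for j, var in enumerate(_VARIABLES):
            cal = type_cal.variables[var]
            if var == "grazing_days":
                columns[var] = _truncnorm_ppf(u[:, j], cal.mean, cal.sd)
            else:
                columns[var] = _lognormal_ppf(u[:, j], cal.mean, cal.sd)
        for i in range(n):
            draws = {var: float(columns[var][i]) for var in _VARIABLES}
            farms.append(
                _build_farm(
                    f"{prefix}{i:04d}", farm_type, draws, type_cal,
                    calibration, climate, grazing_params, uev,
                )
            )
    return farms


def generate_worked_farm() -> Farm:
    """A fixed, fully specified farm whose every emergy flow is
    hand-recomputable (used in the documentation's worked example)."""
    return Farm(
        farm_id="WORKED-01",
        farm_type="weaner",
        agricultural_area_ha=50.0,
        herd=HerdComposition(cows=50, bulls=1, heifers=10, calves=40),
        calendar=GrazingCalendar(
            days_meadows_forests=150.0, days_mountain_pastures=100.0
        ),
        inventory=InputInventory(
            straw_g=15.0e6,
            forage_g=20.0e6,
            concentrates_g=4.0e6,
            vitamin_mineral_supplements_g=0.2e6,
            fuel_j=1.0e11,
            electricity_j=2.0e9,
            fertiliser_g=2.0e6,
            veterinary_medicines_eur=4000.0,
            machinery_depreciation_eur=6000.0,
            buildings_depreciation_eur=10000.0,
            small_equipment_eur=2000.0,
        ),
        economics=EconomicAccount(
            total_income_eur=45000.0,
            cap_payments_eur=30000.0,
            taxes_paid_eur=800.0,
            variable_costs_eur=25000.0,
        ),
        labour_wu=1.5,
    )
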