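"""End-to-end assessment runs: farms + UEV table + climate + parameters ->
per-farm emergy accounts, indicators, classifications, cohort summaries and
resource-group shares, with reproducible CSV/JSON outputs.

Weaner and weaner-finisher farms have different outputs and are therefore
summarised separately, never pooled.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .core import (
    Baseline,
    EmergyAccount,
    EmergyFlow,
    UEVTable,
    aggregate_account,
    flow_emergy,
    net_service_flow,
)
from .defaults import (
    DEFAULT_EM_EURO,
    DEFAULT_WORKING_BASELINE,
    default_climate,
    default_grazing_params,
    default_uev_table,
)
from .farms import Farm, read_farm_table
from .grazing import (
    GrazingParameters,
    natural_pastures_emergy,
    pasture_flow,
    standard_pastures_emergy,
)
from .indicators import (
    INDICATOR_NAMES,
    classify_farm,
    compute_indicators,
    summarise_cohort,
)
from .natural import ClimateRecord, farm_natural_flows, load_climate

__all__ = [
    "RESOURCE_GROUPS",
    "RunConfig",
    "RunResult",
    "assess_farm",
    "run_assessment",
    "compare_allocations",
]

logger = logging.getLogger("emfarm")

AllocationMode = Literal["consumption", "standard", "division_form_audit"]

#: Resource -> reporting group (the cohort-share taxonomy).
RESOURCE_GROUPS: dict[str, str] = {
    "sunlight": "natural_locals",
    "rain_chemical_potential": "natural_locals",
    "evapotranspiration": "natural_locals",
    "wind_kinetic": "natural_locals",
    "soil_erosion": "natural_locals",
    "natural_pastures": "natural_locals",
    "straw": "animal_feeds",
    "corn": "animal_feeds",
    "forage": "animal_feeds",
    "vitamin_mineral_supplements": "animal_feeds",
    "concentrates": "animal_feeds",
    "seeds": "crop_inputs",
    "fertiliser": "crop_inputs",
    "phytochemicals": "crop_inputs",
    "machinery_depreciation": "others",
    "buildings_depreciation": "others",
    "small_equipment": "others",
    "veterinary_medicines": "others",
    "electricity": "others",
    "fuel": "others",
    "labour": "others",
    "services_net": "services",
}


class RunConfig(BaseModel):
    """Configuration of one assessment run.

    Paths left unset fall back to the packaged defaults; ``farms_path`` is
    required.
    """

    farms_path: str
    uev_table_path: Optional[str] = None
    climate_path: Optional[str] = None
    grazing_params_path: Optional[str] = None
    working_baseline_sej: float = Field(DEFAULT_WORKING_BASELINE.value, gt=0)
    em_euro: float = Field(DEFAULT_EM_EURO, gt=0)
    allocation_mode: AllocationMode = "consumption"
    output_dir: str = "emfarm-output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory result of one run, writable as CSV + JSON sidecar."""

    accounts: pd.DataFrame
    indicators: pd.DataFrame
    summaries: pd.DataFrame
    shares: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.accounts.to_csv(out / "accounts.csv", index=False)
        self.indicators.to_csv(out / "indicators.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        self.shares.to_csv(out / "shares.csv", index=False)
        with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def assess_farm(
    farm: Farm,
    uev: UEVTable,
    climate: ClimateRecord,
    params: GrazingParameters,
    allocation_mode: AllocationMode = "consumption",
) -> tuple[EmergyAccount, list[EmergyFlow]]:
    """Assemble and aggregate all emergy flows of one farm.

    ``uev`` must already be rescaled to the working baseline.  Returns the
    account and the per-resource flow list it was aggregated from.
    """
    flows: list[EmergyFlow] = []
    flows.extend(farm_natural_flows(farm.agricultural_area_ha, climate, uev))

    if allocation_mode == "standard":
        pasture_total = standard_pastures_emergy(farm, climate, params, uev)
    else:
        pe = natural_pastures_emergy(
            farm, climate, params, uev,
            division_form=(allocation_mode == "division_form_audit"),
        )
        pasture_total = pe.total_allocated
    if pasture_total > 0:
        flows.append(pasture_flow(pasture_total))

    for resource, quantity in farm.inventory.items():
        if quantity > 0:
            flows.append(flow_emergy(quantity, uev[resource]))
    if farm.labour_wu > 0:
        flows.append(flow_emergy(farm.labour_wu, uev["labour"], quantity_unit="labour"))
    flows.append(
        net_service_flow(
            farm.economics.cap_payments_eur,
            farm.economics.taxes_paid_eur,
            uev["cap_payments"],
        )
    )
    return aggregate_account(flows), flows


def _load_inputs(config: RunConfig):
    uev_raw = (
        UEVTable.from_csv(config.uev_table_path)
        if config.uev_table_path
        else default_uev_table()
    )
    baseline = Baseline(name="working", value=config.working_baseline_sej)
    for entry in uev_raw:
        if entry.source_baseline != baseline.value:
            logger.info(
                "rescaling UEV %s: %.6g -> %.6g sej/unit (baseline %.4g -> %.4g)",
                entry.resource_name, entry.uev_value,
                entry.uev_value * baseline.value / entry.source_baseline,
                entry.source_baseline, baseline.value,
            )
    uev = uev_raw.rescaled(baseline)
    climate = (
        load_climate(config.climate_path) if config.climate_path else default_climate()
    )
    if config.grazing_params_path:
        with open(config.grazing_params_path, "r", encoding="utf-8") as fh:
            params = GrazingParameters(**yaml.safe_load(fh))
    else:
        params = default_grazing_params()
    return uev, climate, params


def run_assessment(
    config: RunConfig,
    farms: Optional[list[Farm]] = None,
    write_outputs: bool = True,
) -> RunResult:
    """Run the full assessment described by ``config``.

    Farms failing validation abort the run with a farm-indexed report
    (fail-fast: silently skipping farms would bias cohort summaries).
    Deterministic given inputs; outputs are byte-identical across runs.
    """
    logger.info(
        "allocation mode %r: pasture emergy uses the %s form",
        config.allocation_mode,
        "multiplicative consumption" if config.allocation_mode == "consumption"
        else config.allocation_mode,
    )
    uev, climate, params = _load_inputs(config)
    if farms is None:
        farms = read_farm_table(config.farms_path)

    account_rows, indicator_rows, share_rows = [], [], []
    for farm in farms:
        try:
            account, flows = assess_farm(
                farm, uev, climate, params, config.allocation_mode
            )
            ind = compute_indicators(
                account, farm.economics.total_income_eur, config.em_euro
            )
        except Exception as exc:
            raise RuntimeError(f"farm {farm.farm_id!r}: {exc}") from exc
        cls = classify_farm(ind)
        account_rows.append(
            {"farm_id": farm.farm_id, "farm_type": farm.farm_type, **account.as_dict()}
        )
        indicator_rows.append(
            {
                "farm_id": farm.farm_id,
                "farm_type": farm.farm_type,
                **{k: getattr(ind, k) for k in INDICATOR_NAMES},
                "nonfinite": ";".join(ind.nonfinite),
                **cls.model_dump(),
            }
        )
        y = account.Y
        for flow in flows:
            share_rows.append(
                {
                    "farm_id": farm.farm_id,
                    "farm_type": farm.farm_type,
                    "resource": flow.resource_name,
                    "group": RESOURCE_GROUPS[flow.resource_name],
                    "emergy_sej": flow.total,
                    "share": flow.total / y if y > 0 else math.nan,
                }
            )

    accounts = pd.DataFrame(account_rows)
    indicators = pd.DataFrame(indicator_rows)
    shares = pd.DataFrame(share_rows)

    summary_rows = []
    for farm_type, group in indicators.groupby("farm_type", sort=True):
        for name in INDICATOR_NAMES:
            values = [v for v in group[name] if math.isfinite(v)]
            if not values:
                continue
            summ = summarise_cohort(values)
            summary_rows.append(
                {"farm_type": farm_type, "indicator": name,
                 **summ.model_dump(exclude={"outliers"}),
                 "n_outliers": len(summ.outliers)}
            )
    summaries = pd.DataFrame(summary_rows)

    import emfarm

    result = RunResult(
        accounts=accounts,
        indicators=indicators,
        summaries=summaries,
        shares=shares,
        metadata={
            "config": config.model_dump(),
            "config_hash": config.config_hash(),
            "emfarm_version": emfarm.__version__,
            "n_farms": len(farms),
            "allocation_mode": config.allocation_mode,
        },
    )
    if write_outputs:
        result.write(config.output_dir)
    return result


def compare_allocations(
    farms: list[Farm],
    uev: Optional[UEVTable] = None,
    climate: Optional[ClimateRecord] = None,
    params: Optional[GrazingParameters] = None,
    working_baseline: Optional[Baseline] = None,
) -> pd.DataFrame:
    """Per-farm natural-pasture emergy under both allocations.

    Returns one row per farm with the consumption-based allocation, the
    standard full-flow baseline, and the reduction 1 - allocated/standard.
    Farms whose baseline is zero (no grazing at all) are flagged with a NaN
    reduction and a warning, and should be excluded from cohort means.
    """
    baseline = working_baseline or DEFAULT_WORKING_BASELINE
    uev = (uev or default_uev_table()).rescaled(baseline)
    climate = climate or default_climate()
    params = params or default_grazing_params()
    rows = []
    for farm in farms:
        allocated = natural_pastures_emergy(farm, climate, params, uev).total_allocated
        standard = standard_pastures_emergy(farm, climate, params, uev)
        if standard == 0:
            warnings.warn(
                f"farm {farm.farm_id!r}: standard pasture emergy is 0; "
                "excluded from mean reduction",
                stacklevel=2,
            )
            reduction = math.nan
        else:
            reduction = 1.0 - allocated / standard
        rows.append(
            {
                "farm_id": farm.farm_id,
                "farm_type": farm.farm_type,
                "allocated_sej": allocated,
                "standard_sej": standard,
                "reduction": reduction,
            }
        )
    return pd.DataFrame(rows)


def mean_reduction(comparison: pd.DataFrame) -> float:
    """Cohort-mean reduction, ignoring flagged (NaN) farms."""
    return float(comparison["reduction"].dropna().mean())
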