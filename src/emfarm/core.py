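"""Emergy conversion core.

Converts resource flows into solar emergy (sej) with unit emergy values
(UEVs), homogenises UEVs to a common global emergy baseline (GEB), splits
every flow into renewable and non-renewable fractions with a renewability
factor, applies the same-origin maximum rule for co-derived natural flows,
and aggregates per-farm flows into the R/N/P/S emergy account.

Notation
--------
R   natural renewable local resources (sej/yr)
N   natural non-renewable local resources (sej/yr)
P   purchased resources, split into renewable Pr and non-renewable Pn
S   services, split into Sr and Sn
Y   emergy yield, Y = R + N + P + S (held as an identity by construction)
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import ClassVar, Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "REL_TOL",
    "UEVEntry",
    "Baseline",
    "EmergyFlow",
    "EmergyAccount",
    "UEVTable",
    "rescale_uev",
    "flow_emergy",
    "money_to_emergy",
    "resolve_same_origin",
    "aggregate_account",
]

#: Relative tolerance for all sej identity checks.
REL_TOL = 1e-9

Category = Literal["R", "N", "P", "S"]
UnitClass = Literal["energy", "mass", "money", "labour"]


class Baseline(BaseModel):
    """A global emergy baseline: total annual emergy driving the geobiosphere."""

    name: str
    value: float = Field(gt=0, description="sej/yr")


class UEVEntry(BaseModel):
    """Unit emergy value for one resource.

    ``uev_value`` is sej per unit of the resource's ``unit_class`` (J for
    energy, g for mass, EUR for money, work-unit-year for labour).
    ``source_baseline`` is the GEB under which the UEV was published; UEVs
    must be rescaled to a common working baseline before use.  The
    renewability factor is the fraction of the resource's emergy that
    derives from renewable sources.
    """

    resource_name: str
    uev_value: float = Field(gt=0)
    unit_class: UnitClass
    source_baseline: float = Field(gt=0, description="sej/yr")
    renewability_factor: float = Field(ge=0, le=1)
    category: Category
    origin_tag: Optional[str] = None
    reference: str = ""


class EmergyFlow(BaseModel):
    """One resource's emergy contribution, split by renewability."""

    resource_name: str
    total: float = Field(ge=0, description="sej/yr")
    renewable: float = Field(ge=0)
    nonrenewable: float = Field(ge=0)
    category: Category
    origin_tag: Optional[str] = None

    @model_validator(mode="after")
    def _parts_sum_to_total(self) -> "EmergyFlow":
        if not math.isclose(
            self.renewable + self.nonrenewable, self.total,
            rel_tol=REL_TOL, abs_tol=1e-300,
        ):
            raise ValueError(
                f"{self.resource_name}: renewable + nonrenewable != total"
            )
        return self


class EmergyAccount(BaseModel):
    """Per-farm emergy totals by resource class.

    ``Y`` is a derived property, so the identity Y = R+N+Pr+Pn+Sr+Sn holds
    exactly by construction.
    """

    R: float = Field(0.0, ge=0)
    N: float = Field(0.0, ge=0)
    Pr: float = Field(0.0, ge=0)
    Pn: float = Field(0.0, ge=0)
    Sr: float = Field(0.0, ge=0)
    Sn: float = Field(0.0, ge=0)

    @property
    def P(self) -> float:
        return self.Pr + self.Pn

    @property
    def S(self) -> float:
        return self.Sr + self.Sn

    @property
    def Y(self) -> float:
        return self.R + self.N + self.Pr + self.Pn + self.Sr + self.Sn

    def as_dict(self) -> dict[str, float]:
        return {
            "R": self.R, "N": self.N, "Pr": self.Pr, "Pn": self.Pn,
            "Sr": self.Sr, "Sn": self.Sn, "Y": self.Y,
        }


def rescale_uev(entry: UEVEntry, target: Baseline) -> UEVEntry:
    """Homogenise a UEV to the working baseline.

    UEVs scale linearly with the GEB under which they were derived:
    ``uev_target = uev_source * target / source``.
    """
    return entry.model_copy(
        update={
            "uev_value": entry.uev_value * target.value / entry.source_baseline,
            "source_baseline": target.value,
        }
    )


def flow_emergy(
    quantity: float,
    entry: UEVEntry,
    quantity_unit: Optional[UnitClass] = None,
) -> EmergyFlow:
    """Convert a physical quantity to an emergy flow via its UEV.

    ``quantity`` must be expressed in the entry's unit class (pass
    ``quantity_unit`` to have this asserted).  The renewability factor
    splits the total into renewable and non-renewable parts.
    """
    if quantity < 0:
        raise ValueError(f"{entry.resource_name}: quantity must be >= 0")
    if quantity_unit is not None and quantity_unit != entry.unit_class:
        raise ValueError(
            f"{entry.resource_name}: quantity unit {quantity_unit!r} does not "
            f"match UEV unit class {entry.unit_class!r}"
        )
    total = quantity * entry.uev_value
    renewable = total * entry.renewability_factor
    return EmergyFlow(
        resource_name=entry.resource_name,
        total=total,
        renewable=renewable,
        nonrenewable=total - renewable,
        category=entry.category,
        origin_tag=entry.origin_tag,
    )


def money_to_emergy(amount_eur: float, em_euro: float) -> float:
    """Emergy supporting ``amount_eur`` of economic product (may be negative
    for deductions such as taxes)."""
    if em_euro <= 0:
        raise ValueError("em_euro must be > 0")
    return amount_eur * em_euro


def resolve_same_origin(flows: list[EmergyFlow]) -> list[EmergyFlow]:
    """Keep only the largest of several co-derived natural flows.

    Solar radiation, wind, rain and evapotranspiration all derive from the
    same solar source; counting more than one double-counts that source, so
    only the flow with the highest emergy value is retained.  Ties break by
    alphabetical resource name (fixed, documented order).
    """
    if not flows:
        raise ValueError("resolve_same_origin: empty flow list")
    tags = {f.origin_tag for f in flows}
    if len(tags) != 1 or None in tags:
        raise ValueError("all flows must share one non-null origin_tag")
    if any(f.category != "R" for f in flows):
        raise ValueError("same-origin resolution applies to category-R flows")
    winner = min(flows, key=lambda f: (-f.total, f.resource_name))
    return [winner]


def aggregate_account(flows: Iterable[EmergyFlow]) -> EmergyAccount:
    """Sum classified flows into the R/N/P/S account.

    Same-origin resolution must already have been applied to the natural
    flows; this function only sums.
    """
    totals = {"R": 0.0, "N": 0.0, "Pr": 0.0, "Pn": 0.0, "Sr": 0.0, "Sn": 0.0}
    for flow in flows:
        if flow.category == "R":
            totals["R"] += flow.total
        elif flow.category == "N":
            totals["N"] += flow.total
        elif flow.category == "P":
            totals["Pr"] += flow.renewable
            totals["Pn"] += flow.nonrenewable
        elif flow.category == "S":
            totals["Sr"] += flow.renewable
            totals["Sn"] += flow.nonrenewable
        else:  # pragma: no cover - Literal already guards this
            raise ValueError(f"unknown category {flow.category!r}")
    return EmergyAccount(**totals)


def net_service_flow(
    cap_payments_eur: float,
    taxes_paid_eur: float,
    entry: UEVEntry,
) -> EmergyFlow:
    """Net services flow: CAP payments received minus taxes paid.

    Taxes enter negatively before conversion; the net flow is floored at
    zero with a warning when taxes exceed subsidies, since the account
    components are non-negative.
    """
    if entry.unit_class != "money":
        raise ValueError("services entry must be a money UEV")
    net_eur = cap_payments_eur - taxes_paid_eur
    if net_eur < 0:
        warnings.warn(
            "taxes exceed CAP payments; net services floored at 0", stacklevel=2
        )
        net_eur = 0.0
    total = money_to_emergy(net_eur, entry.uev_value)
    renewable = total * entry.renewability_factor
    return EmergyFlow(
        resource_name="services_net",
        total=total,
        renewable=renewable,
        nonrenewable=total - renewable,
        category="S",
    )


class UEVTable:
    """A collection of UEV entries keyed by resource name.

    The shipped default table (``emfarm/data/uev_table.csv``) documents a
    source and a source baseline per entry and is user-replaceable.
    """

    COLUMNS: ClassVar[list[str]] = [
        "resource_name", "uev_value", "unit_class", "source_baseline",
        "renewability_factor", "category", "origin_tag", "reference",
    ]

    def __init__(self, entries: Iterable[UEVEntry]):
        self._entries: dict[str, UEVEntry] = {}
        for entry in entries:
            if entry.resource_name in self._entries:
                raise ValueError(f"duplicate UEV entry {entry.resource_name!r}")
            self._entries[entry.resource_name] = entry

    def __getitem__(self, resource_name: str) -> UEVEntry:
        try:
            return self._entries[resource_name]
        except KeyError:
            raise KeyError(f"no UEV entry for resource {resource_name!r}") from None

    def __contains__(self, resource_name: str) -> bool:
        return resource_name in self._entries

    def __iter__(self) -> Iterable[UEVEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UEVTable":
        # round_trip parsing keeps scientific-notation values bit-exact
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"UEV table missing columns: {missing}")
        entries = []
        for _, row in df.iterrows():
            origin = row["origin_tag"]
            entries.append(
                UEVEntry(
                    resource_name=str(row["resource_name"]),
                    uev_value=float(row["uev_value"]),
                    unit_class=str(row["unit_class"]),
                    source_baseline=float(row["source_baseline"]),
                    renewability_factor=float(row["renewability_factor"]),
                    category=str(row["category"]),
                    origin_tag=None if pd.isna(origin) else str(origin),
                    reference="" if pd.isna(row["reference"]) else str(row["reference"]),
                )
            )
        return cls(entries)

    def rescaled(self, target: Baseline) -> "UEVTable":
        """Return a copy with every entry homogenised to ``target``."""
        return UEVTable(rescale_uev(e, target) for e in self)
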