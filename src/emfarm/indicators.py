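"""Emergy sustainability indicators, threshold classification, cohort summaries.

Six per-farm indicators are computed from the R/N/P/S account:

* %R   = R / Y                        renewability
* EYR  = Y / (P + S)                  net contribution to the socio-economy
* EIR  = (P + S) / (R + N)            market dependency
* EER  = Y / (income x em-euro)       market trade status
* ELR  = (N + P + S) / R              environmental load
* ESI  = EYR_alt / ELR_alt            sustainability

ESI uses the alternative formulation that moves the renewable fractions of
purchased resources and services to the renewable side:
EYR_alt = Y / (Pn + Sn) and ELR_alt = (N + Pn + Sn) / (R + Pr + Sr).
When Pr = Sr = 0 this collapses to the classical EYR / ELR.

Thresholds (boundaries follow the printed inequalities verbatim):
EYR <= 2 means no significant net emergy contribution; EIR >= 1 market
dependent; EER > 1 net emergy donor (trade disadvantage); ELR >= 2
moderate-to-high environmental load; ESI <= 1 unsustainable, 1 < ESI <= 5
sustainable in the short term, ESI > 5 in the long term.  The overlap at
ESI = 1 between the printed bands resolves to unsustainable.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .core import EmergyAccount, money_to_emergy

__all__ = [
    "IndicatorSet",
    "SustainabilityClass",
    "CohortSummary",
    "compute_indicators",
    "classify_farm",
    "summarise_cohort",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = ("percent_R", "percent_R_extended", "EYR", "EIR", "EER", "ELR", "ESI")


class IndicatorSet(BaseModel):
    """The six indicators plus the alternative-formulation intermediates.

    Divisions by zero yield ``inf`` and the indicator's name is recorded in
    ``nonfinite``; no exception is raised.
    """

    percent_R: float = Field(ge=0, le=1)
    percent_R_extended: float = Field(ge=0, le=1)
    EYR: float = Field(ge=0)
    EIR: float = Field(ge=0)
    EER: float = Field(ge=0)
    ELR: float = Field(ge=0)
    ESI: float = Field(ge=0)
    EYR_alternative: float = Field(ge=0)
    ELR_alternative: float = Field(ge=0)
    nonfinite: tuple[str, ...] = ()


class SustainabilityClass(BaseModel):
    """Threshold classification of one farm, derived deterministically."""

    net_contribution: Literal["significant", "not_significant"]
    market_dependent: bool
    #: True when the farm receives at least as much emergy through the market
    #: as it delivers (EER <= 1); farms with EER > 1 are net emergy donors.
    trade_advantage: bool
    environmental_load: Literal["low", "moderate-high"]
    sustainability: Literal[
        "unsustainable", "short_term_sustainable", "long_term_sustainable"
    ]


class CohortSummary(BaseModel):
    """Distribution statistics of one indicator across one farm type."""

    n: int = Field(ge=1)
    mean: float
    #: Sample SD (n-1 denominator); None (flagged) for a single value.
    sd: Optional[float]
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return math.inf if num > 0 else 0.0
    return num / den


def compute_indicators(
    account: EmergyAccount, income_eur: float, em_euro: float
) -> IndicatorSet:
    """Compute the six indicators for one farm.

    ``income_eur`` is the farm's product-sale income (not including
    subsidies): EER compares the emergy yield with the emergy equivalent of
    the money actually paid for the product.
    """
    if income_eur < 0:
        raise ValueError("income must be >= 0")
    y = account.Y
    if y == 0:
        raise ValueError("empty system: Y = 0")
    flags: list[str] = []
    p, s = account.P, account.S
    percent_r = account.R / y
    percent_r_ext = (account.R + account.Pr + account.Sr) / y
    eyr = _ratio(y, p + s, "EYR", flags)
    eir = _ratio(p + s, account.R + account.N, "EIR", flags)
    eer = _ratio(y, money_to_emergy(income_eur, em_euro), "EER", flags)
    elr = _ratio(account.N + p + s, account.R, "ELR", flags)
    eyr_alt = _ratio(y, account.Pn + account.Sn, "EYR_alternative", flags)
    elr_alt = _ratio(
        account.N + account.Pn + account.Sn,
        account.R + account.Pr + account.Sr,
        "ELR_alternative",
        flags,
    )
    if math.isinf(eyr_alt) and elr_alt == 0:
        esi = math.inf
        flags.append("ESI")
    else:
        esi = _ratio(eyr_alt, elr_alt, "ESI", flags)
    return IndicatorSet(
        percent_R=percent_r,
        percent_R_extended=percent_r_ext,
        EYR=eyr,
        EIR=eir,
        EER=eer,
        ELR=elr,
        ESI=esi,
        EYR_alternative=eyr_alt,
        ELR_alternative=elr_alt,
        nonfinite=tuple(flags),
    )


def classify_farm(ind: IndicatorSet) -> SustainabilityClass:
    """Apply the sustainability thresholds to one indicator set.

    Infinite values map through the same inequalities (an infinite EYR is a
    significant net contribution, an infinite ELR a moderate-high load, an
    infinite ESI long-term sustainable).
    """
    if ind.ESI <= 1:
        sustainability = "unsustainable"
    elif ind.ESI <= 5:
        sustainability = "short_term_sustainable"
    else:
        sustainability = "long_term_sustainable"
    return SustainabilityClass(
        net_contribution="not_significant" if ind.EYR <= 2 else "significant",
        market_dependent=ind.EIR >= 1,
        trade_advantage=not ind.EER > 1,
        environmental_load="moderate-high" if ind.ELR >= 2 else "low",
        sustainability=sustainability,
    )


def summarise_cohort(values: Sequence[float]) -> CohortSummary:
    """Distribution summary of one indicator across a cohort.

    Quartiles use linear interpolation between order statistics; whiskers
    and outliers follow the Tukey 1.5 x IQR convention (whiskers reach the
    most extreme observations inside the fences).
    """
    arr = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if len(values) == 0:
        raise ValueError("summarise_cohort: empty value list")
    if arr.size == 0:
        raise ValueError("summarise_cohort: no finite values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return CohortSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )
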