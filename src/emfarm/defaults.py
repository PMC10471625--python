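"""Packaged default inputs: UEV table, climate record, grazing parameters,
cohort calibration, working baseline and em-euro ratio.

All of these are package defaults, documented per entry in the shipped
files, and user-replaceable through the run configuration.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core import Baseline, UEVTable
from .grazing import GrazingParameters
from .natural import ClimateRecord, load_climate

_DATA_DIR = Path(__file__).parent / "data"

#: Working global emergy baseline all UEVs are rescaled to before use.
DEFAULT_WORKING_BASELINE = Baseline(name="GEB-12.0e24", value=1.2e25)

#: Emergy per euro of national economic product, sej/EUR (package default).
DEFAULT_EM_EURO = 1.1e12


def default_uev_table() -> UEVTable:
    """The shipped UEV table, NOT yet rescaled to a working baseline."""
    return UEVTable.from_csv(_DATA_DIR / "uev_table.csv")


def default_climate() -> ClimateRecord:
    return load_climate(_DATA_DIR / "climate.yaml")


def default_grazing_params() -> GrazingParameters:
    with open(_DATA_DIR / "grazing_params.yaml", "r", encoding="utf-8") as fh:
        return GrazingParameters(**yaml.safe_load(fh))


def default_calibration():
    from .synthetic import CohortCalibration

    with open(_DATA_DIR / "calibration.yaml", "r", encoding="utf-8") as fh:
        return CohortCalibration.from_mapping(yaml.safe_load(fh))
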