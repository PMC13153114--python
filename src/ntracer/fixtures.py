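"""Packaged study tables: in-situ environment, volumetric and specific uptake rates.

The three tables are shipped as tidy CSVs with explicit missing cells (the
printed tables use an en-dash) and units encoded in the column names. Lake
codes: LA Lake Agawam, LCP the Lake in Central Park, LE western Lake Erie
(sites M1/M2), HE Honeoye Lake, NT Lake Neatahwanta. Glutamic-acid values
printed with an asterisk (footnote illegible in the source) are stored
verbatim with ``glu_flag = 1`` and not interpreted.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["load_fixture", "table2_long", "PAPER_TSI", "FORM_COLUMNS", "fixture_sha256"]

_FILES = {
    "table1": "table1_environment.csv",
    "table2": "table2_volumetric_rates.csv",
    "table3": "table3_specific_rates.csv",
}

#: Published composite TSI per lake (Secchi record unpublished, so these are
#: classification inputs, not recomputable quantities).
PAPER_TSI = {"LCP": 92.8, "LA": 78.8, "LE": 69.2, "HE": 72.9, "NT": 67.5}

#: Lake morphometry referenced in the study (km^2, m).
LAKE_MORPHOMETRY = {
    "LCP": {"area_km2": 0.5, "depth_m": 2.0},
    "LA": {"area_km2": 0.5, "depth_m": 3.0},
    "HE": {"area_km2": 7.2, "depth_m": 9.0},
    "NT": {"area_km2": 3.1, "depth_m": 4.0},
}

FORM_COLUMNS = {
    "NO3": {"table2": "no3_umol_l_h", "table3": "no3_per_d"},
    "NH4": {"table2": "nh4_umol_l_h", "table3": "nh4_per_d"},
    "UREA": {"table2": "urea_umol_l_h", "table3": "urea_per_d"},
    "GLU": {"table2": "glu_umol_l_h", "table3": "glu_per_d"},
}


def _path(name: str) -> Path:
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FILES)}")
    return Path(resources.files("ntracer.data") / _FILES[name])


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged tables ('table1', 'table2', 'table3')."""
    df = pd.read_csv(_path(name), na_values=["", "–", "-"])
    return df


def fixture_sha256(name: str) -> str:
    """Checksum of the raw fixture file (drift guard)."""
    return hashlib.sha256(_path(name).read_bytes()).hexdigest()


def table2_long() -> pd.DataFrame:
    """Tidy volumetric rates: (lake, site, date, fraction, form, v_volumetric)."""
    wide = load_fixture("table2")
    long = wide.melt(
        id_vars=["lake", "site", "date", "fraction"],
        value_vars=[c["table2"] for c in FORM_COLUMNS.values()],
        var_name="form",
        value_name="v_volumetric",
    )
    col_to_form = {v["table2"]: k for k, v in FORM_COLUMNS.items()}
    long["form"] = long["form"].map(col_to_form)
    return long
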