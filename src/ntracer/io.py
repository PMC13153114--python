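"""Readers and writers for the long-format incubation and rate CSV dialects.

Incubation tables carry one row per (lake, date, fraction, N form) with the
measured atom% values, PON and duration; missing values are empty cells (an
en-dash is also accepted on read, matching how the printed tables mark
gaps). Dates are ISO-8601. PON may arrive in mg N/L (as reported) or
umol N/L (as the rate equation needs); the converter is explicit, never
silent.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .isotope import (
    NAT_ABUNDANCE_AP,
    AtomPercent,
    Fraction,
    IncubationRecord,
    NForm,
    pon_mg_to_umol,
    rate_record,
)

__all__ = ["read_incubations", "compute_rates", "write_rates", "INCUBATION_COLUMNS"]

INCUBATION_COLUMNS = [
    "lake",
    "date",
    "fraction",
    "form",
    "na_pre_atompct",
    "ap_post_atompct",
    "ap_enr_atompct",
    "pon_umol_l",
    "duration_h",
]

_NA_MARKERS = ["", "–", "-", "NA"]


def read_incubations(
    path: str | Path,
    *,
    pon_units: str = "umol",
    na_default: float = NAT_ABUNDANCE_AP,
) -> list[IncubationRecord]:
    """Read a long-format incubation CSV into validated records.

    ``pon_units='mg'`` converts PON from mg N/L on read. Rows lacking a
    measured pre-incubation atom% fall back to ``na_default`` (the natural-
    abundance constant); measured values always take precedence. Rows with
    any other missing measurement are skipped with a warning.
    """
    pon_col = "pon_mg_l" if pon_units == "mg" else "pon_umol_l"
    df = pd.read_csv(path, na_values=_NA_MARKERS)
    missing = [c for c in INCUBATION_COLUMNS if c not in df.columns and c != "pon_umol_l"]
    if pon_col not in df.columns:
        raise ValueError(f"missing PON column {pon_col!r}")
    needed = ["ap_post_atompct", "ap_enr_atompct", pon_col, "duration_h"]
    records = []
    for i, row in df.iterrows():
        if row[needed].isna().any():
            warnings.warn(f"row {i}: incomplete measurement, skipped")
            continue
        na_pre = row.get("na_pre_atompct")
        na_pre = na_default if pd.isna(na_pre) else float(na_pre)
        pon = float(row[pon_col])
        if pon_units == "mg":
            pon = pon_mg_to_umol(pon)
        records.append(
            IncubationRecord(
                lake=str(row["lake"]),
                date=str(row["date"]),
                fraction=Fraction(str(row["fraction"])),
                form=NForm(str(row["form"])),
                na_pre=AtomPercent(na_pre),
                ap_post=AtomPercent(float(row["ap_post_atompct"])),
                ap_enr=AtomPercent(float(row["ap_enr_atompct"])),
                pon=pon,
                duration_h=float(row["duration_h"]),
            )
        )
    return records


def compute_rates(records: list[IncubationRecord]) -> pd.DataFrame:
    """Volumetric (umol N/L/h) and specific (1/d) uptake for each record.

    Sub-natural-abundance records keep their signed rate and are marked
    ``flagged=True``; downstream aggregations exclude flagged rows by default.
    """
    rows = []
    for rec in records:
        rr = rate_record(rec)
        rows.append(
            {
                "lake": rec.lake,
                "date": rec.date,
                "fraction": rec.fraction.value,
                "form": rec.form.value,
                "v_volumetric": rr.v_volumetric,
                "v_specific": rr.v_specific,
                "flagged": rr.flagged,
            }
        )
    return pd.DataFrame(rows)


def write_rates(rates: pd.DataFrame, path: str | Path) -> None:
    """Write a rates table; missing values become empty cells (round-trips)."""
    rates.to_csv(path, index=False, na_rep="")
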