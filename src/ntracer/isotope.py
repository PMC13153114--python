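"""Stable-isotope (15N) unit conversions and tracer mass-balance uptake rates.

The tracer method: a nitrogen substrate pool (nitrate, ammonium, urea or
glutamic acid) is spiked with highly 15N-enriched substrate at ~10% of the
ambient concentration, the sample is incubated briefly, and the 15N excess
accumulated in particulate organic nitrogen (PON, >0.7 um) yields a
volumetric uptake rate

    V = (AP_post - AP_pre) / (AP_enr - AP_pre) * PON / T

where the atom-percent (AP) terms are the 15N abundances of the cells before
and after incubation and of the substrate after enrichment. Rates are *net*
uptake: no isotope-dilution correction is applied (regeneration of unlabeled
substrate during incubation biases rates low; the bias is quantified in
:mod:`ntracer.simulate`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "R_AIR",
    "NAT_ABUNDANCE_AP",
    "OVER_ENRICHMENT_PCT",
    "NForm",
    "Fraction",
    "AtomPercent",
    "SubstratePool",
    "IncubationRecord",
    "RateRecord",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "enriched_atom_percent",
    "spike_for_target_fraction",
    "percent_addition",
    "volumetric_uptake",
    "specific_uptake",
    "pon_mg_to_umol",
    "rate_record",
]

#: 15N/14N isotope ratio of atmospheric N2 (the international air standard).
R_AIR = 0.0036765

#: Natural-abundance atom% 15N implied by R_AIR (delta-15N = 0 permil).
NAT_ABUNDANCE_AP = 100.0 * R_AIR / (1.0 + R_AIR)  # 0.36630...

#: Spike additions above this percentage of ambient are flagged as
#: over-enriched (the design targets ~10% of ambient).
OVER_ENRICHMENT_PCT = 15.0

#: Molar mass of nitrogen, g/mol.
N_MOLAR_MASS = 14.0067


class NForm(str, Enum):
    """Nitrogen substrate forms used in the incubations."""

    NITRATE = "NO3"
    AMMONIUM = "NH4"
    UREA = "UREA"
    GLUTAMIC_ACID = "GLU"


class Fraction(str, Enum):
    """Plankton fractions: whole water, free-living (<20 um), colony (>20 um)."""

    WHOLE_WATER = "WW"
    FREE_LIVING = "FL"
    COLONY = "MC"


@dataclass(frozen=True)
class AtomPercent:
    """Atom% 15N of a nitrogen pool (0-100)."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"atom% must lie in [0, 100], got {self.value}")

    def __float__(self) -> float:
        return float(self.value)


def _ap(x: "AtomPercent | float") -> float:
    return float(x)


def delta_to_atom_percent(delta: float) -> AtomPercent:
    """Convert delta-15N (permil vs air) to atom% 15N.

    AP = 100 R / (1 + R) with R = R_air (1 + delta/1000). delta = 0 maps to
    the natural-abundance constant by construction.
    """
    if delta <= -1000.0:
        raise ValueError("delta-15N <= -1000 permil implies a negative isotope ratio")
    r = R_AIR * (1.0 + delta / 1000.0)
    return AtomPercent(100.0 * r / (1.0 + r))


def atom_percent_to_delta(ap: "AtomPercent | float") -> float:
    """Inverse of :func:`delta_to_atom_percent` (permil vs air)."""
    a = _ap(ap)
    if not 0.0 <= a < 100.0:
        raise ValueError("atom% must lie in [0, 100)")
    r = a / (100.0 - a)
    return 1000.0 * (r / R_AIR - 1.0)


@dataclass(frozen=True)
class SubstratePool:
    """An ambient substrate pool plus the 15N spike added to it."""

    form: NForm
    ambient_conc: float  # umol N / L
    spike_conc: float  # umol N / L
    ambient_ap: AtomPercent = field(default_factory=lambda: AtomPercent(NAT_ABUNDANCE_AP))
    spike_ap: AtomPercent = field(default_factory=lambda: AtomPercent(98.0))

    def __post_init__(self) -> None:
        if self.ambient_conc < 0 or self.spike_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if float(self.spike_ap) < float(self.ambient_ap):
            raise ValueError("spike atom% must be >= ambient atom%")


def enriched_atom_percent(pool: SubstratePool) -> AtomPercent:
    """Atom% of the substrate pool after the spike (concentration-weighted mean)."""
    total = pool.ambient_conc + pool.spike_conc
    if total <= 0:
        raise ValueError("ambient and spike concentrations are both zero")
    ap = (
        pool.ambient_conc * float(pool.ambient_ap)
        + pool.spike_conc * float(pool.spike_ap)
    ) / total
    return AtomPercent(ap)


def spike_for_target_fraction(ambient_conc: float, target_fraction: float = 0.10) -> float:
    """Spike concentration (umol N/L) hitting ``target_fraction`` of ambient.

    The design targets ~10% of previously measured in-situ concentration,
    which keeps enrichment low while the tracer stays detectable.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if ambient_conc < 0:
        raise ValueError("ambient concentration must be non-negative")
    if ambient_conc == 0:
        warnings.warn("ambient concentration is zero: no tracer addition possible")
        return 0.0
    return target_fraction * ambient_conc


def percent_addition(spike_conc: float, ambient_conc: float) -> float:
    """Spike as a percentage of ambient; warns above the over-enrichment cutoff."""
    if ambient_conc <= 0:
        raise ValueError("percent addition undefined for ambient_conc <= 0")
    pct = 100.0 * spike_conc / ambient_conc
    if pct > OVER_ENRICHMENT_PCT:
        warnings.warn(
            f"spike is {pct:.1f}% of ambient (> {OVER_ENRICHMENT_PCT:.0f}%): "
            "over-enrichment may violate tracer assumptions"
        )
    return pct


@dataclass(frozen=True)
class IncubationRecord:
    """One tracer incubation measurement (site x date x fraction x N form)."""

    lake: str
    date: str  # ISO-8601
    fraction: Fraction
    form: NForm
    na_pre: AtomPercent  # cells before incubation (N_A)
    ap_post: AtomPercent  # cells after incubation
    ap_enr: AtomPercent  # substrate after the spike
    pon: float  # umol N / L, > 0.7 um particulate pool
    duration_h: float

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("incubation duration must be positive")
        if self.pon <= 0:
            raise ValueError("PON must be positive")
        if float(self.ap_enr) <= float(self.na_pre):
            raise ValueError(
                "substrate atom% after the spike must exceed the cells' "
                "pre-incubation atom% (tracer must enrich the pool)"
            )

    @property
    def sub_natural(self) -> bool:
        """True when cells ended below their pre-incubation atom% (QC flag)."""
        return float(self.ap_post) < float(self.na_pre)


@dataclass(frozen=True)
class RateRecord:
    """Derived volumetric (umol N/L/h) and specific (1/d) uptake for one record."""

    record: IncubationRecord
    v_volumetric: float
    v_specific: float
    flagged: bool = False


def volumetric_uptake(rec: IncubationRecord) -> float:
    """Volumetric net N uptake V (umol N / L / h) by tracer mass balance.

    Negative values (cells below pre-incubation atom%) are returned signed
    with a warning so QC can find bad samples; they are never clipped here.
    """
    num = float(rec.ap_post) - float(rec.na_pre)
    den = float(rec.ap_enr) - float(rec.na_pre)
    if den <= 0:
        raise ValueError("degenerate enrichment: ap_enr must exceed na_pre")
    if num < 0:
        warnings.warn(
            f"{rec.lake} {rec.date} {rec.fraction.value} {rec.form.value}: "
            "post-incubation atom% below pre-incubation value; returning a "
            "signed rate (net release or fractionation artifact)"
        )
    return (num / den) * rec.pon / rec.duration_h


def specific_uptake(v: float, pon: float) -> float:
    """Biomass-weighted (N-specific) uptake, 1/day: V * 24 / PON."""
    if pon <= 0:
        raise ValueError("PON must be positive")
    return v * 24.0 / pon


def pon_mg_to_umol(pon_mg: float) -> float:
    """Convert PON from mg N/L (as reported) to umol N/L (as the rate equation needs)."""
    if pon_mg < 0:
        raise ValueError("PON cannot be negative")
    return pon_mg * 1000.0 / N_MOLAR_MASS


def rate_record(rec: IncubationRecord) -> RateRecord:
    """Compute both uptake rates for one incubation, propagating the QC flag."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = volumetric_uptake(rec)
    return RateRecord(
        record=rec,
        v_volumetric=v,
        v_specific=specific_uptake(v, rec.pon),
        flagged=rec.sub_natural,
    )


def excess_ap(ap: "AtomPercent | float", reference: "AtomPercent | float") -> float:
    """Atom% excess above a reference pool (typically natural abundance)."""
    return _ap(ap) - _ap(reference)
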