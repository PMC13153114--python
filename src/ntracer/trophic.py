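"""Trophic State Index (TSI) sub-indices, composite, and classification bands.

The TSI ranks lakes on a 0-100 productivity scale from Secchi transparency,
chlorophyll-a, total phosphorus and (optionally) orthophosphate using the
Carlson log-linear sub-indices:

    TSI(SD)  = 60 - 14.41 ln(Secchi, m)
    TSI(CHL) = 9.81 ln(chl-a, ug/L) + 30.6
    TSI(TP)  = 14.42 ln(TP, ug/L) + 4.15

No canonical orthophosphate sub-index exists; it defaults to the TP
coefficients and is configurable. The composite is the unweighted mean of
available sub-indices (the combination rule is an assumption; see docs).
Classification bands: >74 hypereutrophic, (54, 74] eutrophic, (44, 54]
mesotrophic, (24, 44] oligotrophic, <=24 ultraoligotrophic — band edges are
closed on the upper side so a score of exactly 74 is eutrophic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

__all__ = [
    "LakeEnvironment",
    "TrophicClass",
    "TSICoefficients",
    "TSIResult",
    "tsi_subindices",
    "composite_tsi",
    "classify_tsi",
    "tsi",
]


class TrophicClass(str, Enum):
    ULTRAOLIGOTROPHIC = "ultraoligotrophic"
    OLIGOTROPHIC = "oligotrophic"
    MESOTROPHIC = "mesotrophic"
    EUTROPHIC = "eutrophic"
    HYPEREUTROPHIC = "hypereutrophic"


@dataclass(frozen=True)
class LakeEnvironment:
    """Physiochemical covariates of one lake feeding TSI and correlations."""

    lake: str
    surface_temp: Optional[float] = None  # degC
    secchi_m: Optional[float] = None
    chla_ug_l: Optional[float] = None
    tp_ug_l: Optional[float] = None
    po4_ug_l: Optional[float] = None
    tn_mg_l: Optional[float] = None
    microcystin_ug_l: Optional[float] = None
    area_km2: Optional[float] = None
    depth_m: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("chla_ug_l", "tp_ug_l", "po4_ug_l", "tn_mg_l", "microcystin_ug_l"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.secchi_m is not None and self.secchi_m <= 0:
            raise ValueError("secchi_m must be positive when present")


@dataclass(frozen=True)
class TSICoefficients:
    """(slope, intercept) of each log-linear sub-index; Carlson defaults."""

    secchi: tuple[float, float] = (-14.41, 60.0)
    chla: tuple[float, float] = (9.81, 30.6)
    tp: tuple[float, float] = (14.42, 4.15)
    po4: tuple[float, float] = (14.42, 4.15)  # no canonical form; TP coefficients


@dataclass(frozen=True)
class TSIResult:
    sub_indices: dict[str, float]
    composite: float
    trophic_class: TrophicClass


def _loglinear(x: Optional[float], slope: float, intercept: float, name: str):
    if x is None:
        return None
    if x <= 0:
        warnings.warn(f"TSI({name}): nonpositive input {x}, sub-index missing")
        return None
    return slope * math.log(x) + intercept


def tsi_subindices(
    env: LakeEnvironment, coeffs: TSICoefficients = TSICoefficients()
) -> dict[str, float]:
    """Available TSI sub-indices for one lake; missing inputs yield missing entries."""
    raw = {
        "secchi": _loglinear(env.secchi_m, *coeffs.secchi, "secchi"),
        "chla": _loglinear(env.chla_ug_l, *coeffs.chla, "chla"),
        "tp": _loglinear(env.tp_ug_l, *coeffs.tp, "tp"),
        "po4": _loglinear(env.po4_ug_l, *coeffs.po4, "po4"),
    }
    sub = {k: v for k, v in raw.items() if v is not None}
    if not sub:
        raise ValueError("no TSI sub-index computable: all drivers missing or nonpositive")
    return sub


def composite_tsi(sub: Mapping[str, float], weights: Optional[Mapping[str, float]] = None) -> float:
    """Weighted mean of available sub-indices (unweighted by default)."""
    if not sub:
        raise ValueError("empty sub-index map")
    if weights is None:
        return sum(sub.values()) / len(sub)
    w = {k: float(weights.get(k, 0.0)) for k in sub}
    tot = sum(w.values())
    if tot <= 0:
        raise ValueError("weights for available sub-indices sum to zero")
    return sum(sub[k] * w[k] for k in sub) / tot


def classify_tsi(score: float) -> TrophicClass:
    """Map a composite TSI to its trophic class (upper band edges closed)."""
    if not math.isfinite(score):
        raise ValueError("TSI score must be finite")
    if score > 74:
        return TrophicClass.HYPEREUTROPHIC
    if score > 54:
        return TrophicClass.EUTROPHIC
    if score > 44:
        return TrophicClass.MESOTROPHIC
    if score > 24:
        return TrophicClass.OLIGOTROPHIC
    return TrophicClass.ULTRAOLIGOTROPHIC


def tsi(
    env: LakeEnvironment,
    coeffs: TSICoefficients = TSICoefficients(),
    weights: Optional[Mapping[str, float]] = None,
) -> TSIResult:
    """Sub-indices, composite and class for one lake in a single call."""
    sub = tsi_subindices(env, coeffs)
    comp = composite_tsi(sub, weights)
    return TSIResult(sub_indices=sub, composite=comp, trophic_class=classify_tsi(comp))
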