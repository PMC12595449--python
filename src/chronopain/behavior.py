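"""Scoring of weight bearing, sucrose preference, affective responses and
catwalk gait ratios.

WB-% = 100 * ipsi / (ipsi + contra): the percentage of hind-limb weight
borne on the injured (ipsilateral) leg; 50% is symmetric. SPT% pools fluid
intake across the two side-swapped test nights: 100 * sucrose / total.
Gait metrics are expressed as ipsi/contra ratios; the guarding index
condenses dynamic loading asymmetry into a single number that is 0 for a
symmetric gait and rises toward 1 as the injured limb is unloaded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "WeightBearingReading",
    "SucroseReading",
    "GaitRecord",
    "AffectiveScore",
    "weight_bearing_pct",
    "sucrose_preference_pct",
    "limb_ratios",
    "guarding_index",
]

AFFECTIVE_FILAMENTS_G = {"low": 0.04, "medium": 0.16, "high": 1.0}
AFFECTIVE_WINDOW_S = 30.0


@dataclass(frozen=True)
class WeightBearingReading:
    ipsi_g: float
    contra_g: float

    def __post_init__(self) -> None:
        if self.ipsi_g < 0 or self.contra_g < 0:
            raise ValueError("weights must be nonnegative")


@dataclass(frozen=True)
class SucroseReading:
    """Two overnight (sucrose_ml, water_ml) readings with the bottle side
    swapped between nights; a single night is tolerated with a warning."""

    nights: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.nights) <= 2:
            raise ValueError("expected readings for one or two nights")
        for s, w in self.nights:
            if s < 0 or w < 0:
                raise ValueError("consumed volumes must be nonnegative")


@dataclass(frozen=True)
class GaitRecord:
    """Per-limb catwalk measures for the ipsi- and contralateral hind limbs."""

    ipsi_stance_s: float
    contra_stance_s: float
    ipsi_swing_s: float
    contra_swing_s: float
    ipsi_contact_area: float
    contra_contact_area: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class AffectiveScore:
    """Duration of attending behavior (licking, biting, lifting, guarding)
    within the 30-s window after stimulation with one filament class."""

    filament_class: Literal["low", "medium", "high"]
    attending_duration_s: float

    def __post_init__(self) -> None:
        if self.filament_class not in AFFECTIVE_FILAMENTS_G:
            raise ValueError("filament_class must be low/medium/high")
        if not 0.0 <= self.attending_duration_s <= AFFECTIVE_WINDOW_S:
            raise ValueError(
                f"attending duration must lie in [0, {AFFECTIVE_WINDOW_S}] s"
            )


def weight_bearing_pct(r: WeightBearingReading) -> float:
    """WB-% = 100 * ipsi / (ipsi + contra)."""
    total = r.ipsi_g + r.contra_g
    if total <= 0:
        raise ValueError("zero total weight: invalid trial")
    return 100.0 * r.ipsi_g / total


def sucrose_preference_pct(r: SucroseReading) -> float:
    """SPT% pooled over the two nights: 100 * sum(sucrose) / sum(all fluid)."""
    if len(r.nights) == 1:
        warnings.warn(
            "single-night sucrose reading: SPT% computed on one night only"
        )
    sucrose = sum(s for s, _ in r.nights)
    total = sum(s + w for s, w in r.nights)
    if total <= 0:
        raise ValueError("zero total fluid consumption")
    return 100.0 * sucrose / total


def limb_ratios(g: GaitRecord) -> dict[str, float]:
    """Ipsi/contra ratios for stance time, swing time and contact area.

    A zero contralateral denominator yields NaN for that metric only (the
    others are still computed), with a warning naming the metric.
    """
    out: dict[str, float] = {}
    for key, ipsi, contra in (
        ("stance_ratio", g.ipsi_stance_s, g.contra_stance_s),
        ("swing_time_ratio", g.ipsi_swing_s, g.contra_swing_s),
        ("contact_area_ratio", g.ipsi_contact_area, g.contra_contact_area),
    ):
        if contra == 0:
            warnings.warn(f"zero contralateral denominator for {key}: missing")
            out[key] = math.nan
        else:
            out[key] = ipsi / contra
    return out


def guarding_index(
    g: GaitRecord,
    stance_weight: float = 1.0,
    area_weight: float = 1.0,
) -> float:
    """Guarding index: 1 minus the ipsi/contra ratio of a dynamic-loading
    composite.

    The composite is the weighted geometric mean of stance time and paw
    contact area, so proportionally halving the ipsilateral loading halves
    the composite ratio and gives an index of 0.5 under default weights.
    Symmetric gait gives 0; ipsi loading above contra gives a negative
    index (permitted: it flags preferential loading of the injured limb).
    """
    if stance_weight < 0 or area_weight < 0 or stance_weight + area_weight == 0:
        raise ValueError("weights must be nonnegative and not both zero")
    wsum = stance_weight + area_weight

    def composite(stance: float, area: float) -> float:
        return (stance ** stance_weight * area ** area_weight) ** (1.0 / wsum)

    contra = composite(g.contra_stance_s, g.contra_contact_area)
    if contra == 0:
        raise ValueError("zero contralateral loading composite")
    ipsi = composite(g.ipsi_stance_s, g.ipsi_contact_area)
    return 1.0 - ipsi / contra
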