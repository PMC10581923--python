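"""Apparent digestibility from inert-marker ratios and digestible intakes.

The apparent digestibility coefficient (ADC, %) of a nutrient is
estimated from the shift of the nutrient:marker ratio between diet and
feces::

    ADC = (1 - (Nf / Nd) * (Md / Mf)) * 100

Digestible content is dietary content x ADC/100, and daily digestible
intake is normalized by the geometric body weight sqrt(IBW x FBW) in kg.
Out-of-range ADCs are propagated with a warning, never clipped, so that
downstream dose-response fits see the real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .trial_io import (
    AdcTable,
    DietFormulation,
    FecalSample,
    TankRecord,
    TrialDataError,
)

__all__ = [
    "DigestibleProfile",
    "compute_adc",
    "compute_adc_table",
    "digestible_content",
    "geometric_body_weight",
    "daily_digestible_intake",
    "digestible_profile",
]


@dataclass
class DigestibleProfile:
    """Digestible contents (g/kg) and daily intakes (g/kg BW/day) for a diet."""

    diet_id: str
    digestible_content: dict[str, float] = field(default_factory=dict)
    daily_digestible_intake: dict[str, float] = field(default_factory=dict)


def compute_adc(
    diet: DietFormulation, feces: FecalSample, nutrient: str
) -> float:
    """Apparent digestibility coefficient (%) of ``nutrient`` for one diet.

    Ratios are unit-invariant, so contents may be in g/kg or percent as
    long as diet and feces use the same units.
    """
    nd = diet.content(nutrient)
    nf = feces.content(nutrient)
    if nd <= 0:
        raise TrialDataError(
            f"diet {diet.diet_id!r}: cannot compute ADC for {nutrient!r} "
            f"with dietary content {nd}"
        )
    if feces.marker <= 0:
        raise TrialDataError(
            f"feces for diet {feces.diet_id!r}: marker must be > 0"
        )
    return (1.0 - (nf / nd) * (diet.marker / feces.marker)) * 100.0


def compute_adc_table(
    diets: Sequence[DietFormulation],
    fecal_samples: Sequence[FecalSample],
    nutrients: Iterable[str] | None = None,
    pooling: str = "pool",
) -> AdcTable:
    """ADCs for every diet and nutrient.

    Multiple fecal samples per diet are combined either by pooling the
    fecal composition first (``pooling="pool"``, the default, mirroring
    physically pooled collections) or by averaging per-sample ADCs
    (``pooling="mean"``).
    """
    if pooling not in ("pool", "mean"):
        raise TrialDataError(f"unknown pooling mode {pooling!r}")
    by_diet: dict[str, list[FecalSample]] = {}
    for sample in fecal_samples:
        by_diet.setdefault(sample.diet_id, []).append(sample)

    table = AdcTable()
    for diet in diets:
        samples = by_diet.get(diet.diet_id)
        if not samples:
            continue
        names = list(nutrients) if nutrients is not None else [
            n for n in diet.nutrients if all(n in s.nutrients for s in samples)
        ]
        for name in names:
            if pooling == "pool":
                pooled = FecalSample(
                    diet_id=diet.diet_id,
                    nutrients={
                        name: float(np.mean([s.content(name) for s in samples]))
                    },
                    marker=float(np.mean([s.marker for s in samples])),
                )
                adc = compute_adc(diet, pooled, name)
            else:
                adc = float(
                    np.mean([compute_adc(diet, s, name) for s in samples])
                )
            table.set(diet.diet_id, name, adc)
    return table


def digestible_content(dietary: float, adc: float) -> float:
    """Digestible nutrient content (g/kg), ``dietary * adc / 100``."""
    if dietary < 0:
        raise TrialDataError(f"dietary content must be >= 0, got {dietary}")
    return dietary * adc / 100.0


def geometric_body_weight(initial: float, final: float) -> float:
    """Geometric mean body weight sqrt(initial x final), in kg."""
    if initial <= 0 or final <= 0:
        raise TrialDataError("weights must be > 0")
    return math.sqrt(initial * final) / 1000.0


def daily_digestible_intake(
    tank: TankRecord,
    diet: DietFormulation,
    adc: float,
    nutrient: str,
) -> float:
    """Daily digestible nutrient intake in g per kg geometric BW per day.

    ``(feed_intake / duration) * content/1000 * adc/100 / geometric BW``,
    with feed intake as-fed (see module notes).
    """
    content = diet.content(nutrient)
    daily_feed = tank.feed_intake / tank.duration
    absorbed = daily_feed * content / 1000.0 * adc / 100.0
    return absorbed / geometric_body_weight(tank.initial_weight, tank.final_weight)


def digestible_profile(
    diet: DietFormulation,
    adc: AdcTable,
    tank: TankRecord | None = None,
    nutrients: Iterable[str] | None = None,
) -> DigestibleProfile:
    """Digestible contents for a diet, plus daily intakes when a tank is given."""
    names = list(nutrients) if nutrients is not None else [
        n for d, n in adc.entries if d == diet.diet_id
    ]
    profile = DigestibleProfile(diet_id=diet.diet_id)
    for name in names:
        coefficient = adc.get(diet.diet_id, name)
        profile.digestible_content[name] = digestible_content(
            diet.content(name), coefficient
        )
        if tank is not None:
            profile.daily_digestible_intake[name] = daily_digestible_intake(
                tank, diet, coefficient, name
            )
    return profile
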