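"""Growth and feed performance metrics computed at tank level.

Metrics follow the standard aquaculture definitions: percentage weight
gain, specific growth rate from log body-weight change, feed conversion
ratio, and hepatosomatic index.  Feed intake is used as provided (as-fed)
by default; pass ``feed_basis="dry_matter"`` to convert via the diet's
dry-matter fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .digestibility import geometric_body_weight
from .trial_io import DietFormulation, FishRecord, TankRecord, TrialDataError

__all__ = [
    "PerformanceMetrics",
    "weight_gain_pct",
    "specific_growth_rate",
    "feed_conversion_ratio",
    "hepatosomatic_index",
    "tank_metrics",
    "summarize_by_diet",
]


@dataclass
class PerformanceMetrics:
    """Per-tank performance summary; ``hsi`` requires fish organ weights."""

    tank_id: str
    diet_id: str
    weight_gain_pct: float
    sgr: float
    fcr: float
    geometric_bw: float  # kg
    hsi: float | None = None
    aggregation: str = "tank_means"  # provenance of the underlying weights


def weight_gain_pct(initial: float, final: float) -> float:
    """Percent weight gain, ``(final - initial) / initial * 100``."""
    if initial <= 0:
        raise TrialDataError(f"initial weight must be > 0, got {initial}")
    return (final - initial) / initial * 100.0


def specific_growth_rate(initial: float, final: float, days: float) -> float:
    """Specific growth rate in %/day from log weight change."""
    if initial <= 0 or final <= 0:
        raise TrialDataError("weights must be > 0")
    if days <= 0:
        raise TrialDataError(f"duration must be > 0, got {days}")
    return (math.log(final) - math.log(initial)) / days * 100.0


def feed_conversion_ratio(feed_intake: float, weight_gain: float) -> float:
    """Feed consumed per unit weight gained (both g/fish).

    Undefined for non-growing tanks: a non-positive gain raises rather
    than returning a silently negative ratio.
    """
    if weight_gain <= 0:
        raise TrialDataError(
            f"FCR undefined for non-positive weight gain ({weight_gain} g)"
        )
    return feed_intake / weight_gain


def hepatosomatic_index(liver: float, body: float) -> float:
    """Liver weight as a percentage of body weight."""
    if body <= 0:
        raise TrialDataError(f"body weight must be > 0, got {body}")
    if liver < 0 or liver >= body:
        raise TrialDataError(
            f"liver weight must satisfy 0 <= liver < body, got {liver}/{body}"
        )
    return liver / body * 100.0


def tank_metrics(
    tank: TankRecord,
    fish: Sequence[FishRecord] | None = None,
    diet: DietFormulation | None = None,
    feed_basis: str = "as_fed",
) -> PerformanceMetrics:
    """Compute all performance metrics for one tank.

    When ``fish`` records with liver weights are supplied, HSI is the mean
    of per-fish indices.  An FCR for a non-growing tank is reported as NaN
    (flagged via the metric itself) instead of being dropped.
    """
    feed = tank.feed_intake
    if feed_basis == "dry_matter":
        if diet is None:
            raise TrialDataError("feed_basis='dry_matter' requires the diet")
        feed = feed * diet.dry_matter
    elif feed_basis != "as_fed":
        raise TrialDataError(f"unknown feed basis {feed_basis!r}")

    gain = tank.final_weight - tank.initial_weight
    try:
        fcr = feed_conversion_ratio(feed, gain)
    except TrialDataError:
        fcr = float("nan")

    hsi: float | None = None
    if fish:
        indices = [
            hepatosomatic_index(f.liver_weight, f.body_weight)
            for f in fish
            if f.tank_id == tank.tank_id and f.liver_weight is not None
        ]
        if indices:
            hsi = float(np.mean(indices))

    return PerformanceMetrics(
        tank_id=tank.tank_id,
        diet_id=tank.diet_id,
        weight_gain_pct=weight_gain_pct(tank.initial_weight, tank.final_weight),
        sgr=specific_growth_rate(
            tank.initial_weight, tank.final_weight, tank.duration
        ),
        fcr=fcr,
        geometric_bw=geometric_body_weight(tank.initial_weight, tank.final_weight),
        hsi=hsi,
    )


def summarize_by_diet(
    metrics: Sequence[PerformanceMetrics],
    tanks: Sequence[TankRecord] | None = None,
) -> pd.DataFrame:
    """Per-diet mean and SEM (sd/sqrt(n) over tanks) of each metric.

    A diet with a single tank gets ``NaN`` SEMs (flagged, not silently
    zero).  Returns a frame indexed by diet with ``<metric>_mean``,
    ``<metric>_sem`` and ``n_tanks`` columns.
    """
    if not metrics:
        raise TrialDataError("no metrics to summarize")
    frame = pd.DataFrame(
        {
            "diet_id": [m.diet_id for m in metrics],
            "weight_gain_pct": [m.weight_gain_pct for m in metrics],
            "sgr": [m.sgr for m in metrics],
            "fcr": [m.fcr for m in metrics],
            "geometric_bw": [m.geometric_bw for m in metrics],
            "hsi": [np.nan if m.hsi is None else m.hsi for m in metrics],
        }
    )
    grouped = frame.groupby("diet_id", sort=False)
    mean = grouped.mean()
    # ddof=1 sample sd; single-tank diets yield NaN SEM by construction
    sem = grouped.std(ddof=1) / np.sqrt(grouped.count())
    out = mean.add_suffix("_mean").join(sem.add_suffix("_sem"))
    out["n_tanks"] = grouped.size()
    return out
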