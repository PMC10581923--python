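"""Bundled reference dataset: a six-diet methionine dose-response trial.

Published diet-level summaries from a 38-day juvenile marine fish feeding
trial with five graded methionine levels plus a taurine-supplemented arm
at near-constant cysteine.  Only diet means are available (raw tank and
fish records were not published), so the tank table carries one
mean-biometry pseudo-tank per diet.  Used by the examples, the validation
suite and the acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sulfur_amino import CYS, MET
from .trial_io import AdcTable, DietFormulation, TankRecord

__all__ = ["ReferenceTrial", "load_reference_trial", "TAURINE_DIET_ID"]

DIET_IDS = ("D1", "D2", "D3", "D4", "D5", "D6")

#: the sixth arm is a taurine contrast, not a sixth methionine level;
#: dose-response fits exclude it by default
TAURINE_DIET_ID = "D6"

_AMINO_ACID_CONTENT = {  # g/kg DM per diet D1..D6
    "arginine": (31.2, 35.3, 33.1, 33.9, 30.7, 34.3),
    "histidine": (12.0, 13.1, 13.1, 12.5, 11.8, 14.0),
    "isoleucine": (15.8, 16.2, 17.1, 17.3, 15.9, 17.8),
    "leucine": (34.2, 34.0, 34.6, 36.0, 33.0, 36.8),
    "lysine": (29.1, 33.2, 32.8, 33.0, 29.2, 31.6),
    MET: (9.5, 11.6, 14.0, 17.9, 21.5, 18.6),
    "phenylalanine": (23.9, 22.3, 23.2, 24.3, 22.3, 25.6),
    "threonine": (20.0, 19.7, 20.2, 21.5, 19.2, 21.2),
    "valine": (21.4, 20.7, 22.2, 22.8, 20.7, 22.7),
    "alanine": (32.4, 31.4, 32.8, 33.9, 31.9, 34.4),
    "aspartic_acid": (48.0, 47.6, 47.8, 49.7, 46.8, 51.2),
    CYS: (4.4, 4.3, 4.3, 4.7, 4.2, 4.9),
    "glutamic_acid": (78.3, 78.5, 80.4, 83.5, 78.0, 87.2),
    "glycine": (62.7, 55.4, 50.5, 55.6, 49.2, 54.1),
    "proline": (34.5, 34.0, 34.8, 35.7, 33.0, 37.7),
    "serine": (24.2, 24.5, 24.8, 25.8, 23.8, 27.0),
    "tyrosine": (14.9, 14.2, 14.7, 15.5, 14.5, 15.7),
    "taurine": (1.8, 1.7, 1.7, 1.9, 1.7, 8.0),
}

_ADC = {  # apparent digestibility coefficients, % per diet D1..D6
    "arginine": (93.5, 97.9, 95.1, 92.9, 93.4, 94.3),
    "histidine": (87.8, 95.7, 90.3, 87.3, 87.5, 90.6),
    "isoleucine": (87.0, 94.9, 89.9, 88.6, 87.9, 90.6),
    "leucine": (88.4, 95.2, 90.6, 88.9, 88.7, 91.4),
    "lysine": (89.4, 96.3, 92.7, 90.8, 91.0, 92.2),
    MET: (88.5, 95.9, 93.9, 93.1, 94.2, 94.7),
    "phenylalanine": (88.8, 95.2, 90.8, 89.3, 89.4, 91.9),
    "threonine": (85.6, 93.5, 86.1, 85.7, 84.7, 88.4),
    "valine": (87.3, 94.5, 89.4, 87.4, 86.9, 90.2),
    "alanine": (89.4, 95.3, 90.3, 89.2, 89.6, 91.6),
    "aspartic_acid": (84.3, 92.3, 84.8, 82.7, 84.0, 86.4),
    CYS: (60.9, 77.3, 56.5, 54.2, 53.9, 65.3),
    "glutamic_acid": (88.7, 95.5, 91.1, 89.6, 90.0, 92.0),
    "glycine": (91.5, 95.3, 89.4, 88.8, 88.2, 91.0),
    "proline": (90.6, 96.0, 91.8, 90.2, 90.0, 92.7),
    "serine": (90.6, 96.0, 91.8, 90.2, 90.0, 92.7),
    "tyrosine": (86.9, 94.6, 89.1, 88.2, 87.7, 90.3),
    "taurine": (43.5, 71.2, 34.3, 39.2, 23.0, 86.4),
}

_DRY_MATTER_PCT = (90.6, 88.4, 86.4, 91.3, 87.3, 91.7)
_GROSS_ENERGY = (19.5, 19.1, 18.8, 19.7, 19.1, 18.3)  # MJ/kg
_MARKER = 1.0  # yttrium-style inert marker, g/kg DM

# diet-mean biometry over 38 days, 3 tanks x 14 fish per diet
_INITIAL_WEIGHT = (83.8, 83.7, 83.8, 84.3, 83.8, 84.3)  # g/fish
_FINAL_WEIGHT = (247.9, 274.4, 271.6, 282.0, 267.7, 284.4)  # g/fish
_FEED_INTAKE = (135.5, 149.0, 145.0, 152.8, 140.5, 151.7)  # g/fish, as-fed
_DURATION = 38.0

# published diet-mean performance (from per-fish aggregation, so not
# exactly reproducible from the diet-mean weights above)
_PERFORMANCE = {
    "weight_gain_pct": (199.0, 231.0, 225.0, 237.0, 221.0, 240.0),
    "fcr": (0.86, 0.81, 0.81, 0.80, 0.81, 0.81),
    "sgr": (2.83, 3.10, 3.07, 3.15, 3.03, 3.18),
    "hsi": (3.20, 2.93, 2.99, 2.86, 2.65, 2.70),
}


@dataclass
class ReferenceTrial:
    diets: list[DietFormulation]
    adc: AdcTable
    tanks: list[TankRecord]  # one mean-biometry pseudo-tank per diet
    performance: pd.DataFrame  # published diet-mean responses
    taurine_diet_id: str = TAURINE_DIET_ID

    @property
    def mean_dietary_cys(self) -> float:
        """Mean cysteine content over all diets (g/kg DM)."""
        return float(np.mean([d.content(CYS) for d in self.diets]))


def load_reference_trial() -> ReferenceTrial:
    """Assemble the bundled reference trial from its printed summaries."""
    diets = [
        DietFormulation(
            diet_id=diet_id,
            nutrients={name: row[i] for name, row in _AMINO_ACID_CONTENT.items()},
            marker=_MARKER,
            dry_matter=_DRY_MATTER_PCT[i] / 100.0,
            gross_energy=_GROSS_ENERGY[i],
        )
        for i, diet_id in enumerate(DIET_IDS)
    ]
    adc = AdcTable(
        {
            (diet_id, name): row[i]
            for name, row in _ADC.items()
            for i, diet_id in enumerate(DIET_IDS)
        }
    )
    tanks = [
        TankRecord(
            tank_id=f"{diet_id}:mean",
            diet_id=diet_id,
            n_fish=14,
            initial_weight=_INITIAL_WEIGHT[i],
            final_weight=_FINAL_WEIGHT[i],
            feed_intake=_FEED_INTAKE[i],
            duration=_DURATION,
        )
        for i, diet_id in enumerate(DIET_IDS)
    ]
    performance = pd.DataFrame(_PERFORMANCE, index=list(DIET_IDS))
    return ReferenceTrial(diets=diets, adc=adc, tanks=tanks, performance=performance)
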