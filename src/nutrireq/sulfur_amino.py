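"""Total sulfur amino acid (TSAA) dose algebra.

Two TSAA definitions are supported on each of three bases (dietary
content, digestible content, daily digestible intake):

* ``TSAA[Met + Cys]`` — the plain sum of methionine and cysteine doses.
* ``TSAA[Met]`` — cysteine expressed in methionine equivalents via the
  molecular-weight ratio, ``met + cys * (MW_met / MW_cys)``.

All chained computations carry full precision; rounding to one decimal
is a display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .digestibility import daily_digestible_intake, digestible_content
from .trial_io import AdcTable, DietFormulation, TankRecord, TrialDataError

__all__ = [
    "MET",
    "CYS",
    "BASES",
    "MolecularWeights",
    "TsaaDose",
    "tsaa_met_plus_cys",
    "tsaa_met_equivalent",
    "dose_table",
    "aggregate_tanks",
]

MET = "methionine"
CYS = "cysteine"
BASES = ("dietary", "digestible", "daily_intake")


@dataclass(frozen=True)
class MolecularWeights:
    """Molecular weights (g/mol) used for methionine-equivalent cysteine."""

    met: float = 149.21
    cys: float = 121.16

    def __post_init__(self) -> None:
        if self.met <= 0 or self.cys <= 0:
            raise TrialDataError("molecular weights must be > 0")

    @property
    def ratio(self) -> float:
        return self.met / self.cys


@dataclass
class TsaaDose:
    """Met/Cys doses and both TSAA totals for one diet on one basis."""

    diet_id: str
    basis: str
    met: float
    cys: float
    tsaa_met_plus_cys: float
    tsaa_met_equivalent: float


def tsaa_met_plus_cys(met: float, cys: float) -> float:
    """TSAA as the plain sum ``met + cys``."""
    if met < 0 or cys < 0:
        raise TrialDataError("doses must be >= 0")
    return met + cys


def tsaa_met_equivalent(
    met: float, cys: float, mw: MolecularWeights = MolecularWeights()
) -> float:
    """TSAA with cysteine converted to methionine equivalents."""
    if met < 0 or cys < 0:
        raise TrialDataError("doses must be >= 0")
    return met + cys * mw.ratio


def _dose(diet_id: str, basis: str, met: float, cys: float,
          mw: MolecularWeights) -> TsaaDose:
    return TsaaDose(
        diet_id=diet_id,
        basis=basis,
        met=met,
        cys=cys,
        tsaa_met_plus_cys=tsaa_met_plus_cys(met, cys),
        tsaa_met_equivalent=tsaa_met_equivalent(met, cys, mw),
    )


def aggregate_tanks(tanks: Sequence[TankRecord], diet_id: str) -> TankRecord:
    """Collapse a diet's tanks to one mean-biometry pseudo-tank."""
    group = [t for t in tanks if t.diet_id == diet_id]
    if not group:
        raise TrialDataError(f"no tanks for diet {diet_id!r}")
    return TankRecord(
        tank_id=f"{diet_id}:mean",
        diet_id=diet_id,
        n_fish=int(round(np.mean([t.n_fish for t in group]))),
        initial_weight=float(np.mean([t.initial_weight for t in group])),
        final_weight=float(np.mean([t.final_weight for t in group])),
        feed_intake=float(np.mean([t.feed_intake for t in group])),
        duration=float(np.mean([t.duration for t in group])),
    )


def dose_table(
    diets: Sequence[DietFormulation],
    adc: AdcTable | None = None,
    tanks: Sequence[TankRecord] | None = None,
    mw: MolecularWeights = MolecularWeights(),
    bases: Sequence[str] = BASES,
) -> list[TsaaDose]:
    """One :class:`TsaaDose` per diet per requested basis.

    The digestible basis chains dietary contents through ADCs; the daily
    intake basis additionally needs tank biometry (tanks are collapsed to
    diet means first).
    """
    unknown = [b for b in bases if b not in BASES]
    if unknown:
        raise TrialDataError(f"unknown basis {unknown}")
    doses: list[TsaaDose] = []
    for diet in diets:
        met = diet.content(MET)
        cys = diet.content(CYS)
        for basis in bases:
            if basis == "dietary":
                doses.append(_dose(diet.diet_id, basis, met, cys, mw))
                continue
            if adc is None:
                raise TrialDataError(f"basis {basis!r} requires an ADC table")
            met_adc = adc.get(diet.diet_id, MET)
            cys_adc = adc.get(diet.diet_id, CYS)
            if basis == "digestible":
                doses.append(
                    _dose(
                        diet.diet_id,
                        basis,
                        digestible_content(met, met_adc),
                        digestible_content(cys, cys_adc),
                        mw,
                    )
                )
            else:  # daily_intake
                if tanks is None:
                    raise TrialDataError(
                        "basis 'daily_intake' requires tank biometry"
                    )
                tank = aggregate_tanks(tanks, diet.diet_id)
                doses.append(
                    _dose(
                        diet.diet_id,
                        basis,
                        daily_digestible_intake(tank, diet, met_adc, MET),
                        daily_digestible_intake(tank, diet, cys_adc, CYS),
                        mw,
                    )
                )
    return doses
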