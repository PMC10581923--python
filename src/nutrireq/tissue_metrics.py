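"""Liver colorimetry and intestinal histomorphometry on measurement tables.

Color samples are mean RGB values over segmented organ pixels (segmentation
is out of scope here); they are converted to CIELAB through the standard
sRGB -> XYZ (D65, 2-degree observer) -> Lab transform, and compared with
the Euclidean (CIE76) color difference.  Histology operates on per-villus
measurement tables exported from slide-annotation software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

from .trial_io import TrialDataError

__all__ = [
    "MUCIN_KINDS",
    "ColorSample",
    "VillusMeasurement",
    "rgb_to_lab",
    "color_distance",
    "pairwise_color_distances",
    "lamina_propria_fraction",
    "mucin_density",
    "total_mucin_density",
]

MUCIN_KINDS = ("acidic", "neutral", "mixed")

_UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class ColorSample:
    """Mean color of one segmented organ image, 8-bit RGB channels."""

    sample_id: str
    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name in "rgb":
            value = getattr(self, name)
            if not 0 <= value <= 255:
                raise TrialDataError(
                    f"sample {self.sample_id!r}: channel {name} out of "
                    f"[0, 255]: {value}"
                )


@dataclass
class VillusMeasurement:
    """One villus: length, areas (um, um^2) and goblet-mucin counts."""

    slide_id: str
    villus_length: float
    villus_area: float
    lamina_propria_area: float
    mucin_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.villus_area < 0 or self.lamina_propria_area < 0:
            raise TrialDataError(f"slide {self.slide_id!r}: areas must be >= 0")
        if self.lamina_propria_area > self.villus_area:
            raise TrialDataError(
                f"slide {self.slide_id!r}: lamina propria area exceeds villus area"
            )
        for kind, count in self.mucin_counts.items():
            if count < 0:
                raise TrialDataError(
                    f"slide {self.slide_id!r}: negative {kind} mucin count"
                )


def rgb_to_lab(c: ColorSample) -> tuple[float, float, float]:
    """CIELAB (L*, a*, b*) of an 8-bit sRGB color (D65, 2-degree observer)."""
    lab = rgb2lab(np.array([[[c.r, c.g, c.b]]], dtype=float) / 255.0)
    return tuple(float(v) for v in lab[0, 0])


def color_distance(
    x: Sequence[float], y: Sequence[float]
) -> float:
    """Euclidean (CIE76) color difference between two CIELAB triples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (3,) or y.shape != (3,):
        raise TrialDataError("CIELAB triples must have exactly three components")
    return float(np.linalg.norm(x - y))


def pairwise_color_distances(samples: Sequence[ColorSample]) -> pd.DataFrame:
    """Symmetric matrix of CIE76 distances between all samples."""
    labs = np.array([rgb_to_lab(s) for s in samples])
    ids = [s.sample_id for s in samples]
    diff = labs[:, None, :] - labs[None, :, :]
    matrix = np.sqrt((diff**2).sum(axis=-1))
    return pd.DataFrame(matrix, index=ids, columns=ids)


def lamina_propria_fraction(v: VillusMeasurement) -> float:
    """Lamina propria area as a fraction of total villus area."""
    if v.villus_area <= 0:
        raise TrialDataError(f"slide {v.slide_id!r}: villus area must be > 0")
    return v.lamina_propria_area / v.villus_area


def mucin_density(v: VillusMeasurement, kind: str) -> float:
    """Goblet-mucin count per mm^2 of villus area (areas given in um^2)."""
    if kind not in MUCIN_KINDS:
        raise TrialDataError(f"unknown mucin kind {kind!r}; expected {MUCIN_KINDS}")
    if v.villus_area <= 0:
        raise TrialDataError(f"slide {v.slide_id!r}: villus area must be > 0")
    return v.mucin_counts.get(kind, 0) / (v.villus_area / _UM2_PER_MM2)


def total_mucin_density(v: VillusMeasurement) -> float:
    """Total goblet-mucin density; equals the sum over kinds exactly."""
    return sum(mucin_density(v, kind) for kind in MUCIN_KINDS)
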