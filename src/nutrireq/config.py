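"""Run configuration: nutrient-name aliases, molecular weights, model list.

A small YAML file customizes a pipeline run; everything has sensible
defaults so configuration is optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dose_response import FAMILIES
from .sulfur_amino import MolecularWeights

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    #: maps column-name aliases to canonical nutrient names (e.g. "met"
    #: -> "methionine")
    nutrient_aliases: dict[str, str] = field(default_factory=dict)
    marker_column: str = "marker"
    molecular_weights: MolecularWeights = field(default_factory=MolecularWeights)
    families: tuple[str, ...] = FAMILIES
    exclude_diets: tuple[str, ...] = ()
    blend_width: float | None = None  # None = 10% of dose span
    bootstrap: int = 0
    seed: int = 0

    def canonical(self, name: str) -> str:
        key = name.strip().lower()
        return self.nutrient_aliases.get(key, key)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    mw_raw = raw.pop("molecular_weights", None)
    config = RunConfig(
        nutrient_aliases={
            str(k).lower(): str(v).lower()
            for k, v in (raw.pop("nutrient_aliases", {}) or {}).items()
        },
        marker_column=raw.pop("marker_column", "marker"),
        families=tuple(raw.pop("families", FAMILIES)),
        exclude_diets=tuple(raw.pop("exclude_diets", ())),
        blend_width=raw.pop("blend_width", None),
        bootstrap=int(raw.pop("bootstrap", 0)),
        seed=int(raw.pop("seed", 0)),
    )
    if mw_raw:
        config.molecular_weights = MolecularWeights(
            met=float(mw_raw.get("met", 149.21)),
            cys=float(mw_raw.get("cys", 121.16)),
        )
    if raw:
        raise ValueError(f"unknown configuration keys: {sorted(raw)}")
    return config
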