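"""Tabular input/output and shared domain types for feeding-trial analyses.

All nutrient contents are stored in g/kg dry matter.  Files are flat
delimited text (comma by default, tab accepted) with a single header row;
identifiers are opaque strings.  Percent inputs for marker/nutrient pairs
are accepted because the digestibility ratio is unit-invariant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrialDataError",
    "DietFormulation",
    "FecalSample",
    "TankRecord",
    "FishRecord",
    "AdcTable",
    "read_diet_table",
    "read_fecal_table",
    "read_tank_table",
    "read_fish_table",
    "read_adc_table",
    "write_diet_table",
    "write_fecal_table",
    "write_tank_table",
    "write_fish_table",
    "write_adc_table",
    "write_results",
    "write_run_summary",
]


class TrialDataError(ValueError):
    """Raised when a trial data table violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: columns of a diet table that are not nutrient contents
_DIET_SPECIAL = ("diet_id", "marker", "dry_matter", "gross_energy")


@dataclass
class DietFormulation:
    """One diet: nutrient contents (g/kg DM), inert-marker level, DM fraction."""

    diet_id: str
    nutrients: dict[str, float]
    marker: float
    dry_matter: float = 1.0
    gross_energy: float | None = None

    def __post_init__(self) -> None:
        if self.marker <= 0:
            raise TrialDataError(
                f"diet {self.diet_id!r}: marker must be > 0, got {self.marker}"
            )
        if not 0 < self.dry_matter <= 1:
            raise TrialDataError(
                f"diet {self.diet_id!r}: dry_matter must be in (0, 1], "
                f"got {self.dry_matter}"
            )
        for name, value in self.nutrients.items():
            if value < 0:
                raise TrialDataError(
                    f"diet {self.diet_id!r}: negative content for {name!r}: {value}"
                )

    def content(self, nutrient: str) -> float:
        try:
            return self.nutrients[nutrient]
        except KeyError:
            raise TrialDataError(
                f"diet {self.diet_id!r} has no nutrient {nutrient!r}"
            ) from None


@dataclass
class FecalSample:
    """Pooled fecal composition for one diet (g/kg DM) with marker level."""

    diet_id: str
    nutrients: dict[str, float]
    marker: float

    def __post_init__(self) -> None:
        if self.marker <= 0:
            raise TrialDataError(
                f"feces for diet {self.diet_id!r}: marker must be > 0"
            )
        for name, value in self.nutrients.items():
            if value < 0:
                raise TrialDataError(
                    f"feces for diet {self.diet_id!r}: negative {name!r}: {value}"
                )

    def content(self, nutrient: str) -> float:
        try:
            return self.nutrients[nutrient]
        except KeyError:
            raise TrialDataError(
                f"feces for diet {self.diet_id!r} has no nutrient {nutrient!r}"
            ) from None


@dataclass
class TankRecord:
    """Biometry of one tank over the trial.

    Weights are mean grams per fish; feed intake is grams per fish over
    the whole trial (as-fed unless converted explicitly).
    """

    tank_id: str
    diet_id: str
    n_fish: int
    initial_weight: float
    final_weight: float
    feed_intake: float
    duration: float

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise TrialDataError(f"tank {self.tank_id!r}: n_fish must be >= 1")
        if self.initial_weight <= 0 or self.final_weight <= 0:
            raise TrialDataError(f"tank {self.tank_id!r}: weights must be > 0")
        if self.duration <= 0:
            raise TrialDataError(f"tank {self.tank_id!r}: duration must be > 0")
        if self.feed_intake < 0:
            raise TrialDataError(f"tank {self.tank_id!r}: feed_intake must be >= 0")


@dataclass
class FishRecord:
    """Individual fish biometry; organ weights optional."""

    fish_id: str
    tank_id: str
    body_weight: float
    liver_weight: float | None = None
    viscera_weight: float | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise TrialDataError(f"fish {self.fish_id!r}: body_weight must be > 0")
        for name in ("liver_weight", "viscera_weight"):
            value = getattr(self, name)
            if value is None:
                continue
            if value < 0 or value >= self.body_weight:
                raise TrialDataError(
                    f"fish {self.fish_id!r}: {name} must satisfy "
                    f"0 <= {name} < body_weight, got {value}"
                )


@dataclass
class AdcTable:
    """Apparent digestibility coefficients (%) keyed by (diet_id, nutrient).

    Out-of-range coefficients (< 0 or > 100, possible with noisy marker
    data) are retained with a warning and never clipped.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (diet_id, nutrient), adc in self.entries.items():
            _warn_adc_range(diet_id, nutrient, adc)

    def get(self, diet_id: str, nutrient: str) -> float:
        try:
            return self.entries[(diet_id, nutrient)]
        except KeyError:
            raise TrialDataError(
                f"no ADC for diet {diet_id!r}, nutrient {nutrient!r}"
            ) from None

    def set(self, diet_id: str, nutrient: str, adc: float) -> None:
        _warn_adc_range(diet_id, nutrient, adc)
        self.entries[(diet_id, nutrient)] = adc

    def diets(self) -> list[str]:
        seen: dict[str, None] = {}
        for diet_id, _ in self.entries:
            seen.setdefault(diet_id, None)
        return list(seen)

    def nutrients(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, nutrient in self.entries:
            seen.setdefault(nutrient, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)


def _warn_adc_range(diet_id: str, nutrient: str, adc: float) -> None:
    if adc < 0 or adc > 100:
        warnings.warn(
            f"ADC outside [0, 100] for diet {diet_id!r}, nutrient {nutrient!r}: "
            f"{adc:.3f}% (retained, not clipped)",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_frame(path: str | Path, sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return frame


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise TrialDataError(f"{what}: missing column(s) {missing}")


def _numeric(frame: pd.DataFrame, columns: Sequence[str], what: str) -> pd.DataFrame:
    out = frame.copy()
    for column in columns:
        converted = pd.to_numeric(out[column], errors="coerce")
        bad = converted.isna() & out[column].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TrialDataError(
                f"{what}: non-numeric value {out.loc[row, column]!r} "
                f"in column {column!r} (row {row})"
            )
        out[column] = converted
    return out


def read_diet_table(path: str | Path, sep: str = ",") -> list[DietFormulation]:
    """Read one :class:`DietFormulation` per row.

    Columns named ``diet_id``, ``marker``, ``dry_matter`` and
    ``gross_energy`` are structural; every other column is preserved as a
    nutrient content in g/kg DM.
    """
    frame = _read_frame(path, sep)
    if frame.empty:
        logger.warning("diet table %s is empty", path)
        return []
    _require_columns(frame, ("diet_id", "marker"), "diet table")
    dupes = frame["diet_id"].astype(str)[frame["diet_id"].astype(str).duplicated()]
    if not dupes.empty:
        raise TrialDataError(f"diet table: duplicate diet_id {sorted(set(dupes))}")
    nutrient_cols = [c for c in frame.columns if c not in _DIET_SPECIAL]
    frame = _numeric(frame, [c for c in frame.columns if c != "diet_id"], "diet table")
    diets = []
    for _, row in frame.iterrows():
        diets.append(
            DietFormulation(
                diet_id=str(row["diet_id"]),
                nutrients={c: float(row[c]) for c in nutrient_cols},
                marker=float(row["marker"]),
                dry_matter=float(row["dry_matter"]) if "dry_matter" in frame else 1.0,
                gross_energy=(
                    float(row["gross_energy"]) if "gross_energy" in frame else None
                ),
            )
        )
    return diets


def read_fecal_table(path: str | Path, sep: str = ",") -> list[FecalSample]:
    """Read one :class:`FecalSample` per row (``diet_id``, ``marker``, nutrients)."""
    frame = _read_frame(path, sep)
    if frame.empty:
        logger.warning("fecal table %s is empty", path)
        return []
    _require_columns(frame, ("diet_id", "marker"), "fecal table")
    nutrient_cols = [c for c in frame.columns if c not in ("diet_id", "marker")]
    frame = _numeric(frame, [c for c in frame.columns if c != "diet_id"], "fecal table")
    return [
        FecalSample(
            diet_id=str(row["diet_id"]),
            nutrients={c: float(row[c]) for c in nutrient_cols},
            marker=float(row["marker"]),
        )
        for _, row in frame.iterrows()
    ]


_TANK_COLUMNS = (
    "tank_id",
    "diet_id",
    "n_fish",
    "initial_weight",
    "final_weight",
    "feed_intake",
    "duration",
)


def read_tank_table(
    path: str | Path,
    sep: str = ",",
    diets: Sequence[DietFormulation] | None = None,
) -> list[TankRecord]:
    """Read tank biometry; cross-check diet ids when a diet table is given."""
    frame = _read_frame(path, sep)
    if frame.empty:
        logger.warning("tank table %s is empty", path)
        return []
    _require_columns(frame, _TANK_COLUMNS, "tank table")
    frame = _numeric(frame, _TANK_COLUMNS[2:], "tank table")
    tanks = [
        TankRecord(
            tank_id=str(row["tank_id"]),
            diet_id=str(row["diet_id"]),
            n_fish=int(row["n_fish"]),
            initial_weight=float(row["initial_weight"]),
            final_weight=float(row["final_weight"]),
            feed_intake=float(row["feed_intake"]),
            duration=float(row["duration"]),
        )
        for _, row in frame.iterrows()
    ]
    if diets is not None:
        known = {d.diet_id for d in diets}
        unknown = sorted({t.diet_id for t in tanks} - known)
        if unknown:
            raise TrialDataError(
                f"tank table references diet_id(s) absent from diet table: {unknown}"
            )
    return tanks


def read_fish_table(path: str | Path, sep: str = ",") -> list[FishRecord]:
    frame = _read_frame(path, sep)
    if frame.empty:
        logger.warning("fish table %s is empty", path)
        return []
    _require_columns(frame, ("fish_id", "tank_id", "body_weight"), "fish table")
    optional = [c for c in ("liver_weight", "viscera_weight") if c in frame.columns]
    frame = _numeric(frame, ["body_weight", *optional], "fish table")
    records = []
    for _, row in frame.iterrows():
        kwargs: dict[str, Any] = {}
        for column in optional:
            value = row[column]
            kwargs[column] = None if pd.isna(value) else float(value)
        records.append(
            FishRecord(
                fish_id=str(row["fish_id"]),
                tank_id=str(row["tank_id"]),
                body_weight=float(row["body_weight"]),
                **kwargs,
            )
        )
    return records


def read_adc_table(path: str | Path, sep: str = ",") -> AdcTable:
    """Read a long-format ADC table (columns diet_id, nutrient, adc)."""
    frame = _read_frame(path, sep)
    if frame.empty:
        logger.warning("ADC table %s is empty", path)
        return AdcTable()
    _require_columns(frame, ("diet_id", "nutrient", "adc"), "ADC table")
    frame = _numeric(frame, ("adc",), "ADC table")
    entries = {
        (str(row["diet_id"]), str(row["nutrient"])): float(row["adc"])
        for _, row in frame.iterrows()
    }
    return AdcTable(entries)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_frame(frame: pd.DataFrame, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats so write -> read round-trips exactly
    frame.to_csv(path, sep=sep, index=False, float_format=None)
    return path


def write_diet_table(
    diets: Sequence[DietFormulation], path: str | Path, sep: str = ","
) -> Path:
    nutrient_cols: list[str] = []
    for diet in diets:
        for name in diet.nutrients:
            if name not in nutrient_cols:
                nutrient_cols.append(name)
    rows = []
    for diet in diets:
        row: dict[str, Any] = {
            "diet_id": diet.diet_id,
            "marker": diet.marker,
            "dry_matter": diet.dry_matter,
        }
        if diet.gross_energy is not None:
            row["gross_energy"] = diet.gross_energy
        row.update({c: diet.nutrients.get(c) for c in nutrient_cols})
        rows.append(row)
    return _write_frame(pd.DataFrame(rows), path, sep)


def write_fecal_table(
    samples: Sequence[FecalSample], path: str | Path, sep: str = ","
) -> Path:
    rows = [
        {"diet_id": s.diet_id, "marker": s.marker, **s.nutrients} for s in samples
    ]
    return _write_frame(pd.DataFrame(rows), path, sep)


def write_tank_table(
    tanks: Sequence[TankRecord], path: str | Path, sep: str = ","
) -> Path:
    return _write_frame(
        pd.DataFrame([dataclasses.asdict(t) for t in tanks]), path, sep
    )


def write_fish_table(
    fish: Sequence[FishRecord], path: str | Path, sep: str = ","
) -> Path:
    return _write_frame(
        pd.DataFrame([dataclasses.asdict(f) for f in fish]), path, sep
    )


def write_adc_table(adc: AdcTable, path: str | Path, sep: str = ",") -> Path:
    rows = [
        {"diet_id": diet_id, "nutrient": nutrient, "adc": value}
        for (diet_id, nutrient), value in adc.entries.items()
    ]
    return _write_frame(pd.DataFrame(rows), path, sep)


def write_results(results: Any, path: str | Path, sep: str = ",") -> Path:
    """Serialize a staged result to delimited text (or JSON for mappings).

    Dispatches on type: lists of domain records go to their table writers;
    fit and requirement lists are written as flat tables (fits sorted by
    AIC ascending); a mapping becomes a JSON run summary.
    """
    if isinstance(results, AdcTable):
        return write_adc_table(results, path, sep)
    if isinstance(results, pd.DataFrame):
        return _write_frame(results, path, sep)
    if isinstance(results, Mapping):
        return write_run_summary(results, path)
    if isinstance(results, Sequence) and results:
        first = results[0]
        if isinstance(first, DietFormulation):
            return write_diet_table(results, path, sep)
        if isinstance(first, FecalSample):
            return write_fecal_table(results, path, sep)
        if isinstance(first, TankRecord):
            return write_tank_table(results, path, sep)
        if isinstance(first, FishRecord):
            return write_fish_table(results, path, sep)
        if dataclasses.is_dataclass(first):
            rows = [_flatten(dataclasses.asdict(r)) for r in results]
            frame = pd.DataFrame(rows)
            if "aic" in frame.columns:
                frame = frame.sort_values("aic", kind="stable")
            return _write_frame(frame, path, sep)
    raise TrialDataError(f"do not know how to serialize {type(results).__name__}")


def _flatten(record: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in record.items():
        name = f"{prefix}{key}"
        if isinstance(value, Mapping):
            flat.update(_flatten(value, f"{name}."))
        else:
            flat[name] = value
    return flat


def write_run_summary(summary: Mapping[str, Any], path: str | Path) -> Path:
    """Write a machine-readable key-value run summary (JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dict(summary), indent=2, default=str) + "\n")
    return path


def read_run_summary(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
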