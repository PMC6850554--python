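"""Tabular I/O for the midden cache-size analysis.

The analysis row is one midden: its relief, microclimate, vegetation and
food-availability covariates, the sex of the resident squirrel, and the
number of cache pits counted during the hoarding season (the proxy for
cache volume).  Everything travels as RFC-4180 CSV with "." decimals.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("middencache")

VALID_SEXES = ("male", "female", "unknown")

#: canonical numeric covariate columns, in Table-ordering
NUMERIC_COLUMNS = (
    "aspect_deg",
    "altitude_m",
    "declivity_deg",
    "air_temp_c",
    "soil_temp_c",
    "humidity_pct",
    "pit_temp_c",
    "scalepile_temp_c",
    "pit_cooling_c",
    "snow_cover_pct",
    "forest_cover_pct",
    "tree_density",
    "live_tree_density",
    "dead_tree_density",
    "live_conifer_density",
    "engelmann_density",
    "douglas_density",
    "ponderosa_density",
    "mushroom_g",
)

#: columns a midden table must provide (the rest may be absent)
REQUIRED_COLUMNS = ("midden_id", "aspect_deg", "sex", "n_pits")

#: densities and masses that must be non-negative when present
_NONNEGATIVE = (
    "tree_density",
    "live_tree_density",
    "dead_tree_density",
    "live_conifer_density",
    "engelmann_density",
    "douglas_density",
    "ponderosa_density",
    "mushroom_g",
)


class SchemaError(ValueError):
    """A table is missing mandatory columns or a cell fails validation."""


@dataclass
class MiddenRecord:
    """One midden's aggregated covariates, resident sex and pit count.

    Temperature/humidity fields hold baseline-corrected means (midden
    reading minus the fixed reference reading at the same time, averaged
    over visits), so they are comparable between middens.
    """

    midden_id: str
    aspect_deg: float
    sex: str
    n_pits: int
    altitude_m: float | None = None
    declivity_deg: float | None = None
    air_temp_c: float | None = None
    soil_temp_c: float | None = None
    humidity_pct: float | None = None
    pit_temp_c: float | None = None
    scalepile_temp_c: float | None = None
    pit_cooling_c: float | None = None
    snow_cover_pct: float | None = None
    forest_cover_pct: float | None = None
    tree_density: float | None = None
    live_tree_density: float | None = None
    dead_tree_density: float | None = None
    live_conifer_density: float | None = None
    engelmann_density: float | None = None
    douglas_density: float | None = None
    ponderosa_density: float | None = None
    mushroom_g: float | None = None
    excluded: bool = False
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= float(self.aspect_deg) < 360.0):
            raise ValueError(
                f"midden {self.midden_id!r}: aspect_deg {self.aspect_deg} "
                "outside [0, 360)"
            )
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"midden {self.midden_id!r}: sex {self.sex!r} not in {VALID_SEXES}"
            )
        self.n_pits = int(self.n_pits)
        if not self.excluded and self.n_pits < 1:
            raise ValueError(
                f"midden {self.midden_id!r}: retained midden needs n_pits >= 1, "
                f"got {self.n_pits}"
            )
        for name in _NONNEGATIVE:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(
                    f"midden {self.midden_id!r}: {name} must be non-negative, "
                    f"got {value}"
                )


@dataclass
class VisitMeasurement:
    """Raw timestamped readings from one visit to one midden.

    ``pit_temp_c`` is the mean over three randomly chosen pits.
    """

    midden_id: str
    timestamp: pd.Timestamp
    air_temp_c: float
    humidity_pct: float
    soil_temp_c: float
    scalepile_temp_c: float
    pit_temp_c: float


@dataclass
class BaselineSeries:
    """A fixed reference series (summit weather station or buried logger).

    Subtracting it from same-time midden readings removes diel and
    day-to-day weather swings, leaving a between-midden-comparable offset.
    """

    source: str  # "station" | "logger"
    records: pd.DataFrame  # columns: timestamp, value

    def __post_init__(self) -> None:
        if self.source not in ("station", "logger"):
            raise ValueError(f"baseline source must be station|logger, got {self.source!r}")
        ts = pd.to_datetime(self.records["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("baseline timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# midden table I/O


def _coerce_cell(column: str, value: Any, line: int) -> Any:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"line {line}: non-numeric value {value!r} in numeric column {column!r}"
        ) from None


def read_midden_table(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
) -> list[MiddenRecord]:
    """Read a per-midden covariate CSV into validated records.

    ``schema_map`` maps *file* column names to canonical ones, absorbing
    whatever headers a given dataset dialect uses.  Unknown columns are
    preserved in ``MiddenRecord.extras``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no header row") from None
    if schema_map:
        df = df.rename(columns=dict(schema_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    known = set(MiddenRecord.__dataclass_fields__) - {"extras"}
    records: list[MiddenRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line = i + 2  # header is line 1
        kwargs: dict[str, Any] = {}
        extras: dict[str, Any] = {}
        for col, value in row.items():
            if col in NUMERIC_COLUMNS:
                kwargs[col] = _coerce_cell(col, value, line)
            elif col == "n_pits":
                coerced = _coerce_cell(col, value, line)
                if coerced is None:
                    raise SchemaError(f"line {line}: missing n_pits")
                kwargs[col] = int(coerced)
            elif col == "excluded":
                kwargs[col] = str(value).strip().lower() in ("true", "1", "yes")
            elif col in known:
                kwargs[col] = str(value)
            else:
                extras[col] = value
        try:
            records.append(MiddenRecord(extras=extras, **kwargs))
        except ValueError as exc:
            raise SchemaError(f"line {line}: {exc}") from None
    logger.info("read %d midden records from %s", len(records), path)
    return records


def records_to_frame(records: Iterable[MiddenRecord]) -> pd.DataFrame:
    """Flatten records (extras included) into an analysis DataFrame."""
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        extras = d.pop("extras")
        d.update(extras)
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[MiddenRecord]:
    known = set(MiddenRecord.__dataclass_fields__) - {"extras"}
    records = []
    for row in df.to_dict(orient="records"):
        kwargs = {k: v for k, v in row.items() if k in known}
        extras = {k: v for k, v in row.items() if k not in known}
        for k, v in list(kwargs.items()):
            if isinstance(v, float) and np.isnan(v):
                kwargs[k] = None
        records.append(MiddenRecord(extras=extras, **kwargs))
    return records


def write_midden_table(records: Iterable[MiddenRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# selection table I/O


def write_selection_table(table, path: str | Path) -> None:
    """Write a ranked model-selection table as CSV.

    Columns and printed precision mirror the conventional multimodel
    summary: ΔAICc to 1 decimal, Akaike weight to 4, bootstrap selection
    frequency to 3, rows sorted ascending by ΔAICc.
    """
    df = table.to_frame()
    if df.empty:
        raise ValueError("selection table is empty")
    out = pd.DataFrame(
        {
            "model_label": df["model_label"],
            "delta_aicc": df["delta_aicc"].map(lambda v: f"{v:.1f}"),
            "df": df["k"].astype(int),
            "waicc": df["waicc"].map(lambda v: f"{v:.4f}"),
            "pi": df["pi"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}"),
        }
    )
    out.to_csv(path, index=False)
    logger.info("wrote selection table (%d models) to %s", len(out), path)


def read_selection_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# flat key=value config files


def save_config(config, path: str | Path) -> None:
    """Serialize a dataclass config as flat key=value lines."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{f.name}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(cls, path: str | Path):
    """Inverse of :func:`save_config` for a given dataclass type."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        text = raw[f.name]
        if f.type in ("int", int):
            kwargs[f.name] = int(text)
        elif f.type in ("float", float):
            kwargs[f.name] = float(text)
        elif f.type in ("bool", bool):
            kwargs[f.name] = text.lower() in ("true", "1", "yes")
        elif "tuple" in str(f.type):
            kwargs[f.name] = tuple(float(v) for v in text.split(",") if v)
        elif text == "uniform":
            kwargs[f.name] = "uniform"
        elif "," in text and "aspect" in f.name:
            kwargs[f.name] = tuple(float(v) for v in text.split(","))
        else:
            kwargs[f.name] = text
    return cls(**kwargs)
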