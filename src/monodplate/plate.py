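"""Plate-reader data model and delimited-text I/O.

The interchange format is a long (tidy) table with one row per
(well, time point) observation.  Concentrations are stored as mass of the
limiting *element* (μg/l of N or of P, totals including the medium
background); times are decimal days from inoculation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "WellSeries",
    "PlateSet",
    "DEFAULT_SCHEMA",
    "read_plate",
    "write_plate",
    "write_results",
]

#: Canonical column names of the long plate table.  ``read_plate`` accepts a
#: ``schema`` mapping from these canonical names to the names actually present
#: in the file.
DEFAULT_SCHEMA: dict[str, str] = {
    "well_id": "well_id",
    "strain": "strain",
    "state": "state",
    "nutrient": "nutrient",
    "concentration": "concentration_ug_per_l",
    "replicate": "replicate",
    "is_control": "is_control",
    "time": "time_days",
    "fluorescence": "rfu",
}

_STATES = frozenset({"axenic", "xenic"})
_NUTRIENTS = frozenset({"N", "P"})


@dataclass
class WellSeries:
    """One well's fluorescence time course plus treatment metadata.

    Parameters
    ----------
    well_id
        Unique well label within the plate.
    strain
        Host strain label (ignored downstream for control wells).
    state
        ``"axenic"`` (no microbiome) or ``"xenic"`` (microbiome added).
    nutrient
        Limiting element assayed, ``"N"`` or ``"P"``.
    concentration
        Total supplied concentration of the limiting element in μg/l,
        including the medium background.
    replicate
        Positive replicate index within (strain, state, concentration).
    is_control
        True for media-blank wells carrying no inoculum.
    times
        Sampling times in days, strictly increasing, length >= 2.
    fluorescence
        Phycocyanin signal in relative fluorescence units, strictly positive.
    """

    well_id: str
    strain: str
    state: str
    nutrient: str
    concentration: float
    replicate: int
    is_control: bool
    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValidationError(f"well {self.well_id}: times/fluorescence must be 1-D")
        if len(self.times) != len(self.fluorescence):
            raise ValidationError(
                f"well {self.well_id}: times and fluorescence lengths differ"
            )
        if len(self.times) < 2:
            raise ValidationError(f"well {self.well_id}: needs >= 2 time points")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.fluorescence)
        ):
            raise ValidationError(f"well {self.well_id}: non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"well {self.well_id}: times not strictly increasing"
            )
        if np.any(self.fluorescence <= 0):
            raise ValidationError(f"well {self.well_id}: nonpositive fluorescence")
        if self.concentration < 0:
            raise ValidationError(f"well {self.well_id}: negative concentration")
        if not self.is_control:
            if self.state not in _STATES:
                raise ValidationError(
                    f"well {self.well_id}: state must be one of {sorted(_STATES)}"
                )
            if int(self.replicate) < 1:
                raise ValidationError(f"well {self.well_id}: replicate must be >= 1")
        if self.nutrient not in _NUTRIENTS:
            raise ValidationError(
                f"well {self.well_id}: nutrient must be one of {sorted(_NUTRIENTS)}"
            )

    @property
    def n_points(self) -> int:
        return len(self.times)

    def group_key(self) -> tuple[str, str, float, int]:
        """(strain, state, concentration, replicate) treatment key."""
        return (self.strain, self.state, float(self.concentration), int(self.replicate))


@dataclass
class PlateSet:
    """A collection of wells sharing one nutrient gradient."""

    wells: list[WellSeries]
    nutrient_assayed: str
    gradient: list[float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nutrient_assayed not in _NUTRIENTS:
            raise ValidationError("nutrient_assayed must be 'N' or 'P'")
        grad = sorted(float(g) for g in self.gradient)
        self.gradient = grad
        seen: set[tuple[str, str, float, int]] = set()
        for w in self.wells:
            if w.is_control:
                continue
            if not any(np.isclose(w.concentration, g, rtol=1e-9) for g in grad):
                raise ValidationError(
                    f"well {w.well_id}: concentration {w.concentration} "
                    "not in the plate gradient"
                )
            key = w.group_key()
            if key in seen:
                raise ValidationError(
                    f"duplicate replicate index for treatment {key}"
                )
            seen.add(key)

    @property
    def treatment_wells(self) -> list[WellSeries]:
        return [w for w in self.wells if not w.is_control]

    @property
    def control_wells(self) -> list[WellSeries]:
        return [w for w in self.wells if w.is_control]

    def groups(self) -> dict[tuple[str, str, float], list[WellSeries]]:
        """Treatment wells grouped by (strain, state, concentration)."""
        out: dict[tuple[str, str, float], list[WellSeries]] = {}
        for w in self.treatment_wells:
            out.setdefault((w.strain, w.state, float(w.concentration)), []).append(w)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            for t, f in zip(w.times, w.fluorescence):
                rows.append(
                    {
                        "well_id": w.well_id,
                        "strain": w.strain,
                        "state": w.state,
                        "nutrient": w.nutrient,
                        "concentration_ug_per_l": w.concentration,
                        "replicate": w.replicate,
                        "is_control": w.is_control,
                        "time_days": t,
                        "rfu": f,
                    }
                )
        return pd.DataFrame(rows)


def _sniff_delimiter(path: str | Path) -> str:
    """Detect comma vs tab vs semicolon from the header line."""
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get) if any(counts.values()) else ","


def _require_columns(df: pd.DataFrame, schema: Mapping[str, str]) -> None:
    missing = [schema[k] for k in DEFAULT_SCHEMA if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def read_plate(path: str | Path, schema: Mapping[str, str] | None = None) -> PlateSet:
    """Read a long-format plate table (CSV or TSV, delimiter auto-detected).

    Rows belonging to the same well are assembled in time order regardless of
    file order, so the reader is invariant to row permutations.
    """
    full_schema = dict(DEFAULT_SCHEMA)
    if schema:
        full_schema.update(schema)
    df = pd.read_csv(path, sep=_sniff_delimiter(path),
                     float_precision="round_trip")
    _require_columns(df, full_schema)
    inv = {v: k for k, v in full_schema.items()}
    df = df.rename(columns=inv)

    for col in ("concentration", "time", "fluorescence"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {full_schema[col]!r} is not numeric: {exc}")
    df["is_control"] = df["is_control"].astype(bool)

    wells: list[WellSeries] = []
    for well_id, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("time", kind="stable")
        times = sub["time"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"well {well_id}: duplicate or non-increasing timestamps"
            )
        first = sub.iloc[0]
        wells.append(
            WellSeries(
                well_id=str(well_id),
                strain=str(first["strain"]),
                state=str(first["state"]),
                nutrient=str(first["nutrient"]),
                concentration=float(first["concentration"]),
                replicate=int(first["replicate"]),
                is_control=bool(first["is_control"]),
                times=times,
                fluorescence=sub["fluorescence"].to_numpy(float),
            )
        )
    nutrients = sorted({w.nutrient for w in wells})
    if len(nutrients) != 1:
        raise ValidationError(f"plate mixes nutrients: {nutrients}")
    gradient = sorted({float(w.concentration) for w in wells if not w.is_control})
    return PlateSet(wells=wells, nutrient_assayed=nutrients[0], gradient=gradient)


def write_plate(plate: PlateSet, path: str | Path) -> None:
    """Write a PlateSet as a long CSV with full float precision."""
    _write_frame(plate.to_frame(), path)


def _write_frame(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly.
    df.to_csv(path, index=False, float_format="%.17g")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write one delimited text table per result kind.

    ``tables`` maps a result name (e.g. ``"growth_estimates"``) to a
    DataFrame; each is written to ``<out_dir>/<name>.csv`` with a header row
    and full-precision floats.  Empty tables produce a header-only file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        _write_frame(df, p)
        written.append(p)
    return written


def frame_to_string(df: pd.DataFrame) -> str:
    """Serialize a result table to CSV text (full precision), for hashing."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    return buf.getvalue()
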