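"""Track-table data model, validation and delimited-text I/O.

The interchange format of the whole pipeline is a long-format table with one
row per cell per frame.  Columns (in order)::

    replicate_id, chamber_id, frame, time_h, track_id, cell_type,
    x_um, y_um, length_um, area_um2

Coordinates are chamber-local micrometres with the origin at the chamber
corner adjacent to the main feeding channel; frames are 0-based and spaced by
a fixed interval (5 min by default, so ``time_h = frame * 5 / 60``).
``cell_type`` is ``WT`` (prototrophic wildtype) or ``AUX`` (amino-acid
auxotroph).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: canonical column order of the track CSV schema
COLUMNS = [
    "replicate_id",
    "chamber_id",
    "frame",
    "time_h",
    "track_id",
    "cell_type",
    "x_um",
    "y_um",
    "length_um",
    "area_um2",
]

NUMERIC_COLUMNS = ["frame", "time_h", "track_id", "x_um", "y_um", "length_um", "area_um2"]
CELL_TYPES = frozenset({"WT", "AUX"})
TRACK_KEY = ["replicate_id", "chamber_id", "track_id"]

#: default chamber side length in micrometres (square growth chamber)
DEFAULT_CHAMBER_SIDE_UM = 40.0

#: default pixel size of the imaging setup, micrometres per pixel
DEFAULT_UM_PER_PIXEL = 0.065


class TrackSchemaError(ValueError):
    """The file or frame does not conform to the track-table schema."""


class TrackValidationError(ValueError):
    """The table violates a track-table invariant."""


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {c: c.strip().lower() for c in df.columns}
    return df.rename(columns=mapping)


def read_tracks(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a track table from a delimited text file.

    Parameters
    ----------
    path
        CSV file with a mandatory header row; column names are matched
        case-insensitively against the schema.
    sep
        Field delimiter (comma by default).

    Returns
    -------
    pandas.DataFrame
        Validated table sorted by (replicate_id, chamber_id, track_id, frame).

    Raises
    ------
    TrackSchemaError
        If a required column is missing or a numeric field fails to parse.
    TrackValidationError
        If the parsed table violates a table invariant (see
        :func:`validate_tracks`).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = _normalize_columns(df)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrackSchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2  # 1-based, after header
            raise TrackSchemaError(f"non-numeric value in column {col!r} at file line {row}")
        df[col] = parsed
    df["frame"] = df["frame"].astype(np.int64)
    df["track_id"] = df["track_id"].astype(np.int64)
    df["cell_type"] = df["cell_type"].str.strip().str.upper()
    report = validate_tracks(df)
    if report:
        raise TrackValidationError("invalid track table:\n" + "\n".join(report))
    return sort_tracks(df)


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as CSV (header, comma-separated, full precision).

    The written file round-trips: ``read_tracks(write_tracks(t))`` reproduces
    ``t`` at value level (floats are written with shortest round-trip repr).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[COLUMNS].to_csv(path, index=False)


def sort_tracks(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(TRACK_KEY + ["frame"], kind="mergesort").reset_index(drop=True)


def validate_tracks(
    table: pd.DataFrame, chamber_side_um: float = DEFAULT_CHAMBER_SIDE_UM
) -> list[str]:
    """Check every track-table invariant; return a report of violations.

    An empty list means the table is valid.  Checks performed:

    - all schema columns present
    - ``frame`` non-negative, ``length_um``/``area_um2`` strictly positive
    - coordinates within ``[0, chamber_side_um]``
    - ``cell_type`` in {WT, AUX} and constant within a track
    - (replicate, chamber, track, frame) unique
    - frames within a track form a consecutive integer run
    """
    report: list[str] = []
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        return [f"missing column(s): {', '.join(missing)}"]
    if table.empty:
        return report

    if (table["frame"] < 0).any():
        rows = table.index[table["frame"] < 0].tolist()[:5]
        report.append(f"negative frame at rows {rows}")
    for col in ("length_um", "area_um2"):
        bad = ~(table[col] > 0)
        if bad.any():
            report.append(f"non-positive {col} at rows {table.index[bad].tolist()[:5]}")
    for col in ("x_um", "y_um"):
        bad = (table[col] < 0) | (table[col] > chamber_side_um)
        if bad.any():
            report.append(
                f"{col} outside [0, {chamber_side_um}] at rows {table.index[bad].tolist()[:5]}"
            )
    bad_type = ~table["cell_type"].isin(CELL_TYPES)
    if bad_type.any():
        report.append(
            f"cell_type not in {sorted(CELL_TYPES)} at rows {table.index[bad_type].tolist()[:5]}"
        )

    dup = table.duplicated(subset=TRACK_KEY + ["frame"], keep=False)
    if dup.any():
        keys = table.loc[dup, TRACK_KEY + ["frame"]].drop_duplicates().head(5)
        report.append(f"duplicate (track, frame) keys:\n{keys.to_string(index=False)}")

    grouped = table.sort_values("frame").groupby(TRACK_KEY, sort=False)
    n_types = grouped["cell_type"].nunique()
    flip = n_types[n_types > 1]
    if len(flip):
        report.append(f"cell_type changes within track(s): {flip.index.tolist()[:5]}")
    frames = grouped["frame"].agg(["min", "max", "size"])
    gapped = frames[(frames["max"] - frames["min"] + 1) != frames["size"]]
    if len(gapped):
        report.append(f"non-consecutive frames within track(s): {gapped.index.tolist()[:5]}")
    return report


def split_on_frame_gaps(table: pd.DataFrame) -> pd.DataFrame:
    """Split tracks with missing frames into maximal consecutive runs.

    The growth fit and the minimum-frame filter are defined on consecutive
    frames, so a track interrupted by a tracking gap is treated as separate
    tracks.  The first run keeps the original ``track_id``; later runs get
    fresh ids above the per-(replicate, chamber) maximum.
    """
    table = sort_tracks(table)
    out = table.copy()
    gap = out.groupby(TRACK_KEY, sort=False)["frame"].diff().fillna(1) > 1
    if not gap.any():
        return out
    segment = gap.groupby([out[k] for k in TRACK_KEY], sort=False).cumsum().astype(int)
    out["_seg"] = segment
    for (rep, cham), sub in out.groupby(["replicate_id", "chamber_id"], sort=False):
        next_id = int(sub["track_id"].max()) + 1
        for (tid, seg), idx in sub.groupby(["track_id", "_seg"], sort=False).groups.items():
            if seg == 0:
                continue
            out.loc[idx, "track_id"] = next_id
            next_id += 1
    return sort_tracks(out.drop(columns="_seg"))


def pixels_to_um(
    table: pd.DataFrame, um_per_pixel: float = DEFAULT_UM_PER_PIXEL
) -> pd.DataFrame:
    """Convert pixel-unit geometry columns to micrometres at ingest.

    Applies ``um_per_pixel`` to coordinates and lengths and its square to
    areas.  All downstream modules assume micrometres.
    """
    if not um_per_pixel > 0:
        raise ValueError("um_per_pixel must be strictly positive")
    out = table.copy()
    for col in ("x_um", "y_um", "length_um"):
        out[col] = out[col] * um_per_pixel
    out["area_um2"] = out["area_um2"] * um_per_pixel**2
    return out


def concat_tracks(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    parts = [t for t in tables if len(t)]
    if not parts:
        return pd.DataFrame(columns=COLUMNS)
    return sort_tracks(pd.concat(parts, ignore_index=True))
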