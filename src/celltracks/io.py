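"""Delimited-text track I/O.

Tracks are read from plain-text tables with one row per observation and
columns mappable to (id, t, x, y[, z]). The default dialect is a
comma-delimited file with a header row and columns named id,t,x,y[,z];
arbitrary headers and delimiters are handled by a :class:`Dialect`
(optionally loaded from a plain-text key: value file).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import Track, TracksDataset

__all__ = ["Dialect", "read_tracks", "write_tracks"]


@dataclass
class Dialect:
    """Column mapping and delimiter for track tables."""

    delimiter: str = ","
    id_col: str = "id"
    time_col: str = "t"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str | None = "z"  # used only if present in the file
    time_unit: str = "min"
    space_unit: str = "micrometer"

    @classmethod
    def from_file(cls, path) -> "Dialect":
        """Load a dialect from a YAML/key: value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**raw)


def read_tracks(path, dialect: Dialect | None = None) -> TracksDataset:
    """Read a delimited track table into a :class:`TracksDataset`.

    Rows are grouped by id and sorted by time within each track; the
    dataset dimensionality is 3 when the mapped z column is present in the
    file, else 2. Duplicate (id, t) pairs and non-numeric coordinates are
    errors.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    mapped = {dialect.id_col: "id", dialect.time_col: "t",
              dialect.x_col: "x", dialect.y_col: "y"}
    missing = [c for c in mapped if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mapped column(s) {missing} in {path}")
    has_z = dialect.z_col is not None and dialect.z_col in raw.columns
    if has_z:
        mapped[dialect.z_col] = "z"
    df = raw[list(mapped)].rename(columns=mapped)

    numeric_cols = ["t", "x", "y"] + (["z"] if has_z else [])
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            # +2: 1-based row numbers counting the header line
            row = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at row {row} of {path}"
            )
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2
            raise ValueError(f"missing value in column {col!r} at row {row} of {path}")
        df[col] = vals

    tracks = []
    for tid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("t")
        t = grp["t"].to_numpy()
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            raise ValueError(
                f"duplicate (id, t) pair: id={tid!r}, t={t[dup[0]]}"
            )
        coords = grp[["x", "y", "z"] if has_z else ["x", "y"]].to_numpy()
        tracks.append(Track(str(tid), t, coords))
    return TracksDataset(tracks, time_unit=dialect.time_unit,
                         space_unit=dialect.space_unit)


def write_tracks(dataset: TracksDataset, path, delimiter: str = ",") -> None:
    """Write a dataset as a delimited table with header id,t,x,y[,z]."""
    dataset.as_table().to_csv(path, sep=delimiter, index=False)
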