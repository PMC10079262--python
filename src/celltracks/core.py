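"""Track / TracksDataset data model and subtrack decomposition.

A *track* is the time-ordered sequence of positions of one tracked cell;
a *step* is the displacement between two consecutive observations. All
analysis scales (cell-based, step-based, staggered) are built on contiguous
slices of tracks ("subtracks"), whose length always counts steps, not
observations.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "Subtrack",
    "SubtrackSet",
    "TracksDataset",
    "subtracks",
    "staggered_subtracks",
]


class Track:
    """Time-ordered positions of one cell.

    Parameters
    ----------
    id : str
        Track label, unique within a dataset.
    times : array-like, shape (n,)
        Strictly increasing timestamps (minutes by convention).
    positions : array-like, shape (n, d)
        Coordinates (micrometers by convention), d in {2, 3}.
    """

    __slots__ = ("id", "times", "positions")

    def __init__(self, id: str, times, positions):
        t = np.asarray(times, dtype=float)
        p = np.asarray(positions, dtype=float)
        if p.ndim == 1:
            p = p.reshape(1, -1)
        if t.ndim != 1 or t.size == 0:
            raise ValueError(f"track {id!r}: need at least one observation")
        if p.shape[0] != t.size:
            raise ValueError(
                f"track {id!r}: {t.size} timestamps but {p.shape[0]} positions"
            )
        if p.shape[1] not in (2, 3):
            raise ValueError(f"track {id!r}: dimensionality must be 2 or 3, got {p.shape[1]}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError(f"track {id!r}: non-finite time or coordinate")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"track {id!r}: times must be strictly increasing")
        self.id = str(id)
        self.times = t
        self.positions = p

    # -- basic geometry ---------------------------------------------------

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def n_obs(self) -> int:
        return self.times.size

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    def steps(self) -> np.ndarray:
        """Step displacement vectors, shape (n_steps, dim)."""
        return np.diff(self.positions, axis=0)

    def step_durations(self) -> np.ndarray:
        return np.diff(self.times)

    def displacement_vector(self) -> np.ndarray:
        return self.positions[-1] - self.positions[0]

    def slice(self, i: int, j: int) -> "Subtrack":
        """Subtrack over observation indices [i, j], both inclusive, j > i."""
        return Subtrack(self, i, j)

    # -- dunder helpers ---------------------------------------------------

    def __len__(self) -> int:
        return self.n_obs

    def __repr__(self) -> str:
        return f"Track({self.id!r}, n_obs={self.n_obs}, dim={self.dim})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Track)
            and self.id == other.id
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.positions, other.positions)
        )

    def __hash__(self):
        return hash((self.id, self.times.tobytes(), self.positions.tobytes()))

    def translated(self, offset) -> "Track":
        return Track(self.id, self.times, self.positions + np.asarray(offset, dtype=float))


class Subtrack(Track):
    """Contiguous slice of a parent track; behaves as a Track."""

    __slots__ = ("parent_id", "start", "end")

    def __init__(self, parent: Track, i: int, j: int):
        if not (0 <= i < j <= parent.n_obs - 1):
            raise ValueError(
                f"invalid subtrack range [{i}, {j}] for track {parent.id!r} "
                f"with {parent.n_obs} observations"
            )
        super().__init__(
            f"{parent.id}[{i},{j}]", parent.times[i : j + 1], parent.positions[i : j + 1]
        )
        self.parent_id = parent.id
        self.start = i
        self.end = j


class SubtrackSet:
    """Ordered collection of subtracks produced by a decomposition."""

    def __init__(self, elements: Iterable[Subtrack]):
        self._elements = list(elements)

    def __iter__(self) -> Iterator[Subtrack]:
        return iter(self._elements)

    def __len__(self) -> int:
        return len(self._elements)

    def __getitem__(self, i):
        return self._elements[i]

    def __repr__(self) -> str:
        return f"SubtrackSet(n={len(self)})"


class TracksDataset(Mapping):
    """Named collection of tracks sharing dimensionality and units.

    Tracks iterate in lexicographic id order so that every downstream
    statistic is deterministic.
    """

    def __init__(self, tracks: Iterable[Track] = (), time_unit: str = "min",
                 space_unit: str = "micrometer"):
        store: dict[str, Track] = {}
        for tr in tracks:
            if tr.id in store:
                raise ValueError(f"duplicate track id {tr.id!r}")
            store[tr.id] = tr
        self._tracks = {k: store[k] for k in sorted(store)}
        dims = {tr.dim for tr in self._tracks.values()}
        if len(dims) > 1:
            raise ValueError(f"tracks mix dimensionalities: {sorted(dims)}")
        self._dim = dims.pop() if dims else None
        self.time_unit = time_unit
        self.space_unit = space_unit

    @property
    def dim(self) -> int | None:
        return self._dim

    @property
    def n_tracks(self) -> int:
        return len(self._tracks)

    @property
    def n_obs(self) -> int:
        return sum(tr.n_obs for tr in self._tracks.values())

    @property
    def n_steps(self) -> int:
        return sum(tr.n_steps for tr in self._tracks.values())

    def __getitem__(self, id: str) -> Track:
        return self._tracks[id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._tracks)

    def __len__(self) -> int:
        return len(self._tracks)

    def tracks(self) -> Iterator[Track]:
        return iter(self._tracks.values())

    def __repr__(self) -> str:
        return f"TracksDataset(n_tracks={self.n_tracks}, dim={self.dim})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TracksDataset)
            and list(self) == list(other)
            and all(self[k] == other[k] for k in self)
        )

    def equals(self, other: "TracksDataset", rtol: float = 0.0, atol: float = 1e-9) -> bool:
        """Equality up to floating-point tolerance (for I/O round trips)."""
        if list(self) != list(other):
            return False
        for k in self:
            a, b = self[k], other[k]
            if a.n_obs != b.n_obs or a.dim != b.dim:
                return False
            if not np.allclose(a.times, b.times, rtol=rtol, atol=atol):
                return False
            if not np.allclose(a.positions, b.positions, rtol=rtol, atol=atol):
                return False
        return True

    # -- construction / conversion ----------------------------------------

    def with_tracks(self, tracks: Iterable[Track]) -> "TracksDataset":
        """New dataset with the given tracks, preserving units."""
        return TracksDataset(tracks, time_unit=self.time_unit, space_unit=self.space_unit)

    def subset(self, ids: Iterable[str]) -> "TracksDataset":
        return self.with_tracks(self[i] for i in ids)

    def map_tracks(self, fn: Callable[[Track], Track]) -> "TracksDataset":
        return self.with_tracks(fn(tr) for tr in self.tracks())

    def as_table(self) -> pd.DataFrame:
        """Long-format table with columns id, t, x, y[, z]."""
        coord_cols = ["x", "y", "z"][: self.dim] if self.dim else ["x", "y"]
        frames = []
        for tr in self.tracks():
            df = pd.DataFrame(tr.positions, columns=coord_cols)
            df.insert(0, "t", tr.times)
            df.insert(0, "id", tr.id)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["id", "t", *coord_cols])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_table(cls, table: pd.DataFrame, time_unit: str = "min",
                   space_unit: str = "micrometer") -> "TracksDataset":
        """Inverse of :meth:`as_table`.

        Rows are grouped by id and sorted by t within each track; the
        dimensionality is inferred from the presence of a z column.
        """
        cols = list(table.columns)
        for required in ("id", "t", "x", "y"):
            if required not in cols:
                raise ValueError(f"missing column {required!r}")
        coord_cols = ["x", "y", "z"] if "z" in cols else ["x", "y"]
        if table[coord_cols].isna().any().any():
            bad = int(table[coord_cols].isna().any(axis=1).idxmax())
            raise ValueError(f"inconsistent or missing coordinates at row {bad}")
        tracks = []
        for tid, grp in table.groupby("id", sort=True):
            grp = grp.sort_values("t")
            t = grp["t"].to_numpy(dtype=float)
            dup = np.flatnonzero(np.diff(t) == 0)
            if dup.size:
                raise ValueError(
                    f"duplicate timestamp t={t[dup[0]]} in track {tid!r}"
                )
            tracks.append(Track(str(tid), t, grp[coord_cols].to_numpy(dtype=float)))
        return cls(tracks, time_unit=time_unit, space_unit=space_unit)


def subtracks(dataset: TracksDataset | Track, length: int, overlap: int | None = None) -> SubtrackSet:
    """Decompose tracks into subtracks of ``length`` steps.

    Consecutive subtracks from the same parent start ``length - overlap``
    steps apart. With maximal overlap (``length - 1``, the default) a track
    with n steps yields n - length + 1 subtracks; with overlap 0 it yields
    floor(n / length). Tracks shorter than ``length`` contribute none.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if overlap is None:
        overlap = length - 1
    if not 0 <= overlap <= length - 1:
        raise ValueError(f"overlap must be in [0, {length - 1}], got {overlap}")
    stride = length - overlap
    parents = dataset.tracks() if isinstance(dataset, TracksDataset) else [dataset]
    out = []
    for tr in parents:
        n = tr.n_steps
        for i in range(0, n - length + 1, stride):
            out.append(tr.slice(i, i + length))
    return SubtrackSet(out)


def staggered_subtracks(track: Track) -> SubtrackSet:
    """All contiguous subtracks [i, j], i < j, of one track.

    A track with n steps yields n(n+1)/2 subtracks, suitable for rendering
    any measure as a triangular matrix over (start, end) observation pairs.
    """
    n = track.n_obs
    out = [track.slice(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    return SubtrackSet(out)
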