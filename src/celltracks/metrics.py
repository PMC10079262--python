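"""Scalar motility measures on (sub)tracks and their aggregation over lags.

Every measure is a plain function ``Track -> float`` (NaN marks an
undefined result: zero-length tracks, zero-duration speeds, degenerate
angles). Any user function with the same contract is accepted wherever a
built-in measure is, including :func:`apply_measure`, :func:`aggregate`,
feature matrices and track selection.

Angles are reported in degrees and computed via the two-argument
arctangent of (||u x v||, u.v), which is numerically stable near 0 and
180 degrees where arccos of the cosine is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .core import SubtrackSet, Track, TracksDataset, staggered_subtracks, subtracks

__all__ = [
    "displacement", "square_displacement", "max_displacement",
    "track_length", "duration", "speed",
    "straightness", "displacement_ratio", "outreach_ratio",
    "turning_angles", "mean_turning_angle", "overall_angle", "overall_dot",
    "asphericity", "n_observations",
    "angle_between", "angle_degrees",
    "MEASURES", "apply_measure", "staggered_matrix",
    "MSDCurve", "aggregate", "modal_dt",
]

MeasureFn = Callable[[Track], float]


# --------------------------------------------------------------------------
# angle helpers

def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in radians, in [0, pi]; NaN if either is 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.any(u) and np.any(v)):
        return float("nan")
    if u.size == 3:
        cross = float(np.linalg.norm(np.cross(u, v)))
    else:
        cross = abs(float(u[0] * v[1] - u[1] * v[0]))
    return float(np.arctan2(cross, float(u @ v)))


def angle_degrees(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(angle_between(u, v)))


# --------------------------------------------------------------------------
# displacement family

def displacement(track: Track) -> float:
    """Euclidean distance between first and last observation (um)."""
    return float(np.linalg.norm(track.displacement_vector()))


def square_displacement(track: Track) -> float:
    """Squared net displacement (um^2); the measure behind MSD curves."""
    return float(np.sum(track.displacement_vector() ** 2))


def max_displacement(track: Track) -> float:
    """Maximum distance from the starting point over all observations (um)."""
    rel = track.positions - track.positions[0]
    return float(np.sqrt((rel**2).sum(axis=1).max()))


def track_length(track: Track) -> float:
    """Total path length: sum of step lengths (um)."""
    return float(np.linalg.norm(track.steps(), axis=1).sum())


def duration(track: Track) -> float:
    """Elapsed time between first and last observation (min)."""
    return float(track.times[-1] - track.times[0])


def speed(track: Track) -> float:
    """Mean speed: path length / duration (um/min); NaN for zero duration."""
    d = duration(track)
    if d == 0:
        return float("nan")
    return track_length(track) / d


# --------------------------------------------------------------------------
# straightness family — all in [0, 1] where defined

def straightness(track: Track) -> float:
    """Net displacement over path length; 1 for straight motion."""
    length = track_length(track)
    if length == 0:
        return float("nan")
    return displacement(track) / length


def displacement_ratio(track: Track) -> float:
    """Net displacement over maximal displacement; 0 for closed loops."""
    m = max_displacement(track)
    if m == 0:
        return float("nan")
    return displacement(track) / m


def outreach_ratio(track: Track) -> float:
    """Maximal displacement over path length."""
    length = track_length(track)
    if length == 0:
        return float("nan")
    return max_displacement(track) / length


# --------------------------------------------------------------------------
# angle family

def turning_angles(track: Track) -> np.ndarray:
    """Angle (degrees, [0, 180]) between consecutive steps, per interior vertex.

    Vertices adjacent to a zero-length step are NaN (undefined).
    """
    steps = track.steps()
    return np.array(
        [angle_degrees(steps[k], steps[k + 1]) for k in range(len(steps) - 1)]
    )


def mean_turning_angle(track: Track) -> float:
    """Mean of the defined turning angles (degrees); NaN if none defined."""
    ang = turning_angles(track)
    ang = ang[~np.isnan(ang)]
    if ang.size == 0:
        return float("nan")
    return float(ang.mean())


def overall_angle(track: Track) -> float:
    """Angle (degrees) between the first and last step of the (sub)track.

    On subtracks of lag L this is the angle autocorrelation measure; on a
    single-step subtrack it is 0 by construction.
    """
    steps = track.steps()
    if len(steps) == 0:
        return float("nan")
    return angle_degrees(steps[0], steps[-1])


def overall_dot(track: Track) -> float:
    """Dot product (um^2) of the first and last step of the (sub)track."""
    steps = track.steps()
    if len(steps) == 0:
        return float("nan")
    return float(steps[0] @ steps[-1])


# --------------------------------------------------------------------------
# shape

def asphericity(track: Track) -> float:
    """Gyration-tensor asphericity in [0, 1].

    From the eigenvalues l_1 >= ... >= l_d of the gyration tensor of the
    observation positions (unweighted):

        A = sum_{i<j} (l_i - l_j)^2 / ((d - 1) (sum_i l_i)^2)

    1 for collinear tracks, 0 for fully isotropic configurations; NaN when
    all points coincide.
    """
    pos = track.positions
    centered = pos - pos.mean(axis=0)
    gyr = centered.T @ centered / pos.shape[0]
    lam = np.linalg.eigvalsh(gyr)
    total = lam.sum()
    if total <= 0:
        return float("nan")
    d = lam.size
    num = sum(
        (lam[i] - lam[j]) ** 2 for i in range(d) for j in range(i + 1, d)
    )
    return float(num / ((d - 1) * total**2))


def n_observations(track: Track) -> float:
    return float(track.n_obs)


#: Registry of built-in measures: name -> (function, units).
MEASURES: dict[str, tuple[MeasureFn, str]] = {
    "displacement": (displacement, "um"),
    "square_displacement": (square_displacement, "um^2"),
    "max_displacement": (max_displacement, "um"),
    "track_length": (track_length, "um"),
    "duration": (duration, "min"),
    "speed": (speed, "um/min"),
    "straightness": (straightness, "1"),
    "displacement_ratio": (displacement_ratio, "1"),
    "outreach_ratio": (outreach_ratio, "1"),
    "mean_turning_angle": (mean_turning_angle, "deg"),
    "overall_angle": (overall_angle, "deg"),
    "overall_dot": (overall_dot, "um^2"),
    "asphericity": (asphericity, "1"),
    "n_observations": (n_observations, "1"),
}


def get_measure(name: str) -> MeasureFn:
    try:
        return MEASURES[name][0]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; available: {sorted(MEASURES)}"
        ) from None


# --------------------------------------------------------------------------
# application scales

def apply_measure(target: TracksDataset | SubtrackSet, measure: MeasureFn) -> pd.DataFrame:
    """Evaluate a measure on every element of a dataset or subtrack set.

    Cell-based analysis applies the measure over whole tracks (pass a
    dataset); step-based analysis applies it over fixed-length subtracks
    (pass ``subtracks(dataset, L, o)``). Undefined values propagate as NaN,
    never dropped silently.
    """
    if isinstance(target, TracksDataset):
        rows = [{"id": tr.id, "value": float(measure(tr))} for tr in target.tracks()]
        return pd.DataFrame(rows, columns=["id", "value"])
    rows = [
        {
            "id": st.parent_id,
            "start": st.start,
            "end": st.end,
            "value": float(measure(st)),
        }
        for st in target
    ]
    return pd.DataFrame(rows, columns=["id", "start", "end", "value"])


def staggered_matrix(track: Track, measure: MeasureFn) -> np.ndarray:
    """Measure over all contiguous subtracks, as an upper-triangular matrix.

    Entry (i, j), i < j, is the measure on the subtrack spanning observation
    indices [i, j]; the diagonal and lower triangle are NaN.
    """
    n = track.n_obs
    mat = np.full((n, n), np.nan)
    for st in staggered_subtracks(track):
        mat[st.start, st.end] = measure(st)
    return mat


# --------------------------------------------------------------------------
# aggregation over subtrack lengths (MSD / autocorrelation curves)

@dataclass
class MSDCurve:
    """A measure aggregated over all subtracks of each lag.

    ``table`` has one row per lag with columns lag_steps, lag_time, mean,
    var, n. With measure = square_displacement this is the mean squared
    displacement curve; with overall_dot the displacement autocovariance;
    with overall_angle the angle autocorrelation.
    """

    measure_name: str
    table: pd.DataFrame
    delta_t: float
    overlap: str = "max"

    @property
    def lags(self) -> np.ndarray:
        return self.table["lag_steps"].to_numpy()


def modal_dt(dataset: TracksDataset, rtol: float = 1e-6) -> float:
    """The dataset's common step duration.

    Raises if step durations are not uniform across the dataset (such data
    must be gap-repaired/interpolated first; lag-to-time conversion would
    otherwise be meaningless).
    """
    durs = np.concatenate([tr.step_durations() for tr in dataset.tracks()
                           if tr.n_steps > 0])
    if durs.size == 0:
        raise ValueError("dataset has no steps")
    ref = float(np.median(durs))
    if np.any(np.abs(durs - ref) > rtol * ref):
        raise ValueError(
            "step durations are not uniform; repair gaps or interpolate "
            "before lag-based aggregation"
        )
    return ref


def aggregate(
    dataset: TracksDataset,
    measure: MeasureFn | str,
    lags: Iterable[int] | None = None,
    overlap: str = "max",
) -> MSDCurve:
    """Aggregate a measure over all subtracks of each lag (in steps).

    Parameters
    ----------
    measure : callable or registry name
        Track -> scalar; fast vectorized paths exist for
        square_displacement, displacement, overall_dot and overall_angle.
    lags : iterable of int, optional
        Subtrack lengths in steps; defaults to 1 .. max steps over tracks.
    overlap : {"max", "none"}
        Maximally overlapping subtracks (default; larger n) or
        non-overlapping ones for independence-sensitive uses.

    Lags with no subtrack are reported with n = 0 and NaN mean/var.
    """
    name = measure if isinstance(measure, str) else getattr(measure, "__name__", "custom")
    fn = get_measure(measure) if isinstance(measure, str) else measure
    if overlap not in ("max", "none"):
        raise ValueError(f"overlap must be 'max' or 'none', got {overlap!r}")
    dt = modal_dt(dataset)
    if lags is None:
        max_steps = max((tr.n_steps for tr in dataset.tracks()), default=0)
        lags = range(1, max_steps + 1)
    lags = [int(L) for L in lags]
    if any(L < 1 for L in lags):
        raise ValueError("lags must be >= 1")

    fast = _FAST_PATHS.get(fn)
    rows = []
    for L in lags:
        if fast is not None:
            vals = np.concatenate(
                [fast(tr, L, overlap) for tr in dataset.tracks()]
            ) if dataset.n_tracks else np.empty(0)
        else:
            o = L - 1 if overlap == "max" else 0
            vals = np.array([fn(st) for st in subtracks(dataset, L, o)])
        vals = vals[np.isfinite(vals)]
        n = vals.size
        rows.append({
            "lag_steps": L,
            "lag_time": L * dt,
            "mean": float(vals.mean()) if n else float("nan"),
            "var": float(vals.var(ddof=1)) if n > 1 else float("nan"),
            "n": n,
        })
    return MSDCurve(name, pd.DataFrame(rows), dt, overlap)


def _lag_starts(n_steps: int, L: int, overlap: str) -> np.ndarray:
    stride = 1 if overlap == "max" else L
    return np.arange(0, n_steps - L + 1, stride)


def _fast_square_displacement(tr: Track, L: int, overlap: str) -> np.ndarray:
    starts = _lag_starts(tr.n_steps, L, overlap)
    if starts.size == 0:
        return np.empty(0)
    disp = tr.positions[starts + L] - tr.positions[starts]
    return (disp**2).sum(axis=1)


def _fast_displacement(tr: Track, L: int, overlap: str) -> np.ndarray:
    return np.sqrt(_fast_square_displacement(tr, L, overlap))


def _fast_overall_dot(tr: Track, L: int, overlap: str) -> np.ndarray:
    starts = _lag_starts(tr.n_steps, L, overlap)
    if starts.size == 0:
        return np.empty(0)
    steps = tr.steps()
    return np.einsum("ij,ij->i", steps[starts], steps[starts + L - 1])


def _fast_overall_angle(tr: Track, L: int, overlap: str) -> np.ndarray:
    starts = _lag_starts(tr.n_steps, L, overlap)
    if starts.size == 0:
        return np.empty(0)
    steps = tr.steps()
    u, v = steps[starts], steps[starts + L - 1]
    dot = np.einsum("ij,ij->i", u, v)
    if tr.dim == 3:
        cross = np.linalg.norm(np.cross(u, v), axis=1)
    else:
        cross = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    ang = np.degrees(np.arctan2(cross, dot))
    zero = (np.linalg.norm(u, axis=1) == 0) | (np.linalg.norm(v, axis=1) == 0)
    ang[zero] = np.nan
    return ang


_FAST_PATHS = {
    square_displacement: _fast_square_displacement,
    displacement: _fast_displacement,
    overall_dot: _fast_overall_dot,
    overall_angle: _fast_overall_angle,
}
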