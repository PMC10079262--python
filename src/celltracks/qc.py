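"""Quality control and preprocessing for track datasets.

Covers the classic tracking artifacts: "double tracking" (one cell tracked
as two near-identical tracks, detected in a distance-angle plot of all
track pairs), gaps in the sampling grid, short tracks, and global drift
(e.g. stage movement), plus interpolation and origin-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import Track, TracksDataset
from .metrics import MeasureFn, angle_degrees

__all__ = [
    "PairDiagnostics", "pair_diagnostics",
    "interpolate_track",
    "GapReport", "repair_gaps",
    "filter_tracks",
    "estimate_drift", "correct_drift",
    "normalize_tracks",
]


@dataclass
class PairDiagnostics:
    """Diagnostics for one unordered pair of temporally overlapping tracks.

    ``min_distance`` is the minimum over shared timepoints of the distance
    between the two cells; ``pair_angle`` the angle (degrees) between the
    tracks' overall displacement vectors. Duplicated cells appear at
    jointly low distance and low angle.
    """

    id_a: str
    id_b: str
    min_distance: float
    pair_angle: float
    n_shared: int


def _shared_time_indices(ta: np.ndarray, tb: np.ndarray, tol: float):
    """Indices into ta/tb of timestamps matching within tol (both sorted)."""
    ia, ib = [], []
    j = 0
    for i, t in enumerate(ta):
        while j < tb.size and tb[j] < t - tol:
            j += 1
        if j < tb.size and abs(tb[j] - t) <= tol:
            ia.append(i)
            ib.append(j)
            j += 1
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def pair_diagnostics(dataset: TracksDataset) -> tuple[list[PairDiagnostics], int]:
    """Distance-angle diagnostics for every pair of tracks with temporal overlap.

    Returns (records, n_omitted) where n_omitted counts pairs lacking any
    shared timestamp (within 1e-6 x the median step duration) or a defined
    overall-displacement angle.
    """
    ids = list(dataset)
    if len(ids) < 2:
        raise ValueError("pair diagnostics need at least 2 tracks")
    durs = np.concatenate(
        [dataset[i].step_durations() for i in ids if dataset[i].n_steps > 0]
    )
    tol = 1e-6 * float(np.median(durs)) if durs.size else 0.0
    records: list[PairDiagnostics] = []
    omitted = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            tr_a, tr_b = dataset[ids[a]], dataset[ids[b]]
            ia, ib = _shared_time_indices(tr_a.times, tr_b.times, tol)
            if ia.size == 0 or tr_a.n_steps == 0 or tr_b.n_steps == 0:
                omitted += 1
                continue
            diff = tr_a.positions[ia] - tr_b.positions[ib]
            min_dist = float(np.sqrt((diff**2).sum(axis=1).min()))
            ang = angle_degrees(tr_a.displacement_vector(), tr_b.displacement_vector())
            if np.isnan(ang):
                omitted += 1
                continue
            records.append(PairDiagnostics(ids[a], ids[b], min_dist, ang, int(ia.size)))
    return records, omitted


def pair_diagnostics_table(dataset: TracksDataset) -> pd.DataFrame:
    records, omitted = pair_diagnostics(dataset)
    df = pd.DataFrame(
        [vars(r) for r in records],
        columns=["id_a", "id_b", "min_distance", "pair_angle", "n_shared"],
    )
    df.attrs["n_omitted"] = omitted
    return df


def rank_product_pairs(records: list[PairDiagnostics]) -> pd.DataFrame:
    """Rank pairs by the product of their distance rank and angle rank.

    The top-ranked pair (lowest product) is the strongest double-tracking
    candidate; use on the output of :func:`pair_diagnostics`.
    """
    df = pd.DataFrame([vars(r) for r in records])
    df["rank_product"] = (
        df["min_distance"].rank(method="average")
        * df["pair_angle"].rank(method="average")
    )
    return df.sort_values("rank_product", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# interpolation

def interpolate_track(track: Track, new_times, method: str = "linear") -> Track:
    """Resample a track at ``new_times`` (within the original time span).

    Linear interpolation reproduces original observations exactly; cubic
    spline interpolation needs at least 4 observations. Extrapolation is an
    error.
    """
    new_times = np.asarray(new_times, dtype=float)
    if new_times.size == 0:
        raise ValueError("new_times is empty")
    if new_times.min() < track.times[0] or new_times.max() > track.times[-1]:
        raise ValueError(
            f"new_times outside [{track.times[0]}, {track.times[-1]}]: "
            "extrapolation is not supported"
        )
    if method == "linear":
        if track.n_obs < 2:
            raise ValueError("linear interpolation needs >= 2 observations")
        pos = np.column_stack(
            [np.interp(new_times, track.times, track.positions[:, k])
             for k in range(track.dim)]
        )
    elif method == "spline":
        if track.n_obs < 4:
            raise ValueError("spline interpolation needs >= 4 observations")
        pos = CubicSpline(track.times, track.positions, axis=0)(new_times)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return Track(track.id, new_times, pos)


# --------------------------------------------------------------------------
# gaps

@dataclass
class GapReport:
    """Per-track sampling-grid diagnostics.

    ``flagged`` maps track id -> indices of steps whose duration deviates
    from the per-track median by more than tolerance x median.
    """

    median_dt: dict[str, float] = field(default_factory=dict)
    modal_dt: dict[str, float] = field(default_factory=dict)
    flagged: dict[str, list[int]] = field(default_factory=dict)
    tolerance: float = 0.5

    @property
    def n_flagged(self) -> int:
        return sum(len(v) for v in self.flagged.values())

    def as_table(self) -> pd.DataFrame:
        rows = [
            {"id": tid, "step": s, "median_dt": self.median_dt[tid]}
            for tid, steps in self.flagged.items()
            for s in steps
        ]
        return pd.DataFrame(rows, columns=["id", "step", "median_dt"])


def _modal_dt(durs: np.ndarray) -> float:
    vals, counts = np.unique(np.round(durs, 9), return_counts=True)
    return float(vals[np.argmax(counts)])


def detect_gaps(dataset: TracksDataset, tolerance: float = 0.5) -> GapReport:
    """Flag steps whose duration deviates beyond tolerance x median duration."""
    report = GapReport(tolerance=tolerance)
    for tr in dataset.tracks():
        if tr.n_steps == 0:
            continue
        durs = tr.step_durations()
        med = float(np.median(durs))
        report.median_dt[tr.id] = med
        report.modal_dt[tr.id] = _modal_dt(durs)
        bad = np.flatnonzero(np.abs(durs - med) > tolerance * med)
        if bad.size:
            report.flagged[tr.id] = bad.tolist()
    return report


def repair_gaps(
    dataset: TracksDataset, how: str = "split", tolerance: float = 0.5
) -> tuple[TracksDataset, GapReport]:
    """Detect and repair irregular sampling.

    how="drop" removes tracks containing flagged steps; how="split" cuts
    tracks at flagged steps into new tracks (ids suffixed ``.1``, ``.2``,
    ... in temporal order); how="interpolate" linearly resamples each track
    onto its modal-duration grid. A :class:`GapReport` is always returned.
    """
    report = detect_gaps(dataset, tolerance)
    if how == "drop":
        kept = [tr for tr in dataset.tracks() if tr.id not in report.flagged]
        return dataset.with_tracks(kept), report
    if how == "split":
        out = []
        existing = set(dataset)
        for tr in dataset.tracks():
            cuts = report.flagged.get(tr.id)
            if not cuts:
                out.append(tr)
                continue
            bounds = [0] + [c + 1 for c in cuts] + [tr.n_obs]
            part = 0
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if hi - lo < 1:
                    continue
                part += 1
                new_id = f"{tr.id}.{part}"
                while new_id in existing:
                    new_id += "_"
                existing.add(new_id)
                out.append(Track(new_id, tr.times[lo:hi], tr.positions[lo:hi]))
        return dataset.with_tracks(out), report
    if how == "interpolate":
        out = []
        for tr in dataset.tracks():
            if tr.n_steps == 0:
                out.append(tr)
                continue
            dt = report.modal_dt[tr.id]
            n = int(np.floor((tr.times[-1] - tr.times[0]) / dt + 1e-9)) + 1
            grid = tr.times[0] + dt * np.arange(n)
            out.append(interpolate_track(tr, grid, method="linear"))
        return dataset.with_tracks(out), report
    raise ValueError(f"unknown repair mode {how!r}")


# --------------------------------------------------------------------------
# filtering / drift / normalization

def filter_tracks(
    dataset: TracksDataset,
    measure: MeasureFn | None = None,
    lower: float = -np.inf,
    upper: float = np.inf,
    min_steps: int | None = None,
) -> TracksDataset:
    """Sub-dataset of tracks satisfying a measure range and/or step minimum.

    Tracks whose measure is undefined (NaN) never satisfy a range predicate.
    The original dataset is untouched.
    """
    if lower > upper:
        raise ValueError(f"lower ({lower}) > upper ({upper})")
    kept = []
    for tr in dataset.tracks():
        if min_steps is not None and tr.n_steps < min_steps:
            continue
        if measure is not None:
            v = measure(tr)
            if not (np.isfinite(v) and lower <= v <= upper):
                continue
        kept.append(tr)
    return dataset.with_tracks(kept)


def estimate_drift(dataset: TracksDataset) -> np.ndarray:
    """Global drift velocity: sum of all step vectors / sum of step durations.

    One vector for the whole dataset — per-track drift is indistinguishable
    from genuine directed motion.
    """
    tracks = [tr for tr in dataset.tracks() if tr.n_steps > 0]
    if not tracks:
        raise ValueError("dataset has no steps")
    total_disp = np.sum([tr.displacement_vector() for tr in tracks], axis=0)
    total_time = float(np.sum([duration for tr in tracks
                               for duration in [tr.times[-1] - tr.times[0]]]))
    if total_time == 0:
        raise ValueError("zero total track duration")
    return total_disp / total_time


def correct_drift(dataset: TracksDataset, velocity) -> TracksDataset:
    """Subtract v * (t - t_first_of_track) from every observation."""
    v = np.asarray(velocity, dtype=float)

    def fix(tr: Track) -> Track:
        rel_t = tr.times - tr.times[0]
        return Track(tr.id, tr.times, tr.positions - np.outer(rel_t, v))

    return dataset.map_tracks(fix)


def normalize_tracks(dataset: TracksDataset) -> TracksDataset:
    """Translate each track so its first observation is the origin.

    A per-track rigid translation: all step vectors (and every step-based
    measure) are unchanged. This is the anchoring rose plots require.
    """
    return dataset.map_tracks(
        lambda tr: Track(tr.id, tr.times, tr.positions - tr.positions[0])
    )
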