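"""Angle/distance analyses against reference objects and Hotelling's T^2.

Under unbiased motion the expected angle of a step to any fixed direction
or point is 90 degrees, and to a fixed plane (in 3D) it is
180/pi * (pi/2 - 1) ~ 32.70 degrees; systematic deviations localize
drift, border effects or genuine directional bias. Hotelling's one-sample
T^2 test formalizes this: it tests whether the mean step displacement
vector is zero, which picks up subtle global directionality that per-track
statistics dilute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Track, TracksDataset
from .metrics import angle_degrees

__all__ = [
    "angle_to_dir", "angle_to_point", "angle_to_plane",
    "distance_to_point", "distance_to_plane",
    "ISOTROPIC_PLANE_ANGLE",
    "HotellingResult", "hotellings_test",
    "step_normal_angles",
]

#: Expected angle (degrees) between an isotropic 3D step and a fixed plane.
ISOTROPIC_PLANE_ANGLE = float(np.degrees(np.pi / 2 - 1))


def _step_vector(step: Track | np.ndarray) -> np.ndarray:
    if isinstance(step, Track):
        return step.displacement_vector()
    return np.asarray(step, dtype=float)


def _start_point(step: Track | np.ndarray) -> np.ndarray:
    if isinstance(step, Track):
        return step.positions[0]
    raise TypeError("distances need a Track (the step's starting observation)")


def angle_to_dir(step: Track | np.ndarray, direction) -> float:
    """Angle (degrees, [0, 180]) between a step and a fixed direction.

    Accepts a single-step subtrack (step-based use) or a whole track, in
    which case the overall displacement vector is used (cell-based use).
    NaN for a zero step.
    """
    direction = np.asarray(direction, dtype=float)
    if not np.any(direction):
        raise ValueError("reference direction must be nonzero")
    return angle_degrees(_step_vector(step), direction)


def angle_to_point(step: Track, point) -> float:
    """Angle (degrees) between a step and the direction towards a point.

    The reference direction runs from the step's starting observation to
    ``point``; 90 expected under unbiased motion, < 90 indicates attraction.
    """
    ref = np.asarray(point, dtype=float) - _start_point(step)
    if not np.any(ref):
        return float("nan")
    return angle_degrees(_step_vector(step), ref)


def angle_to_plane(step: Track | np.ndarray, plane_point, normal) -> float:
    """Angle (degrees, [0, 90]) between a step and a plane.

    Computed as |90 - angle(step, normal)|, i.e. the complement of the
    angle to the plane's normal vector.
    """
    normal = np.asarray(normal, dtype=float)
    if not np.any(normal):
        raise ValueError("plane normal must be nonzero")
    theta = angle_degrees(_step_vector(step), normal)
    if np.isnan(theta):
        return theta
    return abs(90.0 - theta)


def distance_to_point(step: Track, point) -> float:
    """Euclidean distance from the step's starting observation to a point."""
    return float(np.linalg.norm(_start_point(step) - np.asarray(point, dtype=float)))


def distance_to_plane(step: Track, plane_point, normal) -> float:
    """Euclidean distance from the step's starting observation to a plane."""
    normal = np.asarray(normal, dtype=float)
    n_hat = normal / np.linalg.norm(normal)
    return float(abs((_start_point(step) - np.asarray(plane_point, dtype=float)) @ n_hat))


# --------------------------------------------------------------------------
# Hotelling's T^2

@dataclass
class HotellingResult:
    """One-sample Hotelling T^2 test of zero mean step displacement.

    ``ellipse_axes`` holds the half-axis vectors of the (1 - alpha)
    confidence region of the mean (rows are axis vectors, micrometers).
    """

    n: int
    p: int
    mean_vector: np.ndarray
    covariance: np.ndarray
    T2: float
    F: float
    df: tuple[int, int]
    p_value: float
    alpha: float
    ellipse_center: np.ndarray
    ellipse_axes: np.ndarray

    def __repr__(self) -> str:
        return (
            f"HotellingResult(T2={self.T2:.4g}, F={self.F:.4g}, "
            f"df={self.df}, p={self.p_value:.4g}, n={self.n})"
        )


def pooled_steps(dataset: TracksDataset, step_spacing: int = 0) -> np.ndarray:
    """Step displacement vectors pooled across tracks.

    ``step_spacing`` = k keeps every (k+1)-th step per track: consecutive
    steps of one cell are autocorrelated, which inflates type-I error of
    tests that assume independent steps.
    """
    if step_spacing < 0:
        raise ValueError("step_spacing must be >= 0")
    chunks = [tr.steps()[:: step_spacing + 1] for tr in dataset.tracks()
              if tr.n_steps > 0]
    if not chunks:
        raise ValueError("dataset has no steps")
    return np.vstack(chunks)


def hotellings_test(
    dataset: TracksDataset,
    step_spacing: int = 0,
    dim_select: tuple[int, ...] | None = None,
    alpha: float = 0.05,
    per_track_means: bool = False,
) -> HotellingResult:
    """Test H0: the mean step displacement vector is zero.

    T^2 = n * xbar' S^-1 xbar with S the sample covariance of the pooled
    step vectors; F = T^2 (n - p) / (p (n - 1)) follows F(p, n - p) under
    H0. ``dim_select`` restricts the test to a subset of axes (e.g. (0, 1)
    to project a 3D dataset on xy); ``per_track_means`` tests per-track
    mean steps instead of pooled steps.
    """
    if per_track_means:
        steps = np.vstack([
            tr.steps()[:: step_spacing + 1].mean(axis=0)
            for tr in dataset.tracks() if tr.n_steps > 0
        ])
    else:
        steps = pooled_steps(dataset, step_spacing)
    if dim_select is not None:
        steps = steps[:, list(dim_select)]
    n, p = steps.shape
    if n <= p:
        raise ValueError(f"need more steps than dimensions: n={n}, p={p}")
    xbar = steps.mean(axis=0)
    S = np.cov(steps, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    # rcond guards against numerically singular covariance
    if np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError(
            "singular step covariance; reduce dimensions (dim_select) or "
            "provide more varied steps"
        )
    T2 = float(n * xbar @ np.linalg.solve(S, xbar))
    F = T2 * (n - p) / (p * (n - 1))
    p_value = float(stats.f.sf(F, p, n - p))

    f_crit = stats.f.ppf(1 - alpha, p, n - p)
    lam, vec = np.linalg.eigh(S)
    scale = np.sqrt(lam * p * (n - 1) / (n * (n - p)) * f_crit)
    axes = vec.T * scale[:, None]
    return HotellingResult(
        n=n, p=p, mean_vector=xbar, covariance=S, T2=T2, F=float(F),
        df=(p, n - p), p_value=p_value, alpha=alpha,
        ellipse_center=xbar, ellipse_axes=axes,
    )


# --------------------------------------------------------------------------
# per-step angle/distance tables

def step_normal_angles(
    dataset: TracksDataset,
    ref_type: str = "direction",
    direction=None,
    point=None,
    plane_point=None,
    normal=None,
) -> pd.DataFrame:
    """Per-step table of (angle to a reference, distance to it), plot-ready.

    One row per step: track id, step index, start time, angle, distance.
    Under unbiased motion the mean angle to a fixed direction or point is
    90 degrees at all distances; deviations localize drift or border
    artifacts. For a plain direction the distance column is NaN (a
    direction has no position).
    """
    rows = []
    for tr in dataset.tracks():
        steps = tr.steps()
        for k in range(tr.n_steps):
            sub = tr.slice(k, k + 1)
            if ref_type == "direction":
                ang = angle_to_dir(steps[k], direction)
                dist = float("nan")
            elif ref_type == "point":
                ang = angle_to_point(sub, point)
                dist = distance_to_point(sub, point)
            elif ref_type == "plane":
                ang = angle_to_plane(steps[k], plane_point, normal)
                dist = distance_to_plane(sub, plane_point, normal)
            else:
                raise ValueError(f"unknown ref_type {ref_type!r}")
            rows.append({
                "id": tr.id, "step": k, "t": tr.times[k],
                "angle": ang, "distance": dist,
            })
    return pd.DataFrame(rows, columns=["id", "step", "t", "angle", "distance"])
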