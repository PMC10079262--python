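"""Independent naive reimplementations of the motility measures.

These deliberately use pure-Python loops and the arccos form of angles
(clipped), so they share no code path with the package implementation.
They exist only as test oracles.
"""

from __future__ import annotations

import math

import numpy as np

from celltracks import Track


def naive_displacement(tr):
    d = [tr.positions[-1][k] - tr.positions[0][k] for k in range(tr.dim)]
    return math.sqrt(sum(v * v for v in d))


def naive_square_displacement(tr):
    return sum(
        (tr.positions[-1][k] - tr.positions[0][k]) ** 2 for k in range(tr.dim)
    )


def naive_max_displacement(tr):
    best = 0.0
    for row in tr.positions:
        d = math.sqrt(sum((row[k] - tr.positions[0][k]) ** 2 for k in range(tr.dim)))
        best = max(best, d)
    return best


def naive_track_length(tr):
    total = 0.0
    for i in range(len(tr.positions) - 1):
        total += math.sqrt(sum(
            (tr.positions[i + 1][k] - tr.positions[i][k]) ** 2
            for k in range(tr.dim)
        ))
    return total


def naive_duration(tr):
    return tr.times[-1] - tr.times[0]


def naive_speed(tr):
    d = naive_duration(tr)
    return naive_track_length(tr) / d if d > 0 else float("nan")


def naive_straightness(tr):
    length = naive_track_length(tr)
    return naive_displacement(tr) / length if length > 0 else float("nan")


def naive_displacement_ratio(tr):
    m = naive_max_displacement(tr)
    return naive_displacement(tr) / m if m > 0 else float("nan")


def naive_outreach_ratio(tr):
    length = naive_track_length(tr)
    return naive_max_displacement(tr) / length if length > 0 else float("nan")


def _naive_angle(u, v):
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    if nu == 0 or nv == 0:
        return float("nan")
    c = sum(a * b for a, b in zip(u, v)) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _naive_steps(tr):
    return [
        [tr.positions[i + 1][k] - tr.positions[i][k] for k in range(tr.dim)]
        for i in range(len(tr.positions) - 1)
    ]


def naive_mean_turning_angle(tr):
    steps = _naive_steps(tr)
    angles = [
        _naive_angle(steps[i], steps[i + 1]) for i in range(len(steps) - 1)
    ]
    angles = [a for a in angles if not math.isnan(a)]
    return sum(angles) / len(angles) if angles else float("nan")


def naive_overall_angle(tr):
    steps = _naive_steps(tr)
    if not steps:
        return float("nan")
    return _naive_angle(steps[0], steps[-1])


def naive_overall_dot(tr):
    steps = _naive_steps(tr)
    if not steps:
        return float("nan")
    return sum(a * b for a, b in zip(steps[0], steps[-1]))


def naive_asphericity(tr):
    n = len(tr.positions)
    d = tr.dim
    mean = [sum(row[k] for row in tr.positions) / n for k in range(d)]
    gyr = [[0.0] * d for _ in range(d)]
    for row in tr.positions:
        for a in range(d):
            for b in range(d):
                gyr[a][b] += (row[a] - mean[a]) * (row[b] - mean[b]) / n
    lam = sorted(np.linalg.eigvalsh(np.array(gyr)).tolist())
    total = sum(lam)
    if total <= 0:
        return float("nan")
    num = 0.0
    for i in range(d):
        for j in range(i + 1, d):
            num += (lam[i] - lam[j]) ** 2
    return num / ((d - 1) * total * total)


NAIVE_MEASURES = {
    "displacement": naive_displacement,
    "square_displacement": naive_square_displacement,
    "max_displacement": naive_max_displacement,
    "track_length": naive_track_length,
    "duration": naive_duration,
    "speed": naive_speed,
    "straightness": naive_straightness,
    "displacement_ratio": naive_displacement_ratio,
    "outreach_ratio": naive_outreach_ratio,
    "mean_turning_angle": naive_mean_turning_angle,
    "overall_angle": naive_overall_angle,
    "overall_dot": naive_overall_dot,
    "asphericity": naive_asphericity,
}


def _t(n):
    return list(range(n))


#: Hand-constructed 3-6-observation tracks covering straight, bent, closed,
#: collinear, coincident and 3D geometries.
TRACK_LIBRARY = [
    Track("pyth345", _t(3), [[0, 0], [3, 0], [3, 4]]),
    Track("straight2d", _t(4), [[0, 0], [1, 0], [2, 0], [3, 0]]),
    Track("lshape", _t(3), [[0, 0], [1, 0], [1, 1]]),
    Track("backforth", _t(3), [[0, 0], [1, 0], [0, 0]]),
    Track("loop", _t(5), [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]),
    Track("bent", _t(3), [[0, 0], [3, 4], [3, 9]]),
    Track("square", _t(4), [[0, 0], [1, 0], [1, 1], [0, 1]]),
    Track("coincident", _t(3), [[2, 2], [2, 2], [2, 2]]),
    Track("zigzag", _t(5), [[0, 0], [1, 1], [2, 0], [3, 1], [4, 0]]),
    Track("spiralish", _t(6), [[0, 0], [2, 0], [2, 2], [-1, 2], [-1, -2], [3, -2]]),
    Track("zerostep", _t(4), [[0, 0], [1, 0], [1, 0], [2, 1]]),
    Track("negcoord", _t(3), [[-1, -1], [-4, -5], [-4, -1]]),
    Track("tiny", _t(3), [[0, 0], [1e-4, 0], [1e-4, 1e-4]]),
    Track("uneven_t", [0.0, 0.5, 2.5], [[0, 0], [1, 1], [0, 3]]),
    Track("straight3d", _t(4), [[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]]),
    Track("pyth3d", _t(3), [[0, 0, 0], [3, 4, 0], [3, 4, 12]]),
    Track("helix", _t(5), [[1, 0, 0], [0, 1, 1], [-1, 0, 2], [0, -1, 3], [1, 0, 4]]),
    Track("tetra", _t(4), [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]),
    Track("loop3d", _t(4), [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0]]),
    Track("drift3d", [0, 2, 3], [[0, 0, 0], [2, -1, 4], [5, 5, 5]]),
    Track("plane3d", _t(4), [[0, 0, 1], [2, 0, 1], [2, 3, 1], [0, 3, 1]]),
    Track("twostep", _t(3), [[0, 0, 0], [0, 0, 2], [0, 2, 2]]),
]


def naive_subtrack_count(n_steps, length, overlap):
    """Exhaustive enumeration of valid subtrack start indices."""
    stride = length - overlap
    count = 0
    start = 0
    while start + length <= n_steps:
        count += 1
        start += stride
    return count
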