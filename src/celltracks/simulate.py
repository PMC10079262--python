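"""Random-walk simulators and MSD model fitting.

Three generative models of cell motion:

* Brownian: independent Gaussian increments, optionally with drift — the
  null model of diffusive motion, MSD(L) = d sigma^2 L.
* Bootstrap: step lengths and turning angles resampled with replacement
  from an empirical dataset — reproduces a dataset's single-step
  statistics with no parametric assumptions.
* Beauchemin: the T-cell random walk alternating straight "free" runs
  (speed v_free, duration t_free) with pauses (t_pause) and uniform
  re-orientation, optionally biased toward a direction. Its long-run
  motility coefficient is M = v_free^2 t_free^2 / (2 d (t_free + t_pause)),
  giving the asymptotic MSD slope v_free^2 t_free^2 / (t_free + t_pause)
  per unit time irrespective of dimension.

Every simulator is bit-reproducible given its seed; replicate sets expand
one root seed into per-track substreams so results do not depend on
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .core import Track, TracksDataset
from .metrics import MSDCurve, mean_turning_angle, turning_angles

__all__ = [
    "BrownianParams", "brownian_track",
    "bootstrap_track",
    "BeaucheminParams", "beauchemin_track", "beauchemin_msd_asymptote",
    "FitResult", "fit_msd",
    "replicate_dataset",
]


def _unit_vectors(rng: np.random.Generator, n: int, dim: int,
                  bias_dir=None, p_bias: float = 0.0) -> np.ndarray:
    """n directions uniform on the circle/sphere, optionally tilted.

    Bias: add p_bias * bias_dir to each uniform unit vector and
    renormalize — exactly uniform at p_bias = 0, monotone in p_bias.
    """
    v = rng.normal(size=(n, dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if p_bias > 0.0:
        b = np.asarray(bias_dir, dtype=float)
        b = b / np.linalg.norm(b)
        v = v + p_bias * b
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


# --------------------------------------------------------------------------
# Brownian

@dataclass(frozen=True)
class BrownianParams:
    """Parameters of a Gaussian random walk.

    step_sd is the per-axis standard deviation of one increment (um);
    drift is the deterministic displacement per step (um).
    """

    n_steps: int
    dim: int = 3
    delta_t: float = 1.0
    step_sd: float = 1.0
    drift: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")


def brownian_track(params: BrownianParams, track_id: str = "brownian") -> Track:
    """One realization: position_k = position_{k-1} + drift + N(0, sd^2 I)."""
    rng = np.random.default_rng(params.seed)
    inc = rng.normal(0.0, params.step_sd, size=(params.n_steps, params.dim))
    if params.drift is not None:
        inc = inc + np.asarray(params.drift, dtype=float)
    pos = np.vstack([np.zeros(params.dim), np.cumsum(inc, axis=0)])
    times = params.delta_t * np.arange(params.n_steps + 1)
    return Track(track_id, times, pos)


# --------------------------------------------------------------------------
# bootstrap

def bootstrap_track(
    n_steps: int,
    reference: TracksDataset,
    seed: int = 0,
    track_id: str = "bootstrap",
) -> Track:
    """Resample a synthetic track from a dataset's empirical distributions.

    Step lengths and turning angles are drawn independently with
    replacement from the reference's pooled step-length and turning-angle
    distributions. Each new step is the previous direction rotated by the
    sampled turning angle (rotation axis uniform on the circle normal to
    the previous direction in 3D) and scaled to the sampled length;
    the time grid uses the reference's modal step duration.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    lengths = np.concatenate([
        np.linalg.norm(tr.steps(), axis=1) for tr in reference.tracks()
        if tr.n_steps > 0
    ])
    if lengths.size < 2:
        raise ValueError("reference needs at least 2 steps")
    if np.all(lengths == 0):
        raise ValueError("degenerate reference: all steps have zero length")
    angles = np.concatenate([
        turning_angles(tr) for tr in reference.tracks() if tr.n_steps >= 2
    ]) if any(tr.n_steps >= 2 for tr in reference.tracks()) else np.empty(0)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise ValueError("reference has no defined turning angle")

    durs = np.concatenate([tr.step_durations() for tr in reference.tracks()
                           if tr.n_steps > 0])
    vals, counts = np.unique(np.round(durs, 9), return_counts=True)
    dt = float(vals[np.argmax(counts)])

    dim = reference.dim
    rng = np.random.default_rng(seed)
    samp_len = rng.choice(lengths, size=n_steps, replace=True)
    samp_ang = np.radians(rng.choice(angles, size=n_steps - 1, replace=True))

    direction = _unit_vectors(rng, 1, dim)[0]
    pos = np.zeros((n_steps + 1, dim))
    pos[1] = samp_len[0] * direction
    for k in range(1, n_steps):
        theta = samp_ang[k - 1]
        if dim == 2:
            sign = rng.choice([-1.0, 1.0])
            c, s = np.cos(theta), np.sin(sign * theta)
            direction = np.array([
                c * direction[0] - s * direction[1],
                s * direction[0] + c * direction[1],
            ])
        else:
            w = rng.normal(size=3)
            w -= (w @ direction) * direction
            nw = np.linalg.norm(w)
            if nw == 0:  # pathological draw; retry deterministic fallback
                w = np.array([direction[1], -direction[0], 0.0])
                nw = np.linalg.norm(w)
            w /= nw
            direction = np.cos(theta) * direction + np.sin(theta) * w
        direction /= np.linalg.norm(direction)
        pos[k + 1] = pos[k] + samp_len[k] * direction
    times = dt * np.arange(n_steps + 1)
    return Track(track_id, times, pos)


# --------------------------------------------------------------------------
# Beauchemin

@dataclass(frozen=True)
class BeaucheminParams:
    """Parameters of the Beauchemin T-cell random walk.

    Defaults follow the published intravital T-cell parameterization
    (v_free = 18.8 um/min, t_free = 2 min, t_pause = 0.5 min); they are
    defaults, not constants.
    """

    total_time: float = 60.0
    delta_t: float = 0.5
    v_free: float = 18.8
    t_free: float = 2.0
    t_pause: float = 0.5
    dim: int = 3
    bias_dir: tuple[float, ...] | None = None
    p_bias: float = 0.0
    seed: int = 0
    stationary: bool = True

    def __post_init__(self):
        if self.v_free <= 0 or self.t_free <= 0:
            raise ValueError("v_free and t_free must be > 0")
        if self.t_pause < 0:
            raise ValueError("t_pause must be >= 0")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.p_bias < 0:
            raise ValueError("p_bias must be >= 0")
        if self.p_bias > 0 and self.bias_dir is None:
            raise ValueError("p_bias > 0 requires bias_dir")


def beauchemin_msd_asymptote(params: BeaucheminParams):
    """(slope, intercept_time) of the long-run MSD line.

    MSD(t) -> slope * (t - t_free / 3) with
    slope = v_free^2 t_free^2 / (t_free + t_pause), valid for
    t >> t_free + t_pause; the slope equals 2 d M with motility
    coefficient M = v^2 t_free^2 / (2 d (t_free + t_pause)).
    """
    slope = params.v_free**2 * params.t_free**2 / (params.t_free + params.t_pause)
    return slope, params.t_free / 3.0


def beauchemin_track(params: BeaucheminParams, track_id: str = "beauchemin") -> Track:
    """One realization of the Beauchemin walk, observed every delta_t.

    The continuous trajectory alternates free runs (straight motion at
    v_free for t_free, direction uniform on the sphere/circle, optionally
    biased) with stationary pauses (t_pause); turning happens at pause
    end. With ``stationary`` (default) the process is started uniformly
    within its free+pause cycle so observed statistics are
    time-stationary; with ``stationary=False`` it starts at the beginning
    of a free run, aligning phases with t = 0. Observations interpolate
    the piecewise-linear continuous path exactly.
    """
    rng = np.random.default_rng(params.seed)
    cycle = params.t_free + params.t_pause
    n_cycles = int(np.ceil((params.total_time + cycle) / cycle)) + 1
    dirs = _unit_vectors(rng, n_cycles, params.dim, params.bias_dir, params.p_bias)

    # breakpoints of the piecewise-linear path
    bp_t = [0.0]
    bp_x = [np.zeros(params.dim)]
    if params.stationary:
        u = rng.uniform(0.0, cycle)
    else:
        u = 0.0
    t = 0.0
    ci = 0
    if u < params.t_free:
        # start mid free run
        free_left = params.t_free - u
        pause_left = params.t_pause
    else:
        free_left = 0.0
        pause_left = cycle - u
    while t < params.total_time:
        if free_left > 0:
            t_next = t + free_left
            bp_t.append(t_next)
            bp_x.append(bp_x[-1] + params.v_free * free_left * dirs[ci])
            t = t_next
        if pause_left > 0:
            t_next = t + pause_left
            bp_t.append(t_next)
            bp_x.append(bp_x[-1].copy())
            t = t_next
        ci += 1
        free_left = params.t_free
        pause_left = params.t_pause

    bp_t = np.asarray(bp_t)
    bp_x = np.asarray(bp_x)
    n_obs = int(np.floor(params.total_time / params.delta_t + 1e-9)) + 1
    obs_t = params.delta_t * np.arange(n_obs)
    pos = np.column_stack([
        np.interp(obs_t, bp_t, bp_x[:, k]) for k in range(params.dim)
    ])
    return Track(track_id, obs_t, pos)


# --------------------------------------------------------------------------
# replicates

def replicate_dataset(simulator, base_params, n_tracks: int, seed: int,
                      id_prefix: str = "sim") -> TracksDataset:
    """n_tracks independent realizations with per-track substreams.

    The root seed expands through numpy's SeedSequence so replicate sets
    are reproducible regardless of execution order.
    """
    children = np.random.SeedSequence(seed).spawn(n_tracks)
    width = len(str(n_tracks - 1)) if n_tracks > 1 else 1
    tracks = []
    for i, child in enumerate(children):
        sub = int(child.generate_state(1)[0] % (2**31))
        params = replace(base_params, seed=sub)
        tracks.append(simulator(params, track_id=f"{id_prefix}{i:0{width}d}"))
    return TracksDataset(tracks)


# --------------------------------------------------------------------------
# MSD fitting

@dataclass
class FitResult:
    """Least-squares fit of a model MSD to an empirical MSD curve."""

    model: str
    params: dict[str, float]
    objective: float
    lags_used: np.ndarray
    predicted: np.ndarray

    def __repr__(self) -> str:
        pstr = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"FitResult({self.model}, {pstr}, objective={self.objective:.4g})"


def _usable(empirical: MSDCurve, max_fit_lag: int | None):
    tab = empirical.table
    ok = (tab["n"] > 0) & np.isfinite(tab["mean"])
    if max_fit_lag is not None:
        ok &= tab["lag_steps"] <= max_fit_lag
    tab = tab[ok]
    if len(tab) < 2:
        raise ValueError("fewer than 2 usable lags within max_fit_lag")
    return (tab["lag_steps"].to_numpy(), tab["lag_time"].to_numpy(),
            tab["mean"].to_numpy())


def _model_msd_beauchemin(params: BeaucheminParams, lag_times: np.ndarray,
                          delta_t: float, n_sim: int, seed: int) -> np.ndarray:
    """Model MSD at the empirical lags by forward simulation (CRN)."""
    horizon = max(10.0 * lag_times.max(),
                  20.0 * (params.t_free + params.t_pause))
    base = replace(params, total_time=horizon, delta_t=delta_t)
    sim = replicate_dataset(beauchemin_track, base, n_sim, seed)
    out = np.empty(lag_times.size)
    for i, lt in enumerate(lag_times):
        L = int(round(lt / delta_t))
        vals = []
        for tr in sim.tracks():
            starts = np.arange(0, tr.n_steps - L + 1)
            disp = tr.positions[starts + L] - tr.positions[starts]
            vals.append((disp**2).sum(axis=1))
        out[i] = float(np.concatenate(vals).mean())
    return out


def fit_msd(
    empirical: MSDCurve,
    model: str,
    max_fit_lag: int | None = None,
    fit_params: tuple[str, ...] = ("v_free",),
    base_params: BeaucheminParams | None = None,
    method: str = "simulate",
    n_sim: int = 50,
    seed: int = 0,
    weights: str = "equal",
) -> FitResult:
    """Fit a motion model's MSD to an empirical MSD curve.

    Long lags are excluded via ``max_fit_lag`` (in steps): a limited
    imaging window biases the empirical MSD at long lags, so only short
    lags are trustworthy. All fitted lags are weighted equally by default;
    ``weights="inverse_variance"`` uses 1/ (var/n) per lag instead, since
    long-lag means pool fewer subtracks.

    Models
    ------
    brownian : MSD linear through the origin, one free parameter
        (slope = 2 d D per unit time; D reported for the curve's source
        dimension cannot be known here, so both slope and D per dim in
        {2, 3} are returned).
    beauchemin : MSD computed by forward simulation with common random
        numbers (method="simulate", default) or by the asymptotic closed
        form (method="closed_form"); free parameters a subset of
        (v_free, t_free, t_pause) around ``base_params``.
    """
    lag_steps, lag_times, y = _usable(empirical, max_fit_lag)
    if weights == "equal":
        w = np.ones_like(y)
    elif weights == "inverse_variance":
        tab = empirical.table.set_index("lag_steps")
        var = tab.loc[lag_steps, "var"].to_numpy()
        n = tab.loc[lag_steps, "n"].to_numpy()
        w = np.where(var > 0, n / var, 1.0)
    else:
        raise ValueError(f"unknown weights {weights!r}")

    if model == "brownian":
        slope = float(np.sum(w * lag_times * y) / np.sum(w * lag_times**2))
        pred = slope * lag_times
        obj = float(np.sum(w * (y - pred) ** 2))
        return FitResult(
            "brownian",
            {"slope": slope, "D_2d": slope / 4.0, "D_3d": slope / 6.0},
            obj, lag_steps, pred,
        )

    if model == "beauchemin":
        base = base_params or BeaucheminParams()
        allowed = {"v_free", "t_free", "t_pause"}
        if not set(fit_params) <= allowed:
            raise ValueError(f"fit_params must be a subset of {sorted(allowed)}")

        if method == "closed_form":
            def predict(p: BeaucheminParams) -> np.ndarray:
                slope, t0 = beauchemin_msd_asymptote(p)
                return np.clip(slope * (lag_times - t0), 0.0, None)
        elif method == "simulate":
            if set(fit_params) == {"v_free"}:
                # positions scale linearly in v_free, so MSD scales as
                # v^2: one CRN simulation at the reference speed plus a
                # closed-form scale fit replaces the iterative search.
                m = _model_msd_beauchemin(base, lag_times, empirical.delta_t,
                                          n_sim, seed)
                c = float(np.sum(w * m * y) / np.sum(w * m**2))
                if c <= 0:
                    raise RuntimeError("MSD scale fit failed (nonpositive scale)")
                v = base.v_free * np.sqrt(c)
                pred = c * m
                obj = float(np.sum(w * (y - pred) ** 2))
                return FitResult("beauchemin", {"v_free": v}, obj, lag_steps, pred)

            def predict(p: BeaucheminParams) -> np.ndarray:
                return _model_msd_beauchemin(p, lag_times, empirical.delta_t,
                                             n_sim, seed)
        else:
            raise ValueError(f"unknown method {method!r}")

        names = list(fit_params)
        x0 = np.array([getattr(base, nm) for nm in names])

        def objective(x):
            if np.any(x <= 0):
                return 1e30
            p = replace(base, **dict(zip(names, x)))
            return float(np.sum(w * (y - predict(p)) ** 2))

        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-8,
                                         "maxiter": 400})
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"Beauchemin MSD fit did not converge: {res.message}")
        fitted = replace(base, **dict(zip(names, res.x)))
        pred = predict(fitted)
        return FitResult(
            "beauchemin", {nm: float(v) for nm, v in zip(names, res.x)},
            float(np.sum(w * (y - pred) ** 2)), lag_steps, pred,
        )

    raise ValueError(f"unknown model {model!r}")
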