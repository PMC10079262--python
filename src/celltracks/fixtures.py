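"""Deterministic synthetic datasets emulating three immune-cell archetypes.

The generator produces labeled multi-class datasets with the qualitative
structure of typical two-photon experiments: a fast, fairly straight
unbiased walker ("tcell_like"), a slower walker with more turning
("bcell_like"), and a directionally biased migrator ("neutrophil_like",
biased toward the (1, -1) direction, as neutrophils converging on a wound
would be). Tracks come from the Beauchemin walk with class-specific
parameters plus Gaussian positional noise emulating localization error.

This emulates real imaging data only at the trajectory level: there is no
z-anisotropy, fluorophore blinking, segmentation error or cell-cell
exclusion, so passing tests establish correctness of the analysis code,
not biological realism of any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import Track, TracksDataset
from .simulate import BeaucheminParams, beauchemin_track

__all__ = ["FixtureSpec", "generate_fixture", "inject_duplicate", "CLASS_PARAMS"]

_SQ2 = float(np.sqrt(2.0))

#: Class-specific walk parameters (um/min, min); effect sizes chosen so the
#: classes are separable at 70 tracks per class without being trivial.
CLASS_PARAMS: dict[str, dict] = {
    "tcell_like": {"v_free": 18.8, "t_free": 2.0, "t_pause": 0.5, "p_bias": 0.0},
    "bcell_like": {"v_free": 6.5, "t_free": 0.8, "t_pause": 0.7, "p_bias": 0.0},
    "neutrophil_like": {
        "v_free": 14.0, "t_free": 2.0, "t_pause": 0.5,
        "p_bias": 1.0, "bias_dir": (1 / _SQ2, -1 / _SQ2),
    },
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic multi-class dataset.

    70 tracks per class of 40 observations at 0.5 min intervals mirror a
    typical time-lapse recording; noise_sd is the per-coordinate Gaussian
    localization error (um). Track starting positions are scattered
    uniformly over a field_size-wide field of view, as cells in an imaging
    volume are.
    """

    n_tracks: int = 70
    n_steps: int = 39
    delta_t: float = 0.5
    noise_sd: float = 0.5
    field_size: float = 400.0
    dim: int = 2
    classes: tuple[str, ...] = ("tcell_like", "bcell_like", "neutrophil_like")
    seed: int = 0

    def metadata(self) -> dict:
        meta = asdict(self)
        meta["class_params"] = {c: dict(CLASS_PARAMS[c]) for c in self.classes}
        return meta


def _class_params(name: str, spec: FixtureSpec, seed: int) -> BeaucheminParams:
    raw = dict(CLASS_PARAMS[name])
    bias = raw.pop("bias_dir", None)
    if bias is not None and spec.dim == 3:
        bias = (*bias, 0.0)
    return BeaucheminParams(
        total_time=spec.n_steps * spec.delta_t,
        delta_t=spec.delta_t,
        dim=spec.dim,
        bias_dir=bias,
        seed=seed,
        **raw,
    )


def generate_fixture(spec: FixtureSpec | None = None) -> tuple[TracksDataset, pd.DataFrame]:
    """Generate the labeled dataset described by ``spec``.

    Returns (dataset, labels) where labels has columns id, label. Fully
    deterministic given spec.seed: each track draws from its own
    substream, and positional noise comes from a separate stream.
    """
    spec = spec or FixtureSpec()
    root = np.random.SeedSequence(spec.seed)
    walk_seeds, noise_seed = root.spawn(2)
    children = walk_seeds.spawn(len(spec.classes) * spec.n_tracks)
    noise_rng = np.random.default_rng(noise_seed)
    width = max(2, len(str(spec.n_tracks - 1)))

    tracks, rows = [], []
    idx = 0
    for cls in spec.classes:
        for i in range(spec.n_tracks):
            sub = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            params = _class_params(cls, spec, sub)
            tr = beauchemin_track(params, track_id=f"{cls}_{i:0{width}d}")
            origin = noise_rng.uniform(0.0, spec.field_size, size=spec.dim)
            noisy = tr.positions + origin + noise_rng.normal(
                0.0, spec.noise_sd, size=tr.positions.shape
            )
            tracks.append(Track(tr.id, tr.times, noisy))
            rows.append({"id": tr.id, "label": cls})
    dataset = TracksDataset(tracks)
    labels = pd.DataFrame(rows).sort_values("id", kind="stable").reset_index(drop=True)
    return dataset, labels


def inject_duplicate(
    dataset: TracksDataset,
    target_id: str,
    noise_sd: float = 0.5,
    seed: int = 0,
    new_id: str | None = None,
) -> tuple[TracksDataset, str]:
    """Simulate a double-tracking error.

    Appends a copy of ``target_id`` with iid Gaussian noise added to each
    coordinate (same timestamps, fresh id). Returns (dataset, new_id) so
    the ground truth is recorded.
    """
    if target_id not in dataset:
        raise KeyError(f"unknown track id {target_id!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    src = dataset[target_id]
    dup_id = new_id or f"{target_id}_dup"
    while dup_id in dataset:
        dup_id += "_"
    noisy = src.positions + rng.normal(0.0, noise_sd, size=src.positions.shape)
    dup = Track(dup_id, src.times, noisy)
    return dataset.with_tracks([*dataset.tracks(), dup]), dup_id
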