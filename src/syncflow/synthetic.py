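"""Synthetic fixtures with recorded ground truth.

Every downstream stage of the pipeline (feature extraction, CRQA, ISC,
dynamic-ISC GLM) can be exercised without any external download: this
module fabricates performer accelerometry whose pairwise synchrony follows
a prescribed schedule, spectator rating streams with a tunable within-group
coupling, BOLD-like multi-subject volumes with a known shared-signal
fraction and feature-coupled voxel blocks, a moving-dot video with matching
amplitude-modulated audio, and block ROI label volumes.  All generators
take explicit seeds and record their parameters in a GroundTruth object;
identical seeds give bit-identical output.

Generative models
-----------------
* Performers: each axis of each performer is a convex mixture
  ``c*shared + (1-c)*private`` of smoothed Gaussian white-noise drivers
  (0.5 s moving average), where the coupling ``c`` follows the schedule
  segment by segment; measurement noise is added on top.  The pairwise
  correlation of two performers' axes is c^2 / (c^2 + (1-c)^2), monotone in
  c, so CRQA-based synchrony provably tracks the schedule.
* Ratings: bounded [0,1] random walks whose increments mix a group-shared
  and an idiosyncratic stream with the same convex-coupling rule.
* BOLD: per voxel, unit-variance noise splits into a group-shared Gaussian
  signal (variance ``shared_fraction``) and independent noise (variance
  ``1 - shared_fraction``), so the expected pairwise correlation equals
  ``shared_fraction`` exactly.  Feature coupling multiplies a group-shared
  stochastic carrier by the scaled, lag-convolved feature: voxels with a
  nonzero beta carry more shared signal when the feature is high, which is
  precisely the effect the dynamic-ISC GLM is built to detect.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError
from .filters import gaussian_lag_filter, minmax_scale
from .kinematics import resample_to_grid
from .types import (
    AccelTrace,
    BoldDataset,
    FeatureSeries,
    GroundTruth,
    SynchronySchedule,
)

_SMOOTH_SECONDS = 0.5  # moving-average width of the performer drivers


def _smoothed_noise(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Gaussian white noise smoothed with a 0.5 s moving average."""
    w = max(int(round(_SMOOTH_SECONDS * rate)), 1)
    raw = rng.standard_normal(n + w - 1)
    kernel = np.ones(w) / w
    return np.convolve(raw, kernel, mode="valid")


def gen_performers(
    n_performers: int,
    duration: float,
    rate: float,
    schedule: SynchronySchedule,
    noise_sd: float,
    seed: int,
    amplitude: float = 30.0,
) -> tuple[list[AccelTrace], GroundTruth]:
    """Generate coupled 3-axis accelerometer traces for a performer group.

    ``amplitude`` sets the raw-unit scale of the axes (wrist accelerometers
    report integer counts of 1/64 g, so movement swings span tens of
    units); with the default, a recurrence radius of 10 raw units is a
    discriminative fraction of the trace spread.  ``noise_sd`` is in the
    same raw units.
    """
    if n_performers < 2:
        raise InvalidArgumentError("need at least 2 performers")
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    n = int(round(duration * rate))
    if n < 2:
        raise InvalidArgumentError("duration * rate must give at least 2 samples")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(n) / rate
    c = schedule.level_at(times)  # per-sample coupling weight
    shared = np.stack([_smoothed_noise(rng, n, rate) for _ in range(3)], axis=1)
    traces = []
    for p in range(n_performers):
        private = np.stack(
            [_smoothed_noise(rng, n, rate) for _ in range(3)], axis=1
        )
        samples = amplitude * (c[:, None] * shared + (1 - c)[:, None] * private)
        if noise_sd > 0:
            samples = samples + noise_sd * rng.standard_normal(samples.shape)
        traces.append(
            AccelTrace(performer_id=f"performer_{p:02d}", rate=rate, samples=samples)
        )
    truth = GroundTruth(
        schedule=schedule,
        seed=seed,
        extra={
            "n_performers": n_performers,
            "duration": duration,
            "rate": rate,
            "noise_sd": noise_sd,
            "amplitude": amplitude,
        },
    )
    return traces, truth


def gen_ratings(
    n_subjects: int,
    duration: float,
    rate: float = 24.0,
    coupling: float = 0.5,
    seed: int = 0,
) -> list[FeatureSeries]:
    """Generate bounded [0,1] continuous rating streams for one group.

    Increments mix a shared and a private random-walk stream with weight
    ``coupling``; the walk starts at 0.5 and is clipped to [0, 1].
    """
    if n_subjects < 1:
        raise InvalidArgumentError("need at least 1 subject")
    if not (0 <= coupling <= 1):
        raise InvalidArgumentError("coupling must lie in [0, 1]")
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    n = int(round(duration * rate))
    if n < 2:
        raise InvalidArgumentError("duration * rate must give at least 2 samples")
    rng = np.random.default_rng(seed)
    step_sd = 0.25 / np.sqrt(n)  # full-length walk SD ~ a quarter of the scale
    shared_steps = rng.standard_normal(n)
    out = []
    for s in range(n_subjects):
        private_steps = rng.standard_normal(n)
        steps = coupling * shared_steps + (1 - coupling) * private_steps
        walk = 0.5 + step_sd * np.cumsum(steps)
        out.append(
            FeatureSeries(
                name=f"rating_{s:02d}", t0=0.0, dt=1.0 / rate,
                values=np.clip(walk, 0.0, 1.0),
            )
        )
    return out


def gen_bold(
    n_subjects: int,
    grid_shape: tuple[int, int, int],
    n_volumes: int,
    tr: float,
    features: Mapping[str, FeatureSeries],
    truth: GroundTruth,
    seed: int,
    sigma: float = 2.8,
    lag: float = 5.0,
) -> list[BoldDataset]:
    """Generate multi-subject BOLD-like series on a common small grid.

    Per voxel v and subject s::

        y[v, t] = sum_f beta[v][f] * g_f(t) * eta_f[v, t]
                  + sqrt(shared_fraction) * shared[v, t]
                  + sqrt(1 - shared_fraction) * noise_s[v, t]

    where g_f is the feature resampled to the volume grid, scaled to [0,1]
    and convolved with a lagged Gaussian (``sigma``/``lag`` seconds), and
    eta_f and shared are group-shared standard-normal fields.  With all
    betas zero, the expected pairwise correlation of any two subjects
    equals ``shared_fraction``.
    """
    if n_subjects < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    if n_volumes < 2:
        raise InvalidArgumentError("n_volumes must be at least 2")
    if tr <= 0:
        raise InvalidArgumentError("tr must be positive")
    grid_shape = tuple(int(g) for g in grid_shape)
    mask = np.ones(grid_shape, dtype=bool)
    n_vox = int(np.prod(grid_shape))
    for v in truth.beta_map:
        if not (0 <= v < n_vox):
            raise InvalidArgumentError(f"beta_map voxel {v} outside the mask")
    rng = np.random.default_rng(seed)
    # Feature drivers on the volume grid, transformed as the GLM will see them.
    drivers: dict[str, np.ndarray] = {}
    for name, series in features.items():
        if series.duration + 1e-9 < n_volumes * tr:
            raise InvalidArgumentError(
                f"feature {name!r} covers {series.duration} s but "
                f"{n_volumes * tr} s are required"
            )
        g = resample_to_grid(series, 0.0, tr, n_volumes).values
        g, _ = minmax_scale(g)
        drivers[name] = gaussian_lag_filter(g, tr, sigma, lag)
    shared = rng.standard_normal((n_vox, n_volumes))
    carriers = {name: rng.standard_normal((n_vox, n_volumes)) for name in drivers}
    sf = truth.shared_fraction
    base = np.zeros((n_vox, n_volumes))
    for v, betas in truth.beta_map.items():
        for name, beta in betas.items():
            if name not in drivers:
                raise InvalidArgumentError(
                    f"beta_map names feature {name!r} not present in features"
                )
            base[v] += beta * drivers[name] * carriers[name][v]
    base += np.sqrt(sf) * shared
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # synthetic 3 mm isotropic grid
    datasets = []
    for s in range(n_subjects):
        noise = rng.standard_normal((n_vox, n_volumes))
        data = base + np.sqrt(1 - sf) * noise
        datasets.append(
            BoldDataset(
                subject_id=f"sub-{s + 1:02d}",
                data=data, mask=mask, tr=tr, affine=affine,
            )
        )
    return datasets


def gen_video_audio(
    n_frames: int,
    frame_shape: tuple[int, int],
    motion_schedule: FeatureSeries,
    seed: int,
    frame_rate: float = 25.0,
    n_dots: int = 16,
    audio_rate: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-dot frames plus amplitude-modulated noise audio.

    ``motion_schedule`` values (clipped to [0, 1]) give each dot's
    per-transition probability of taking a 1-pixel step, so the expected
    inter-frame pixel change is proportional to the schedule; the audio is
    white noise whose instantaneous amplitude follows the same schedule.
    """
    if n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames")
    h, w = (int(v) for v in frame_shape)
    if h < 2 or w < 2:
        raise InvalidArgumentError("frames must be at least 2x2")
    if n_dots < 1 or n_dots > h * w:
        raise InvalidArgumentError("n_dots must be in [1, h*w]")
    rng = np.random.default_rng(seed)
    frame_times = np.arange(n_frames) / frame_rate
    sched = np.clip(
        np.interp(frame_times, motion_schedule.times, motion_schedule.values), 0, 1
    )
    flat = rng.choice(h * w, size=n_dots, replace=False)
    pos = np.stack(np.unravel_index(flat, (h, w)), axis=1)
    steps = np.array([[0, 1], [0, -1], [1, 0], [-1, 0]])
    frames = np.zeros((n_frames, h, w))
    frames[0][pos[:, 0], pos[:, 1]] = 1.0
    for k in range(1, n_frames):
        move = rng.random(n_dots) < sched[k - 1]
        direction = steps[rng.integers(0, 4, size=n_dots)]
        pos = np.where(move[:, None], (pos + direction) % [h, w], pos)
        frames[k][pos[:, 0], pos[:, 1]] = 1.0
    n_audio = int(round(n_frames / frame_rate * audio_rate))
    audio_times = np.arange(n_audio) / audio_rate
    amp = np.clip(
        np.interp(audio_times, motion_schedule.times, motion_schedule.values), 0, 1
    )
    audio = amp * rng.standard_normal(n_audio)
    return frames, audio


def gen_roi_labels(
    grid_shape: tuple[int, int, int], n_rois: int, seed: int = 0
) -> np.ndarray:
    """Partition the grid into ``n_rois`` contiguous equal blocks.

    Labels run 1..n_rois over contiguous C-order slabs of the volume; with
    a full-grid mask there is no 0 background.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    n_vox = int(np.prod(grid_shape))
    if n_rois < 1:
        raise InvalidArgumentError("need at least 1 ROI")
    if n_rois > n_vox:
        raise InvalidArgumentError("more ROIs than voxels")
    flat = 1 + (np.arange(n_vox) * n_rois) // n_vox
    return flat.reshape(grid_shape).astype(int)
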