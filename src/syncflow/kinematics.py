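"""Performance-feature extraction.

Four low-level descriptors of a live group performance feed the downstream
synchrony analyses: per-performer acceleration magnitude from 3-axis wrist
accelerometers, its group average in coarse time windows, frame-differencing
motion energy from the video, and aggregate sound energy from the audio
track.  A generic bin-average resampler moves any of these onto an
arbitrary analysis grid (e.g. the dynamic-ISC window grid).
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError
from .types import AccelTrace, FeatureSeries, require_common_grid


def accel_magnitude(trace: AccelTrace) -> FeatureSeries:
    """Euclidean norm of the three acceleration axes, sample by sample.

    Returns a series named ``"acceleration"`` on the trace's own grid.
    """
    mag = np.sqrt(np.sum(trace.samples**2, axis=1))
    return FeatureSeries(name="acceleration", t0=0.0, dt=trace.dt, values=mag)


def window_average(series: FeatureSeries, width: float) -> FeatureSeries:
    """Average a series in contiguous non-overlapping windows of ``width`` s.

    Window k collects samples whose time falls in
    [t0 + k*width, t0 + (k+1)*width); a trailing partial window is averaged
    over the samples it actually contains.
    """
    if width < series.dt:
        raise InvalidArgumentError(
            f"window width {width} s is below the sample spacing {series.dt} s"
        )
    # Assign by index arithmetic so exact multiples land deterministically.
    rel = (series.times - series.t0) / width
    idx = np.floor(rel + 1e-12).astype(int)
    n_win = idx[-1] + 1
    sums = np.bincount(idx, weights=series.values, minlength=n_win)
    counts = np.bincount(idx, minlength=n_win)
    return FeatureSeries(
        name=series.name, t0=series.t0, dt=width, values=sums / counts
    )


def group_mean(series_set: Sequence[FeatureSeries]) -> FeatureSeries:
    """Element-wise mean of series sharing a common grid."""
    require_common_grid(series_set)
    if len(series_set) < 1:
        raise InvalidArgumentError("need at least one series")
    stacked = np.stack([s.values for s in series_set])
    return FeatureSeries(
        name=f"mean_{series_set[0].name}",
        t0=series_set[0].t0,
        dt=series_set[0].dt,
        values=stacked.mean(axis=0),
    )


def motion_energy(frames: np.ndarray, frame_rate: float) -> FeatureSeries:
    """Inter-frame pixel change of a grayscale frame stack.

    Value k is the summed absolute difference between frames k+1 and k, so
    the output has n_frames - 1 samples at dt = 1/frame_rate.  Adding a
    constant to every frame leaves the result unchanged.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise InvalidArgumentError("need a (n_frames, h, w) stack with >= 2 frames")
    if frame_rate <= 0:
        raise InvalidArgumentError("frame_rate must be positive")
    diffs = np.abs(np.diff(frames, axis=0)).sum(axis=(1, 2))
    return FeatureSeries(
        name="motion_energy", t0=0.0, dt=1.0 / frame_rate, values=diffs
    )


def sound_energy(audio: np.ndarray, audio_rate: float, bin: float) -> FeatureSeries:
    """Per-bin total power (mean squared amplitude) of a mono audio track.

    By Parseval's theorem the mean squared amplitude over a bin equals the
    summed spectral power of that bin, so no per-band decomposition is done.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise InvalidArgumentError("audio must be a non-empty 1-D array")
    if audio_rate <= 0:
        raise InvalidArgumentError("audio_rate must be positive")
    if bin < 1.0 / audio_rate:
        raise InvalidArgumentError("bin must cover at least one sample")
    power = FeatureSeries(
        name="sound_energy", t0=0.0, dt=1.0 / audio_rate, values=audio**2
    )
    out = window_average(power, bin)
    out.name = "sound_energy"
    return out


def resample_to_grid(
    series: FeatureSeries, t0: float, dt: float, n: int
) -> FeatureSeries:
    """Bin-average a series onto the grid (t0, dt, n).

    Output value k is the mean of input samples whose time falls in
    [t0 + k*dt, t0 + (k+1)*dt).  Bins containing no sample are filled by
    linear interpolation between the neighbouring non-empty bins; leading or
    trailing empty bins take the nearest filled bin's value.
    """
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    t = series.times
    rel = (t - t0) / dt
    idx = np.floor(rel + 1e-12).astype(int)
    keep = (idx >= 0) & (idx < n)
    if not np.any(keep):
        raise InvalidArgumentError("series does not overlap the requested grid")
    sums = np.bincount(idx[keep], weights=series.values[keep], minlength=n)
    counts = np.bincount(idx[keep], minlength=n)
    values = np.full(n, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    if not np.all(nz):
        filled = np.flatnonzero(nz)
        values = np.interp(np.arange(n), filled, values[filled])
    return FeatureSeries(name=series.name, t0=t0, dt=dt, values=values)
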