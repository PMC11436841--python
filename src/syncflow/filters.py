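"""Shared 1-D signal helpers: [0,1] scaling and lagged Gaussian convolution.

Used both when building GLM regressors and when injecting feature drivers
into synthetic BOLD, so that the generator and the analysis apply the same
transform to a feature.
"""
from __future__ import annotations

import warnings

import numpy as np


def minmax_scale(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale to [0, 1]; a constant input maps to 0.5 with a warning.

    Returns (scaled, constant_flag).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant series: [0,1] scaling undefined, using 0.5")
        return np.full_like(values, 0.5), True
    return (values - lo) / (hi - lo), False


def gaussian_lag_filter(
    values: np.ndarray, dt: float, sigma: float, lag: float
) -> np.ndarray:
    """Convolve with a Gaussian kernel whose centre is displaced by ``lag``.

    ``sigma`` and ``lag`` are in seconds and are converted to grid units
    (lag rounded to the nearest sample).  A positive lag delays the output
    relative to the input, approximating hemodynamic delay.  Edges are
    handled by reflection.  ``sigma`` of 0 reduces to a pure shift (identity
    when lag is 0 too).
    """
    values = np.asarray(values, dtype=float)
    sigma_u = sigma / dt
    lag_u = int(round(lag / dt))
    half = int(np.ceil(4 * sigma_u)) if sigma_u > 0 else 0
    # Kernel support [lag_u - half, lag_u + half]; out[k] = sum_j w[j] in[k-j].
    offsets = np.arange(lag_u - half, lag_u + half + 1)
    if sigma_u > 0:
        w = np.exp(-0.5 * ((offsets - lag_u) / sigma_u) ** 2)
    else:
        w = np.ones(1)
        offsets = np.array([lag_u])
    w = w / w.sum()
    pad = max(abs(int(offsets[0])), abs(int(offsets[-1])), 1)
    padded = np.pad(values, pad, mode="reflect")
    out = np.zeros_like(values)
    n = values.size
    for off, weight in zip(offsets, w):
        out += weight * padded[pad - off : pad - off + n]
    return out
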