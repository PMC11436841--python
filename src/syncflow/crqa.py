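"""Cross-recurrence quantification of paired time series.

Two series are compared in (optionally delay-embedded) state space: a point
(i, j) of the cross-recurrence plot is recurrent when the Euclidean distance
between the embedded vectors is at most the radius.  The recurrence rate is
the fraction of recurrent points within a diagonal lag band |i-j|*dt <=
lag_window, which restricts "visiting the same state" to near-simultaneous
visits.  The same machinery serves performer movement synchrony (raw-unit
radius) and spectator rating agreement (SD-unit radius via ``normalize``),
both as a single rate per pair and as a windowed, time-resolved series.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidArgumentError, UndefinedStatisticError
from .types import CRQAParams, FeatureSeries, PairwiseRecurrence
from . import kinematics


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay-embed a 1-D series into an (m, dim) trajectory matrix."""
    n = x.size
    m = n - (dim - 1) * delay
    if m < 1:
        raise InvalidArgumentError(
            f"series of length {n} too short for embedding dim {dim}, delay {delay}"
        )
    if dim == 1:
        return x[:, None]
    return sliding_window_view(x, (dim - 1) * delay + 1)[:, ::delay]


def _banded_counts(
    x: np.ndarray, y: np.ndarray, params: CRQAParams, dt: float
) -> tuple[int, int]:
    """(# recurrent, # total) cross-recurrence points in the lag band."""
    if params.normalize:
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise UndefinedStatisticError("cannot normalize a zero-variance series")
        x = (x - x.mean()) / sx
        y = (y - y.mean()) / sy
    X = _embed(x, params.embedding_dim, params.delay)
    Y = _embed(y, params.embedding_dim, params.delay)
    m = X.shape[0]
    max_lag = int(np.floor(params.lag_window / dt + 1e-9))
    r2 = params.radius**2
    recurrent = 0
    total = 0
    for k in range(-min(max_lag, m - 1), min(max_lag, m - 1) + 1):
        if k >= 0:
            d2 = np.sum((X[: m - k] - Y[k:]) ** 2, axis=1)
        else:
            d2 = np.sum((X[-k:] - Y[: m + k]) ** 2, axis=1)
        recurrent += int(np.count_nonzero(d2 <= r2))
        total += d2.size
    return recurrent, total


def _check_pair(x: FeatureSeries, y: FeatureSeries) -> None:
    if x.n != y.n or abs(x.dt - y.dt) > 1e-9:
        raise InvalidArgumentError(
            f"series must share length and dt; got ({x.n}, {x.dt}) vs ({y.n}, {y.dt})"
        )


def cross_recurrence_rate(
    x: FeatureSeries, y: FeatureSeries, params: CRQAParams
) -> float:
    """Lag-banded cross-recurrence rate of two series, in [0, 1]."""
    _check_pair(x, y)
    recurrent, total = _banded_counts(x.values, y.values, params, x.dt)
    return recurrent / total


def pairwise_recurrence(
    series_set: Sequence[FeatureSeries], params: CRQAParams
) -> list[PairwiseRecurrence]:
    """Recurrence rate for every ordered pair (a, b), a != b.

    n series yield n*(n-1) results.  With a symmetric lag band and embedding
    dimension 1 the rate is symmetric in (a, b); both orders are retained so
    that pair counts match the ordered-pair bookkeeping of group studies
    (10 performers -> 90 pairs).
    """
    if len(series_set) < 2:
        raise InvalidArgumentError("need at least 2 series")
    # Rates are symmetric under the symmetric lag band; compute each
    # unordered pair once and emit both orders.
    out: list[PairwiseRecurrence] = []
    cache: dict[tuple[int, int], float] = {}
    for i, a in enumerate(series_set):
        for j, b in enumerate(series_set):
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key not in cache:
                cache[key] = cross_recurrence_rate(series_set[key[0]], series_set[key[1]], params)
            out.append(PairwiseRecurrence(pair_ids=(a.name, b.name), recurrence_rate=cache[key]))
    return out


def windowed_recurrence(
    x: FeatureSeries, y: FeatureSeries, params: CRQAParams, window: float
) -> FeatureSeries:
    """Time-resolved recurrence: one rate per non-overlapping window.

    Windows span ``window`` seconds; a trailing partial window is evaluated
    when it still holds enough samples to embed, otherwise dropped.  The
    output grid has dt = window.
    """
    _check_pair(x, y)
    if window < x.dt:
        raise InvalidArgumentError("window must be at least one sample wide")
    if params.normalize:
        # Normalize once over the whole series so the SD-unit radius means
        # the same thing in every window.
        sx, sy = x.values.std(), y.values.std()
        if sx == 0 or sy == 0:
            raise UndefinedStatisticError("cannot normalize a zero-variance series")
        from dataclasses import replace

        x = FeatureSeries(x.name, x.t0, x.dt, (x.values - x.values.mean()) / sx)
        y = FeatureSeries(y.name, y.t0, y.dt, (y.values - y.values.mean()) / sy)
        params = replace(params, normalize=False)
    per_win = int(round(window / x.dt))
    min_len = (params.embedding_dim - 1) * params.delay + 1
    rates = []
    for start in range(0, x.n, per_win):
        xs = x.values[start : start + per_win]
        ys = y.values[start : start + per_win]
        if xs.size < min_len:
            break
        recurrent, total = _banded_counts(xs, ys, params, x.dt)
        rates.append(recurrent / total)
    return FeatureSeries(
        name=f"rr_{x.name}_{y.name}", t0=x.t0, dt=window, values=np.array(rates)
    )


def group_agreement(
    rating_set: Mapping[str, FeatureSeries],
    group_labels: Mapping[str, str],
    params: CRQAParams,
    window: float,
    bin_dt: float | None = None,
) -> dict[str, np.ndarray]:
    """Within-group distributions of window-averaged pairwise recurrence.

    For each group, every unordered within-group pair's windowed recurrence
    series is averaged over windows, giving one agreement scalar per pair.
    ``bin_dt`` optionally bins the (possibly asynchronous) rating streams to
    a common grid before CRQA.
    """
    groups: dict[str, list[str]] = {}
    for sid, g in group_labels.items():
        groups.setdefault(g, []).append(sid)
    out: dict[str, np.ndarray] = {}
    for g, members in groups.items():
        if len(members) < 2:
            raise InvalidArgumentError(f"group {g!r} has fewer than 2 members")
        series = {}
        for sid in members:
            s = rating_set[sid]
            if bin_dt is not None:
                n_bins = int(np.floor(s.duration / bin_dt + 1e-9))
                s = kinematics.resample_to_grid(s, s.t0, bin_dt, n_bins)
            series[sid] = s
        scalars = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                wr = windowed_recurrence(series[a], series[b], params, window)
                scalars.append(float(wr.values.mean()))
        out[g] = np.array(scalars)
    return out


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch unequal-variance t statistic with Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # Zero difference over zero spread: define t = 0 at the df of
            # equal-variance pooling so identical groups compare as equal.
            na, nb = a.size, b.size
            return 0.0, float(na + nb - 2)
        raise UndefinedStatisticError("both groups have zero variance")
    sa2, sb2 = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
    return float(t), float(df)


def reference_correlation(
    reference: FeatureSeries, group_mean: FeatureSeries
) -> float:
    """Pearson correlation of a reference rater with a group-average series."""
    _check_pair(reference, group_mean)
    x, y = reference.values, group_mean.values
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])
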