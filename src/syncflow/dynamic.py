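"""Sliding-window dynamic ISC and its feature regression.

Inter-subject correlation recomputed in short sliding windows gives a
per-voxel time course of spectator brain synchrony.  A GLM then relates
that time course to performance features (performer acceleration, video
motion, performer synchrony, sound energy) and to the windowed
rating-agreement series of each spectator group.  Regressors are [0,1]
scaled, convolved with a lagged Gaussian (an inexpensive stand-in for
hemodynamic delay) and sequentially orthogonalized; both the dynamic-ISC
series and the design columns are high-pass filtered with the same cosine
basis before ordinary least squares.  Cluster-level inference uses a
permutation null of the maximum supra-threshold cluster extent rather than
Gaussian-random-field theory.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .crqa import windowed_recurrence
from .errors import InvalidArgumentError
from .filters import gaussian_lag_filter, minmax_scale
from .isc import _mean_pairwise_r, _zscore_rows, highpass_rows
from .kinematics import resample_to_grid
from .types import (
    BoldDataset,
    CRQAParams,
    Cluster,
    DesignMatrix,
    DynamicISC,
    FeatureSeries,
    GLMResult,
)

Z_CAP = 38.0  # |z| ceiling: beyond this the normal tail underflows anyway


def sliding_isc(
    datasets: Sequence[BoldDataset], window_len: int, step: int = 1
) -> DynamicISC:
    """Mean pairwise ISC in sliding windows of ``window_len`` volumes.

    Window k covers volumes [k*step, k*step + window_len); the number of
    windows is floor((T - window_len)/step) + 1 and each window's values
    equal ``pairwise_isc`` on that slice of the data.
    """
    if window_len < 3:
        raise InvalidArgumentError("window_len must be at least 3 volumes")
    if step < 1:
        raise InvalidArgumentError("step must be at least 1")
    d0 = datasets[0]
    T = d0.n_volumes
    if window_len > T:
        raise InvalidArgumentError("window_len exceeds the number of volumes")
    stack = np.stack([d.data for d in datasets])
    n_windows = (T - window_len) // step + 1
    values = np.empty((d0.n_voxels, n_windows))
    for k in range(n_windows):
        sl = stack[:, :, k * step : k * step + window_len]
        z, _ = _zscore_rows(sl)
        values[:, k] = _mean_pairwise_r(z)
    centres = (np.arange(n_windows) * step + (window_len - 1) / 2.0) * d0.tr
    return DynamicISC(
        values=values, window_len=window_len, step=step, tr=d0.tr,
        window_times=centres,
    )


def prepare_regressor(
    series: FeatureSeries,
    window_times: np.ndarray,
    sigma: float = 2.8,
    lag: float = 5.0,
) -> np.ndarray:
    """Turn a feature series into a GLM column on the window grid.

    The series is bin-averaged onto the window grid, min-max scaled to
    [0, 1] (a constant series becomes 0.5 with a warning) and convolved
    with a Gaussian kernel of ``sigma`` seconds whose centre is displaced
    by ``lag`` seconds, delaying the regressor relative to the feature.
    """
    window_times = np.asarray(window_times, dtype=float)
    if window_times.size < 2:
        raise InvalidArgumentError("need at least 2 windows")
    dt = float(window_times[1] - window_times[0])
    on_grid = (
        series.n == window_times.size
        and abs(series.dt - dt) < 1e-9
        and abs(series.t0 - window_times[0]) < 1e-9
    )
    if not on_grid:
        # Bin grid aligned so each window time is a bin centre.
        series = resample_to_grid(
            series, window_times[0] - dt / 2.0, dt, window_times.size
        )
    scaled, constant = minmax_scale(series.values)
    if constant:
        return scaled
    return gaussian_lag_filter(scaled, dt, sigma, lag)


def orthogonalize(
    columns: Mapping[str, np.ndarray], order: Sequence[str]
) -> DesignMatrix:
    """Sequential Gram-Schmidt over mean-centred columns in ``order``.

    The first column is kept as-is (mean-centred); each later column has
    its projections onto all earlier orthogonalized columns removed, which
    makes later betas depend on the chosen order.  Rank deficiency raises,
    naming the collinear pair.
    """
    if len(order) == 0:
        raise InvalidArgumentError("need at least one column")
    mats = []
    for name in order:
        col = np.asarray(columns[name], dtype=float)
        col = col - col.mean()
        for earlier_name, earlier in zip(order, mats):
            norm2 = earlier @ earlier
            if norm2 > 0:
                col = col - (earlier @ col) / norm2 * earlier
        if np.linalg.norm(col) <= 1e-10 * max(
            1.0, np.linalg.norm(np.asarray(columns[name], dtype=float))
        ):
            raise InvalidArgumentError(
                f"column {name!r} is collinear with earlier columns "
                f"{list(order[: len(mats)])}"
            )
        mats.append(col)
    return DesignMatrix(
        names=list(order),
        columns=np.column_stack(mats),
        orthogonalization_order=list(order),
    )


def glm_fit(
    dyn: DynamicISC, design: DesignMatrix, highpass: float | None = 100.0
) -> GLMResult:
    """Voxelwise OLS of dynamic ISC on the design, with t -> z conversion.

    An identical high-pass (cosine-basis, ``highpass`` seconds cutoff) is
    applied to the per-voxel ISC series and to every design column before
    fitting; an intercept is always included.  z statistics map the t CDF
    through the normal quantile, capped at |z| = 38.
    """
    if design.n_rows != dyn.n_windows:
        raise InvalidArgumentError(
            f"design has {design.n_rows} rows but dynamic ISC has "
            f"{dyn.n_windows} windows"
        )
    X = design.columns.copy()
    Y = dyn.values.copy()
    if X.shape[0] < X.shape[1] + 2:
        raise InvalidArgumentError("fewer windows than regressors + 2")
    if highpass is not None:
        dt = dyn.window_dt
        X = highpass_rows(X.T, dt, highpass).T
        Y = highpass_rows(Y, dt, highpass)
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta_all, _, rank, _ = np.linalg.lstsq(Xd, Y.T, rcond=None)
    resid = Y.T - Xd @ beta_all
    df = n - p - 1
    if df < 1:
        raise InvalidArgumentError("non-positive residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    se = np.where(se == 0, np.inf, se)
    t_stats = beta_all / se
    z = _t_to_z(t_stats[1:].T, df)
    return GLMResult(names=list(design.names), betas=beta_all[1:].T, z_stats=z)


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to z scores through the tail probability."""
    with np.errstate(over="ignore"):
        tail = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(tail, 1e-300, 1.0))
    z = np.minimum(z, Z_CAP)
    return np.sign(t) * z


def cluster_threshold(
    z_vol: np.ndarray,
    z_thresh: float = 3.1,
    min_extent: int = 0,
    connectivity: int = 26,
    regressor: str = "",
) -> list[Cluster]:
    """Connected components of z > z_thresh (default 26-connectivity)."""
    if z_thresh <= 0:
        raise InvalidArgumentError("z_thresh must be positive")
    z_vol = np.asarray(z_vol, dtype=float)
    if z_vol.size == 0:
        raise InvalidArgumentError("empty z map")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise InvalidArgumentError("connectivity must be 6 or 26")
    labels, n = ndimage.label(z_vol > z_thresh, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if coords.shape[0] < min_extent:
            continue
        zs = z_vol[tuple(coords.T)]
        clusters.append(
            Cluster(
                regressor=regressor,
                voxels=coords,
                peak_z=float(zs.max()),
                extent=int(coords.shape[0]),
            )
        )
    clusters.sort(key=lambda c: c.extent, reverse=True)
    return clusters


def cluster_permutation(
    dyn: DynamicISC,
    design: DesignMatrix,
    mask: np.ndarray,
    z_thresh: float = 3.1,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
    highpass: float | None = 100.0,
) -> GLMResult:
    """GLM fit plus cluster-level inference by permuting design rows.

    The null distribution of the maximum supra-threshold cluster extent is
    built per regressor by refitting the GLM with randomly permuted design
    rows; observed clusters get p = (1 + #{null max >= extent}) /
    (1 + n_perm) and survive at ``alpha``.
    """
    result = glm_fit(dyn, design, highpass=highpass)
    rng = np.random.default_rng(seed)
    n_reg = len(design.names)
    null_max = np.zeros((n_perm, n_reg))
    for b in range(n_perm):
        perm = rng.permutation(design.n_rows)
        shuffled = DesignMatrix(
            names=list(design.names), columns=design.columns[perm]
        )
        null_res = glm_fit(dyn, shuffled, highpass=highpass)
        for j in range(n_reg):
            vol = np.zeros(mask.shape)
            vol[mask] = null_res.z_stats[:, j]
            cl = cluster_threshold(vol, z_thresh, regressor=design.names[j])
            null_max[b, j] = cl[0].extent if cl else 0
    clusters: list[Cluster] = []
    for j, name in enumerate(design.names):
        vol = np.zeros(mask.shape)
        vol[mask] = result.z_stats[:, j]
        for c in cluster_threshold(vol, z_thresh, regressor=name):
            c.p_value = float(
                (1 + np.sum(null_max[:, j] >= c.extent)) / (1 + n_perm)
            )
            if c.p_value <= alpha:
                clusters.append(c)
    result.clusters = clusters
    return result


def roi_summary(
    result: GLMResult, roi_labels: np.ndarray, mask: np.ndarray
) -> pd.DataFrame:
    """Mean beta per ROI per regressor (rows: ROI label, columns: regressor).

    ROI labels live on the analysis grid; label 0 is background.  An ROI
    with no in-mask voxels reports NaN.
    """
    roi_labels = np.asarray(roi_labels)
    if roi_labels.shape != mask.shape:
        raise InvalidArgumentError("ROI label volume must match the analysis grid")
    labels_in_mask = roi_labels[mask]
    rois = sorted(int(v) for v in np.unique(roi_labels) if v != 0)
    table = pd.DataFrame(index=rois, columns=result.names, dtype=float)
    table.index.name = "roi"
    for roi in rois:
        sel = labels_in_mask == roi
        if not np.any(sel):
            continue
        table.loc[roi] = result.betas[sel].mean(axis=0)
    return table


def rating_similarity_regressor(
    rating_set: Mapping[str, FeatureSeries],
    group_labels: Mapping[str, str],
    params: CRQAParams,
    window: float = 3.0,
) -> dict[str, FeatureSeries]:
    """Windowed within-group rating-agreement series, one per group.

    For each group, the windowed recurrence series of every unordered
    within-group pair are averaged window by window, yielding the group's
    rating-similarity time course (the D-D / N-N regressors); feed the
    result through :func:`prepare_regressor` to use it in the GLM.
    """
    groups: dict[str, list[str]] = {}
    for sid, g in group_labels.items():
        groups.setdefault(g, []).append(sid)
    out: dict[str, FeatureSeries] = {}
    for g, members in groups.items():
        if len(members) < 2:
            raise InvalidArgumentError(f"group {g!r} has fewer than 2 members")
        pair_series = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pair_series.append(
                    windowed_recurrence(rating_set[a], rating_set[b], params, window)
                )
        stacked = np.stack([s.values for s in pair_series])
        out[g] = FeatureSeries(
            name=f"similarity_{g}",
            t0=pair_series[0].t0,
            dt=pair_series[0].dt,
            values=stacked.mean(axis=0),
        )
    return out
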