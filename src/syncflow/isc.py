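"""Inter-subject correlation maps and their nonparametric inference.

The summative ISC at a voxel is the arithmetic mean of the Pearson
correlations over all unordered subject pairs (mean of raw r, not of
Fisher-z).  Significance comes from a circular-shift bootstrap: every
subject's series is rotated by an independent random offset, which
destroys between-subject temporal alignment while preserving each
subject's autocorrelation, and the map statistic is recomputed.  Voxelwise
multiplicity is handled by Benjamini-Hochberg FDR.  Reference-subject maps
(each subject against one reference, e.g. the work's choreographer) are
Fisher-z transformed and smoothed, then tested with sign-flip one-sample
and label-exchange two-sample permutation tests using max-statistic
family-wise correction (optionally TFCE).
"""
from __future__ import annotations

import warnings
from itertools import combinations, product
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .types import BoldDataset, ISCMap


# ---------------------------------------------------------------------------
# filtering / smoothing


def temporal_highpass(data: BoldDataset, cutoff: float) -> BoldDataset:
    """Remove drifts slower than ``cutoff`` seconds from every voxel.

    The drift subspace is spanned by an intercept, a linear trend and
    discrete cosines with period above the cutoff; each voxel's series is
    replaced by its residual after projection onto that subspace, so the
    output is mean-zero per voxel.
    """
    if cutoff <= 2 * data.tr:
        raise InvalidArgumentError(
            f"cutoff {cutoff} s must exceed twice the TR ({data.tr} s)"
        )
    basis = _drift_basis(data.n_volumes, data.tr, cutoff)
    q, _ = np.linalg.qr(basis)
    resid = data.data - (data.data @ q) @ q.T
    return BoldDataset(
        subject_id=data.subject_id,
        data=resid, mask=data.mask, tr=data.tr, affine=data.affine,
    )


def _drift_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """Intercept + linear trend + slow cosines (period > cutoff)."""
    t = np.arange(n)
    cols = [np.ones(n), t - t.mean()]
    k = 1
    while 2 * n * tr / k > cutoff:
        cols.append(np.cos(np.pi * k * (t + 0.5) / n))
        k += 1
    return np.column_stack(cols)


def highpass_rows(rows: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Row-wise drift removal for plain (n_series, n_samples) matrices."""
    basis = _drift_basis(rows.shape[1], dt, cutoff)
    q, _ = np.linalg.qr(basis)
    return rows - (rows @ q) @ q.T


def spatial_smooth(
    volume: np.ndarray, fwhm: float, voxel_size: float = 3.0
) -> np.ndarray:
    """Gaussian smoothing of a 3-D volume; ``fwhm`` in mm, 0 is identity."""
    if fwhm < 0:
        raise InvalidArgumentError("fwhm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm == 0:
        return volume.copy()
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    return ndimage.gaussian_filter(volume, sigma, mode="reflect")


# ---------------------------------------------------------------------------
# summative ISC


def _check_common(datasets: Sequence[BoldDataset]) -> None:
    if len(datasets) < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    d0 = datasets[0]
    for d in datasets[1:]:
        if d.mask.shape != d0.mask.shape or not np.array_equal(d.mask, d0.mask):
            raise InvalidArgumentError("subjects must share an identical mask")
        if d.n_volumes != d0.n_volumes:
            raise InvalidArgumentError("subjects must have equal volume counts")


def _zscore_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row z-score (population SD); zero-variance rows become 0, flagged."""
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    flat = sd[..., 0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return (data - mean) / sd, flat


def _mean_pairwise_r(z: np.ndarray) -> np.ndarray:
    """Mean over unordered subject pairs of per-voxel Pearson r.

    ``z`` is (n_subjects, n_voxels, T), already z-scored per voxel (rows of
    zero variance are all-zero and contribute r = 0 to their pairs).
    Uses sum_{i<j} z_i.z_j = ((sum_i z_i)^2 - sum_i z_i^2) / 2.
    """
    n_sub, _, T = z.shape
    total = z.sum(axis=0)
    cross = (np.einsum("vt,vt->v", total, total) - np.einsum("svt,svt->v", z, z)) / 2.0
    n_pairs = n_sub * (n_sub - 1) // 2
    return cross / (T * n_pairs)


def pairwise_isc(datasets: Sequence[BoldDataset]) -> ISCMap:
    """Per-voxel mean Pearson correlation over all unordered subject pairs.

    Zero-variance voxels in any subject yield r = 0 for that subject's
    pairs and are flagged rather than raising.
    """
    _check_common(datasets)
    stack = np.stack([d.data for d in datasets])
    z, flat = _zscore_rows(stack)
    flags = flat.any(axis=0)
    if flags.any():
        warnings.warn(
            f"{int(flags.sum())} zero-variance voxel(s): correlation set to 0"
        )
    values = _mean_pairwise_r(z)
    n_sub = len(datasets)
    return ISCMap(values=values, n_pairs=n_sub * (n_sub - 1) // 2, flags=flags)


def isc_bootstrap(
    datasets: Sequence[BoldDataset], n_resamples: int = 10_000, seed: int = 0
) -> np.ndarray:
    """One-sided circular-shift bootstrap p-values for the mean pairwise ISC.

    Each resample rotates every subject's series by an independent uniform
    offset in [1, T-1] and recomputes the per-voxel statistic;
    p = (1 + #{null >= observed}) / (1 + n_resamples).
    """
    _check_common(datasets)
    if n_resamples < 100:
        raise InvalidArgumentError("need at least 100 resamples")
    T = datasets[0].n_volumes
    if T < 4:
        raise InvalidArgumentError("need at least 4 volumes")
    stack = np.stack([d.data for d in datasets])
    z, _ = _zscore_rows(stack)  # z-scoring is shift-invariant
    observed = _mean_pairwise_r(z)
    rng = np.random.default_rng(seed)
    n_sub = z.shape[0]
    exceed = np.zeros_like(observed)
    for _ in range(n_resamples):
        shifts = rng.integers(1, T, size=n_sub)
        rolled = np.stack([np.roll(z[s], shifts[s], axis=-1) for s in range(n_sub)])
        null = _mean_pairwise_r(rolled)
        exceed += null >= observed
    return (1.0 + exceed) / (1.0 + n_resamples)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject all p <= p_(k*) with
    k* = max{k : p_(k) <= k q / m}.  Returns (reject mask, critical p);
    the critical p is 0.0 when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise InvalidArgumentError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= thresholds)
    if passing.size == 0:
        return np.zeros(p.shape, dtype=bool), 0.0
    crit = float(sorted_p[passing[-1]])
    return p <= crit, crit


# ---------------------------------------------------------------------------
# reference-subject (choreographer) ISC


def reference_isc(
    datasets: Sequence[BoldDataset],
    reference: BoldDataset,
    fisher: bool = True,
    smooth_fwhm: float = 3.0,
    voxel_size: float = 3.0,
) -> list[np.ndarray]:
    """Per-subject correlation maps against one reference subject.

    Each non-reference subject yields a per-voxel Pearson r with the
    reference; with ``fisher`` the map is atanh-transformed (r clamped to
    +/-(1 - 1e-7)) and then Gaussian-smoothed at ``smooth_fwhm`` mm.
    """
    _check_common(list(datasets) + [reference])
    z_ref, flat_ref = _zscore_rows(reference.data)
    T = reference.n_volumes
    maps = []
    for d in datasets:
        if d.subject_id == reference.subject_id:
            continue
        z_d, _ = _zscore_rows(d.data)
        r = np.einsum("vt,vt->v", z_ref, z_d) / T
        if fisher:
            r = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
        if smooth_fwhm > 0:
            vol = np.zeros(d.mask.shape)
            vol[d.mask] = r
            r = spatial_smooth(vol, smooth_fwhm, voxel_size)[d.mask]
        maps.append(r)
    return maps


# ---------------------------------------------------------------------------
# permutation tests


def _tfce(stat_vol: np.ndarray, e: float, h: float, dh_frac: float) -> np.ndarray:
    """Threshold-free cluster enhancement of a (non-negative part of a)
    statistic volume, 26-connectivity."""
    out = np.zeros_like(stat_vol)
    peak = stat_vol.max()
    if peak <= 0:
        return out
    dh = dh_frac * peak
    structure = np.ones((3, 3, 3), dtype=bool)
    heights = np.arange(dh, peak + dh / 2, dh)
    for height in heights:
        labels, n = ndimage.label(stat_vol >= height, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        enhanced = (sizes.astype(float) ** e)[labels] * height**h * dh
        enhanced[labels == 0] = 0
        out += enhanced
    return out


def _enhance(
    t_vec: np.ndarray, correction: str, mask: np.ndarray | None,
    tfce_e: float, tfce_h: float, tfce_dh: float,
) -> np.ndarray:
    if correction == "max-stat":
        return t_vec
    if correction == "tfce":
        if mask is None:
            raise InvalidArgumentError("tfce correction needs the 3-D mask")
        vol = np.zeros(mask.shape)
        vol[mask] = t_vec
        pos = _tfce(np.maximum(vol, 0), tfce_e, tfce_h, tfce_dh)
        neg = _tfce(np.maximum(-vol, 0), tfce_e, tfce_h, tfce_dh)
        return (pos - neg)[mask]
    raise InvalidArgumentError(f"unknown correction {correction!r}")


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / np.sqrt(n))


def one_sample_perm(
    maps: Sequence[np.ndarray],
    n_perm: int = 5000,
    seed: int = 0,
    correction: str = "max-stat",
    mask: np.ndarray | None = None,
    tfce_e: float = 0.5,
    tfce_h: float = 2.0,
    tfce_dh: float = 0.1,
) -> np.ndarray:
    """Sign-flip one-sample permutation test of per-subject maps vs 0.

    Family-wise corrected one-sided p per voxel from the null distribution
    of the maximum (optionally TFCE-enhanced) t statistic.  When ``n_perm``
    reaches 2^n the full sign-flip set is enumerated (with a warning) and p
    is the exact proportion.
    """
    maps = np.stack(maps)
    n = maps.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 maps")

    def enhanced_t(data: np.ndarray) -> np.ndarray:
        return _enhance(_one_sample_t(data), correction, mask, tfce_e, tfce_h, tfce_dh)

    observed = enhanced_t(maps)
    if n_perm >= 2**n:
        warnings.warn(
            f"n_perm={n_perm} >= 2^{n}; running the exhaustive sign-flip set"
        )
        exceed = np.zeros_like(observed)
        count = 0
        for signs in product((1.0, -1.0), repeat=n):
            null_max = enhanced_t(np.array(signs)[:, None] * maps).max()
            exceed += null_max >= observed
            count += 1
        return exceed / count
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        signs = rng.choice((1.0, -1.0), size=n)
        null_max = enhanced_t(signs[:, None] * maps).max()
        exceed += null_max >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    se = np.where(se == 0, np.inf, se)
    return (a.mean(axis=0) - b.mean(axis=0)) / se


def two_sample_perm(
    maps_a: Sequence[np.ndarray],
    maps_b: Sequence[np.ndarray],
    n_perm: int = 5000,
    seed: int = 0,
    correction: str = "max-stat",
    mask: np.ndarray | None = None,
    tfce_e: float = 0.5,
    tfce_h: float = 2.0,
    tfce_dh: float = 0.1,
) -> np.ndarray:
    """Unpaired two-sample permutation test by group-label exchange.

    One-sided (A > B) family-wise corrected p per voxel via the max
    statistic; exhaustive over all label splits when ``n_perm`` reaches
    C(na+nb, na).
    """
    a = np.stack(maps_a)
    b = np.stack(maps_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 maps per group")
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n_total = pooled.shape[0]

    def enhanced_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _enhance(_two_sample_t(x, y), correction, mask, tfce_e, tfce_h, tfce_dh)

    observed = enhanced_t(a, b)
    from math import comb

    n_splits = comb(n_total, na)
    if n_perm >= n_splits:
        warnings.warn(f"n_perm={n_perm} >= C({n_total},{na}); exhaustive enumeration")
        exceed = np.zeros_like(observed)
        for idx in combinations(range(n_total), na):
            sel = np.zeros(n_total, dtype=bool)
            sel[list(idx)] = True
            null_max = enhanced_t(pooled[sel], pooled[~sel]).max()
            exceed += null_max >= observed
        return exceed / n_splits
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        null_max = enhanced_t(pooled[perm[:na]], pooled[perm[na:]]).max()
        exceed += null_max >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def group_isc_difference(
    datasets_a: Sequence[BoldDataset],
    datasets_b: Sequence[BoldDataset],
    n_perm: int = 1000,
    seed: int = 0,
    correction: str = "max-stat",
) -> tuple[np.ndarray, np.ndarray]:
    """Difference of group mean pairwise ISCs with a label-permutation null.

    The statistic is ISC_A - ISC_B per voxel; the null exchanges subjects
    between groups and recomputes both groups' pairwise ISC.  Returns the
    observed difference map and two-sided p-values (max-|stat| corrected
    when ``correction`` is "max-stat", uncorrected voxelwise otherwise).
    """
    _check_common(list(datasets_a) + list(datasets_b))
    na = len(datasets_a)
    stack = np.stack([d.data for d in list(datasets_a) + list(datasets_b)])
    z, _ = _zscore_rows(stack)

    def diff(indices_a: np.ndarray, indices_b: np.ndarray) -> np.ndarray:
        return _mean_pairwise_r(z[indices_a]) - _mean_pairwise_r(z[indices_b])

    n_total = z.shape[0]
    observed = diff(np.arange(na), np.arange(na, n_total))
    rng = np.random.default_rng(seed)
    if correction == "max-stat":
        exceed = np.zeros_like(observed)
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            null = diff(perm[:na], perm[na:])
            exceed += np.abs(null).max() >= np.abs(observed)
    else:
        exceed = np.zeros_like(observed)
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            null = diff(perm[:na], perm[na:])
            exceed += np.abs(null) >= np.abs(observed)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return observed, p
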