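"""Independent brute-force reference implementations used only by tests.

Each oracle is written in the most literal way possible (double loops,
exhaustive enumeration, library one-liners) and must stay independent of
the package's vectorized implementations it is used to check.
"""
from __future__ import annotations

from itertools import combinations, product

import numpy as np


def crqa_rate_bruteforce(
    x: np.ndarray,
    y: np.ndarray,
    radius: float,
    dim: int = 1,
    delay: int = 1,
    max_lag: int = 2,
    normalize: bool = False,
) -> float:
    """Literal double-loop cross-recurrence rate in a +/-max_lag sample band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if normalize:
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
    m = len(x) - (dim - 1) * delay
    recurrent = total = 0
    for i in range(m):
        for j in range(m):
            if abs(i - j) > max_lag:
                continue
            xi = np.array([x[i + a * delay] for a in range(dim)])
            yj = np.array([y[j + a * delay] for a in range(dim)])
            total += 1
            if np.sqrt(np.sum((xi - yj) ** 2)) <= radius:
                recurrent += 1
    return recurrent / total


def mean_pairwise_isc_bruteforce(datas: list[np.ndarray]) -> np.ndarray:
    """Per-voxel mean Pearson r over unordered subject pairs, via corrcoef."""
    n_vox = datas[0].shape[0]
    out = np.zeros(n_vox)
    pairs = list(combinations(range(len(datas)), 2))
    for v in range(n_vox):
        rs = []
        for i, j in pairs:
            rs.append(np.corrcoef(datas[i][v], datas[j][v])[0, 1])
        out[v] = np.mean(rs)
    return out


def sliding_isc_bruteforce(
    datas: list[np.ndarray], window_len: int, step: int
) -> np.ndarray:
    """Slice-and-recompute dynamic ISC."""
    T = datas[0].shape[1]
    n_windows = (T - window_len) // step + 1
    cols = []
    for k in range(n_windows):
        sl = [d[:, k * step : k * step + window_len] for d in datas]
        cols.append(mean_pairwise_isc_bruteforce(sl))
    return np.stack(cols, axis=1)


def fdr_bh_reference(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg via statsmodels (independent implementation)."""
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def one_sample_signflip_exhaustive(maps: np.ndarray) -> np.ndarray:
    """Exact max-statistic sign-flip p-values by full enumeration."""
    n = maps.shape[0]

    def tstat(data):
        return data.mean(axis=0) / (data.std(axis=0, ddof=1) / np.sqrt(n))

    observed = tstat(maps)
    exceed = np.zeros_like(observed)
    count = 0
    for signs in product([1.0, -1.0], repeat=n):
        null = tstat(np.array(signs)[:, None] * maps)
        exceed += np.nanmax(null) >= observed
        count += 1
    return exceed / count


def two_sample_label_exhaustive(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact max-statistic label-exchange p-values by full enumeration."""
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n = pooled.shape[0]

    def tstat(x, y):
        vx = x.var(axis=0, ddof=1)
        vy = y.var(axis=0, ddof=1)
        sp = ((x.shape[0] - 1) * vx + (y.shape[0] - 1) * vy) / (n - 2)
        return (x.mean(axis=0) - y.mean(axis=0)) / np.sqrt(
            sp * (1 / x.shape[0] + 1 / y.shape[0])
        )

    observed = tstat(a, b)
    exceed = np.zeros_like(observed)
    count = 0
    for idx in combinations(range(n), na):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        null = tstat(pooled[sel], pooled[~sel])
        exceed += np.nanmax(null) >= observed
        count += 1
    return exceed / count
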