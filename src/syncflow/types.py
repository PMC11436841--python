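"""Core in-memory containers shared across the pipeline.

All time series live on explicit uniform grids (origin ``t0``, spacing
``dt`` in seconds); volumetric data are stored masked, as voxel-by-volume
matrices plus the boolean mask and affine needed to put values back on the
grid.  Voxel indexing is 0-based and windows are half-open throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class FeatureSeries:
    """A named 1-D time series on a uniform grid.

    Parameters
    ----------
    name : str
        Label of the quantity (e.g. ``"acceleration"``, ``"synchrony"``).
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sample spacing, seconds; must be positive.
    values : np.ndarray
        1-D float array, at least one sample, no missing values.
    """

    name: str
    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise InvalidArgumentError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidArgumentError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("values contain non-finite entries")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times t0 + k*dt."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Span covered by the samples, treating each as a dt-wide bin."""
        return self.n * self.dt


@dataclass
class AccelTrace:
    """One performer's 3-axis wrist-accelerometer recording.

    ``samples`` is an (n, 3) array of x, y, z acceleration values recorded
    at ``rate`` Hz.
    """

    performer_id: str
    rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise InvalidArgumentError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidArgumentError(
                f"samples must be (n, 3); got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise InvalidArgumentError("trace must contain at least one sample")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclass
class BoldDataset:
    """One subject's masked 4-D BOLD series.

    ``data`` is (n_voxels, n_volumes) where n_voxels equals the number of
    True entries in ``mask`` (C-order flattening).
    """

    subject_id: str
    data: np.ndarray
    mask: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tr <= 0:
            raise InvalidArgumentError(f"tr must be positive, got {self.tr}")
        if self.mask.ndim != 3:
            raise InvalidArgumentError("mask must be a 3-D boolean volume")
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be (n_voxels, n_volumes)")
        if self.data.shape[0] != int(self.mask.sum()):
            raise InvalidArgumentError(
                f"data has {self.data.shape[0]} rows but mask selects "
                f"{int(self.mask.sum())} voxels"
            )
        if self.data.shape[1] < 2:
            raise InvalidArgumentError("need at least 2 volumes")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked per-voxel vector back onto the 3-D grid."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol


@dataclass
class ISCMap:
    """Per-voxel mean pairwise inter-subject correlation.

    ``flags`` marks voxels whose correlation was undefined (zero variance in
    at least one subject) and was set to 0.
    """

    values: np.ndarray
    n_pairs: int
    flags: np.ndarray | None = None
    p_values: np.ndarray | None = None
    threshold_mask: np.ndarray | None = None


@dataclass
class CRQAParams:
    """Cross-recurrence settings.

    ``radius`` is in raw series units unless ``normalize`` is set, in which
    case both series are z-scored first and the radius is in SD units.
    ``lag_window`` restricts recurrence counting to |i-j|*dt <= lag_window.
    """

    radius: float
    embedding_dim: int = 1
    delay: int = 1
    lag_window: float = 2.0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise InvalidArgumentError("embedding_dim must be >= 1")
        if self.delay < 1:
            raise InvalidArgumentError("delay must be >= 1")
        if self.radius <= 0:
            raise InvalidArgumentError("radius must be > 0")
        if self.lag_window < 0:
            raise InvalidArgumentError("lag_window must be >= 0")


@dataclass
class PairwiseRecurrence:
    """Recurrence rate for one ordered pair of series.

    ``recurrence_rate`` is a scalar, or a FeatureSeries for windowed runs.
    """

    pair_ids: tuple[str, str]
    recurrence_rate: "float | FeatureSeries"


@dataclass
class SynchronySchedule:
    """Piecewise-constant coupling schedule for the performer generator.

    Segment i covers [breakpoints[i], breakpoints[i+1]) (the final segment
    extends to the end of the generated series) at coupling ``levels[i]``.
    """

    breakpoints: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.breakpoints.size == 0 or self.levels.size == 0:
            raise InvalidArgumentError("schedule must have at least one segment")
        if self.breakpoints.size != self.levels.size:
            raise InvalidArgumentError("one level per breakpoint required")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise InvalidArgumentError("breakpoints must be strictly increasing")
        if np.any((self.levels < 0) | (self.levels > 1)):
            raise InvalidArgumentError("levels must lie in [0, 1]")

    def level_at(self, t: np.ndarray) -> np.ndarray:
        """Coupling level at each time (times before the first breakpoint
        take the first segment's level)."""
        idx = np.searchsorted(self.breakpoints, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, self.levels.size - 1)
        return self.levels[idx]


@dataclass
class GroundTruth:
    """Everything needed to reproduce or score a synthetic run."""

    schedule: SynchronySchedule | None = None
    shared_fraction: float = 0.0
    beta_map: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    rating_coupling: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.shared_fraction < 1):
            raise InvalidArgumentError("shared_fraction must lie in [0, 1)")


@dataclass
class DynamicISC:
    """Voxel-by-window matrix of mean pairwise correlations."""

    values: np.ndarray
    window_len: int
    step: int
    tr: float
    window_times: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def window_dt(self) -> float:
        return self.step * self.tr


@dataclass
class DesignMatrix:
    """Window-by-regressor design, after scaling/convolution/orthogonalization."""

    names: list[str]
    columns: np.ndarray
    scaling: dict = field(default_factory=dict)
    convolution: dict = field(default_factory=dict)
    orthogonalization_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.names):
            raise InvalidArgumentError("column count must equal name count")

    @property
    def n_rows(self) -> int:
        return self.columns.shape[0]


@dataclass
class Cluster:
    """One supra-threshold connected component of a z map."""

    regressor: str
    voxels: np.ndarray  # (k, 3) integer voxel coordinates
    peak_z: float
    extent: int
    p_value: float | None = None


@dataclass
class GLMResult:
    """Per-voxel betas and z statistics of the dynamic-ISC regression."""

    names: list[str]
    betas: np.ndarray  # (n_voxels, n_regressors)
    z_stats: np.ndarray  # (n_voxels, n_regressors)
    clusters: list[Cluster] = field(default_factory=list)
    roi_summaries: "object | None" = None


def require_common_grid(series: Sequence[FeatureSeries], *, atol: float = 1e-9) -> None:
    """Raise unless all series share t0, dt and length."""
    if len(series) == 0:
        raise InvalidArgumentError("need at least one series")
    s0 = series[0]
    for s in series[1:]:
        if abs(s.t0 - s0.t0) > atol or abs(s.dt - s0.dt) > atol or s.n != s0.n:
            raise InvalidArgumentError(
                f"series {s.name!r} grid (t0={s.t0}, dt={s.dt}, n={s.n}) does not "
                f"match {s0.name!r} (t0={s0.t0}, dt={s0.dt}, n={s0.n})"
            )
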