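"""On-disk formats: NIfTI volumes, CSV time series, YAML config, run logs.

CSV series files are comma-separated UTF-8 with a mandatory header whose
first column is ``time_s``; one value column makes a FeatureSeries, three
(x, y, z) make an AccelTrace.  Volumes are NIfTI only, affines passed
through untouched.  Floats are written with 17 significant digits so CSV
round-trips are lossless at double precision.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InvalidArgumentError
from .types import AccelTrace, BoldDataset, FeatureSeries

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# NIfTI


def write_bold(dataset: BoldDataset, path: str | Path) -> None:
    """Write a masked BOLD dataset as a 4-D NIfTI (zeros outside the mask)."""
    vol = np.zeros(dataset.mask.shape + (dataset.n_volumes,))
    vol[dataset.mask] = dataset.data
    img = nib.Nifti1Image(vol, dataset.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (dataset.tr,))
    nib.save(img, str(path))


def write_volume(
    volume: np.ndarray, affine: np.ndarray, path: str | Path
) -> None:
    """Write a 3-D volume (map, mask or label image) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI; returns (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def read_bold(
    path: str | Path,
    mask_path: str | Path,
    tr_override: float | None = None,
) -> BoldDataset:
    """Read a 4-D NIfTI plus mask into a masked BoldDataset.

    The TR comes from the header's 4th zoom; a non-positive header TR is
    replaced by ``tr_override`` (with a warning) when given.  Grid or
    affine mismatches beyond 1e-4 and non-finite values are format errors.
    """
    img = nib.load(str(path))
    data4d = np.asarray(img.dataobj, dtype=float)
    if data4d.ndim != 4 or data4d.shape[3] < 2:
        raise FormatError(f"{path}: expected 4-D NIfTI with >= 2 volumes")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data4d.shape[:3]:
        raise FormatError(
            f"mask shape {mask.shape} does not match data grid {data4d.shape[:3]}"
        )
    if not np.allclose(mask_img.affine, img.affine, atol=1e-4):
        raise FormatError("mask affine differs from data affine beyond 1e-4")
    bad = np.argwhere(~np.isfinite(data4d))
    if bad.size:
        raise FormatError(
            f"{path}: non-finite values at indices {bad[:5].tolist()}"
            + ("..." if bad.shape[0] > 5 else "")
        )
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        if tr_override is None:
            raise FormatError(f"{path}: header TR is {tr} and no override given")
        import warnings

        warnings.warn(f"header TR {tr} invalid; using override {tr_override}")
        tr = float(tr_override)
    elif tr_override is not None and abs(tr_override - tr) > 1e-9:
        tr = float(tr_override)
    return BoldDataset(
        subject_id=Path(path).name.split(".")[0],
        data=data4d[mask],
        mask=mask,
        tr=tr,
        affine=img.affine,
    )


# ---------------------------------------------------------------------------
# CSV series


def write_series_csv(series: FeatureSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": series.times, "value": series.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    t = np.arange(trace.n) * trace.dt
    df = pd.DataFrame(
        {"time_s": t, "x": trace.samples[:, 0], "y": trace.samples[:, 1],
         "z": trace.samples[:, 2]}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series_csv(path: str | Path) -> FeatureSeries | AccelTrace:
    """Read a series CSV; 1 value column -> FeatureSeries, 3 -> AccelTrace.

    The time_s column must be strictly increasing on a uniform grid
    (relative spacing tolerance 1e-6).
    """
    try:
        # the default parser is fast but not correctly rounded; round_trip
        # makes read(write(x)) == x exactly at %.17g
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # ragged rows etc.
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing mandatory 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    dts = np.diff(t)
    if np.any(dts <= 0):
        row = int(np.argmax(dts <= 0)) + 1
        raise FormatError(f"{path}: time_s not strictly increasing at row {row}")
    dt = float(np.median(dts))
    off = np.abs(dts - dt) > 1e-6 * max(dt, 1.0)
    if np.any(off):
        row = int(np.argmax(off)) + 1
        raise FormatError(f"{path}: irregular time spacing, first at row {row}")
    value_cols = [c for c in df.columns if c != "time_s"]
    if df[value_cols].isna().any().any():
        raise FormatError(f"{path}: missing values in data columns")
    if len(value_cols) == 1:
        return FeatureSeries(
            name=Path(path).stem, t0=float(t[0]), dt=dt,
            values=df[value_cols[0]].to_numpy(dtype=float),
        )
    if len(value_cols) == 3:
        return AccelTrace(
            performer_id=Path(path).stem,
            rate=1.0 / dt,
            samples=df[value_cols].to_numpy(dtype=float),
        )
    raise FormatError(
        f"{path}: expected 1 (FeatureSeries) or 3 (AccelTrace) value columns, "
        f"got {len(value_cols)}"
    )


# ---------------------------------------------------------------------------
# config and run log


def load_config(path: str | Path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Check referenced input paths exist and seeds are integers."""
    for key in ("inputs",):
        for p in (cfg.get(key) or {}).values():
            if not Path(p).exists():
                raise InvalidArgumentError(f"configured input path missing: {p}")
    seed = cfg.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise InvalidArgumentError(f"seed must be an integer, got {seed!r}")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunLog:
    """Timestamped stage records with enough detail to replay the run."""

    version: str = ""
    config: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)

    def record(self, stage: str, params: dict) -> None:
        self.stages.append(
            {"stage": stage, "params": params, "completed_at": time.time()}
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "input_checksums": self.input_checksums,
                },
                fh,
                indent=2,
                default=_json_default,
            )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
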