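"""End-to-end orchestration of the three-hypothesis workflow.

``run_pipeline`` chains the stages — optional simulation, feature
extraction, rating CRQA, summative ISC, dynamic-ISC GLM — writing each
stage's outputs and a replayable run log.  With the same configuration and
seeds a rerun is bit-identical for every deterministic stage.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, crqa, dynamic, isc, kinematics, synthetic
from .errors import SyncflowError
from .io import (
    RunLog,
    validate_config,
    write_accel_csv,
    write_bold,
    write_series_csv,
    write_volume,
)
from .types import CRQAParams, FeatureSeries, GroundTruth, SynchronySchedule


class StageFailure(SyncflowError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _defaults() -> dict:
    return {
        "seed": 0,
        "simulate": {
            "n_performers": 10,
            "duration": 180.0,
            "rate": 20.0,
            "schedule": {"breakpoints": [0.0, 60.0, 120.0], "levels": [0.2, 0.9, 0.5]},
            "noise_sd": 0.1,
            "n_subjects_per_group": 4,
            "rating_coupling": {"dancers": 0.8, "novices": 0.2},
            "rating_rate": 24.0,
            "grid_shape": [6, 6, 6],
            "n_volumes": 60,
            "tr": 3.0,
            "shared_fraction": 0.3,
        },
        "features": {"accel_window": 2.0},
        "crqa": {
            "radius": 10.0,
            "lag_window": 2.0,
            "window": 3.0,
            "rating_radius_sd": 0.5,
            "rating_bin": 1.0,
        },
        "isc": {"n_resamples": 500, "q": 0.05},
        "dynisc": {
            "window_volumes": 10,
            "step": 1,
            "z_thresh": 3.1,
            "sigma": 2.8,
            "lag": 5.0,
            "n_rois": 3,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict, out_dir: str | Path) -> RunLog:
    """Execute simulate -> features -> crqa -> isc -> dynisc.

    Every stage writes its outputs under ``out_dir`` before the next stage
    starts, so a failure preserves prior results; the raised StageFailure
    names the failing stage.
    """
    cfg = _merge(_defaults(), config or {})
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(version=__version__, config=cfg)
    state: dict = {}
    for stage, fn in [
        ("simulate", _stage_simulate),
        ("features", _stage_features),
        ("crqa", _stage_crqa),
        ("isc", _stage_isc),
        ("dynisc", _stage_dynisc),
    ]:
        try:
            params = fn(cfg, out, state)
        except Exception as exc:
            log.record(stage, {"error": str(exc)})
            log.write(out / "run_log.json")
            raise StageFailure(stage, exc) from exc
        log.record(stage, params)
    log.write(out / "run_log.json")
    return log


def _stage_simulate(cfg: dict, out: Path, state: dict) -> dict:
    sc = cfg["simulate"]
    seed = int(cfg["seed"])
    schedule = SynchronySchedule(
        breakpoints=np.asarray(sc["schedule"]["breakpoints"]),
        levels=np.asarray(sc["schedule"]["levels"]),
    )
    traces, truth = synthetic.gen_performers(
        sc["n_performers"], sc["duration"], sc["rate"], schedule,
        sc["noise_sd"], seed,
    )
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    for tr_ in traces:
        write_accel_csv(tr_, sim_dir / f"{tr_.performer_id}.csv")
    ratings: dict[str, FeatureSeries] = {}
    groups: dict[str, str] = {}
    for gi, (group, coupling) in enumerate(sorted(sc["rating_coupling"].items())):
        series = synthetic.gen_ratings(
            sc["n_subjects_per_group"], sc["duration"], sc["rating_rate"],
            coupling, seed + 1000 + gi,
        )
        for s in series:
            sid = f"{group}_{s.name}"
            s.name = sid
            ratings[sid] = s
            groups[sid] = group
            write_series_csv(s, sim_dir / f"{sid}.csv")
    state.update(traces=traces, truth=truth, ratings=ratings, groups=groups)
    return {"seed": seed, **{k: v for k, v in sc.items()}}


def _stage_features(cfg: dict, out: Path, state: dict) -> dict:
    fc = cfg["features"]
    cc = cfg["crqa"]
    sc = cfg["simulate"]
    traces = state["traces"]
    mags = [kinematics.accel_magnitude(t) for t in traces]
    for m, t in zip(mags, traces):
        m.name = t.performer_id
    windowed = [kinematics.window_average(m, fc["accel_window"]) for m in mags]
    acceleration = kinematics.group_mean(windowed)
    acceleration.name = "acceleration"
    params = CRQAParams(
        radius=cc["radius"], lag_window=cc["lag_window"], normalize=False
    )
    pair_rrs = []
    members = list(range(len(mags)))
    for i in members:
        for j in members[i + 1 :]:
            pair_rrs.append(
                crqa.windowed_recurrence(mags[i], mags[j], params, cc["window"])
            )
    synchrony = FeatureSeries(
        name="synchrony", t0=pair_rrs[0].t0, dt=pair_rrs[0].dt,
        values=np.stack([p.values for p in pair_rrs]).mean(axis=0),
    )
    # Video/audio stand-ins driven by the group acceleration level.
    motion_schedule = FeatureSeries(
        name="motion_schedule", t0=acceleration.t0, dt=acceleration.dt,
        values=np.clip(
            acceleration.values / max(acceleration.values.max(), 1e-12), 0, 1
        ),
    )
    frame_rate = 10.0
    # One extra frame: frame differencing drops a sample, and the motion
    # series must still cover the full scanned duration.
    n_frames = int(sc["duration"] * frame_rate) + 1
    frames, audio = synthetic.gen_video_audio(
        n_frames, (32, 32), motion_schedule, int(cfg["seed"]) + 7,
        frame_rate=frame_rate,
    )
    motion = kinematics.motion_energy(frames, frame_rate)
    motion.name = "motion"
    sound = kinematics.sound_energy(audio, 1000.0, 1.0)
    sound.name = "sound"
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for s in (acceleration, synchrony, motion, sound):
        write_series_csv(s, feat_dir / f"{s.name}.csv")
    state["features"] = {
        "acceleration": acceleration,
        "motion": motion,
        "synchrony": synchrony,
        "sound": sound,
    }
    return {"accel_window": fc["accel_window"], "crqa_window": cc["window"]}


def _stage_crqa(cfg: dict, out: Path, state: dict) -> dict:
    cc = cfg["crqa"]
    params = CRQAParams(
        radius=cc["rating_radius_sd"], lag_window=cc["lag_window"], normalize=True
    )
    agreement = crqa.group_agreement(
        state["ratings"], state["groups"], params, cc["window"],
        bin_dt=cc["rating_bin"],
    )
    rows = [
        {"group": g, "pair_index": i, "mean_recurrence": v}
        for g, vals in agreement.items()
        for i, v in enumerate(vals)
    ]
    crqa_dir = out / "crqa"
    crqa_dir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(crqa_dir / "group_agreement.csv", index=False)
    result: dict = {}
    names = sorted(agreement)
    if len(names) == 2:
        t, df = crqa.welch_t(agreement[names[0]], agreement[names[1]])
        result = {"welch_t": t, "welch_df": df, "groups": names}
        pd.DataFrame([result]).to_csv(crqa_dir / "group_welch.csv", index=False)
    state["agreement"] = agreement
    return {"params": vars(params), **result}


def _make_bold(cfg: dict, state: dict, seed: int):
    sc = cfg["simulate"]
    dc = cfg["dynisc"]
    truth = GroundTruth(
        shared_fraction=sc["shared_fraction"], seed=seed,
        beta_map=sc.get("beta_map", {}),
    )
    return synthetic.gen_bold(
        sc["n_subjects_per_group"], tuple(sc["grid_shape"]), sc["n_volumes"],
        sc["tr"], state["features"], truth, seed,
        sigma=dc["sigma"], lag=dc["lag"],
    )


def _stage_isc(cfg: dict, out: Path, state: dict) -> dict:
    ic = cfg["isc"]
    seed = int(cfg["seed"])
    datasets = _make_bold(cfg, state, seed + 2000)
    isc_dir = out / "isc"
    isc_dir.mkdir(exist_ok=True)
    for d in datasets:
        write_bold(d, isc_dir / f"{d.subject_id}_bold.nii.gz")
    imap = isc.pairwise_isc(datasets)
    p = isc.isc_bootstrap(datasets, ic["n_resamples"], seed + 3000)
    reject, crit = isc.fdr_bh(p, ic["q"])
    affine = datasets[0].affine
    write_volume(datasets[0].to_volume(imap.values), affine, isc_dir / "isc_map.nii.gz")
    write_volume(datasets[0].to_volume(p, fill=1.0), affine, isc_dir / "isc_p.nii.gz")
    write_volume(
        datasets[0].to_volume(reject.astype(float)), affine,
        isc_dir / "isc_reject.nii.gz",
    )
    state["bold"] = datasets
    return {
        "n_resamples": ic["n_resamples"], "q": ic["q"],
        "critical_p": crit, "n_significant": int(reject.sum()),
        "mean_isc": float(imap.values.mean()),
    }


def _stage_dynisc(cfg: dict, out: Path, state: dict) -> dict:
    dc = cfg["dynisc"]
    datasets = state["bold"]
    dyn = dynamic.sliding_isc(datasets, dc["window_volumes"], dc["step"])
    cols = {
        name: dynamic.prepare_regressor(
            series, dyn.window_times, sigma=dc["sigma"], lag=dc["lag"]
        )
        for name, series in state["features"].items()
    }
    order = dc.get("order", ["acceleration", "motion", "synchrony", "sound"])
    design = dynamic.orthogonalize(cols, order)
    mask = datasets[0].mask
    result = dynamic.cluster_permutation(
        dyn, design, mask, z_thresh=dc["z_thresh"],
        n_perm=dc.get("cluster_perms", 100), seed=int(cfg["seed"]) + 4000,
    )
    roi_labels = synthetic.gen_roi_labels(mask.shape, dc["n_rois"])
    table = dynamic.roi_summary(result, roi_labels, mask)
    dyn_dir = out / "dynisc"
    dyn_dir.mkdir(exist_ok=True)
    affine = datasets[0].affine
    for j, name in enumerate(result.names):
        write_volume(
            datasets[0].to_volume(result.z_stats[:, j]), affine,
            dyn_dir / f"z_{name}.nii.gz",
        )
        write_volume(
            datasets[0].to_volume(result.betas[:, j]), affine,
            dyn_dir / f"beta_{name}.nii.gz",
        )
    table.to_csv(dyn_dir / "roi_summary.csv")
    cluster_rows = [
        {
            "regressor": c.regressor, "peak_z": c.peak_z, "extent": c.extent,
            "p_value": c.p_value,
            "x": int(c.voxels[0][0]), "y": int(c.voxels[0][1]),
            "z": int(c.voxels[0][2]),
        }
        for c in result.clusters
    ]
    pd.DataFrame(
        cluster_rows, columns=["regressor", "peak_z", "extent", "p_value", "x", "y", "z"]
    ).to_csv(dyn_dir / "clusters.csv", index=False)
    return {
        "n_windows": dyn.n_windows, "order": order,
        "n_clusters": len(result.clusters),
    }
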