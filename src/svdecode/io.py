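"""Readers/writers and run manifests.

Tabular artifacts are TSV, parameters and summaries are JSON, beta-series
and null matrices live in ``.npz`` array containers, and volumetric data
can be exported as NIfTI (trials along the 4th axis, plus an integer ROI
label volume).  Each pipeline stage writes a manifest recording the
config hash, seeds, and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROI, ROIAtlas
from .choice import ChoiceDataset, FitResult, PreferenceParams
from .decoding import BetaSeries
from .task import Context, Trial, TrialSchedule

__all__ = [
    "write_schedule", "read_schedule", "write_events",
    "write_choices", "read_choices",
    "write_fit_results", "read_fit_results",
    "write_beta_series", "read_beta_series",
    "write_atlas", "read_atlas",
    "beta_series_to_nifti",
    "write_manifest",
]


def write_schedule(schedule: TrialSchedule, path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_schedule(path) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t")
    trials = [
        Trial(run_id=int(r.run_id), position=int(r.position),
              context=Context(r.context), win_prob=float(r.win_prob),
              ambiguity=float(r.ambiguity),
              lottery_value=float(r.lottery_value),
              safe_value=float(r.safe_value), is_catch=bool(r.is_catch),
              onset_s=float(r.onset_s),
              decision_duration_s=float(r.decision_duration_s))
        for r in df.itertuples()
    ]
    return TrialSchedule(trials=trials, n_runs=int(df["run_id"].max()))


def write_events(schedule: TrialSchedule, path) -> None:
    schedule.events_frame().to_csv(path, sep="\t", index=False)


def write_choices(data: ChoiceDataset, path) -> None:
    df = data.schedule.to_frame()[
        ["run_id", "context", "win_prob", "ambiguity", "lottery_value"]]
    df.insert(0, "trial_id", np.arange(len(df)))
    df["response"] = data.responses
    df["participant_id"] = data.participant_id
    df.to_csv(path, sep="\t", index=False)


def read_choices(path, schedule: TrialSchedule) -> ChoiceDataset:
    df = pd.read_csv(path, sep="\t")
    pid = str(df["participant_id"].iloc[0]) if "participant_id" in df else "sub-00"
    return ChoiceDataset(schedule=schedule,
                         responses=df["response"].to_numpy(),
                         participant_id=pid)


def write_fit_results(results: dict[str, FitResult], path) -> None:
    payload = {pid: fr.to_dict() for pid, fr in results.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_results(path) -> dict[str, PreferenceParams]:
    payload = json.loads(Path(path).read_text())
    return {pid: PreferenceParams(d["alpha"], d["beta"], d["gamma"])
            for pid, d in payload.items()}


def write_beta_series(beta: dict[int, BetaSeries], path) -> None:
    """All ROIs of one participant in a single ``.npz`` container."""
    arrays = {}
    for roi_id, bs in beta.items():
        arrays[f"roi{roi_id}_matrix"] = bs.matrix
        arrays[f"roi{roi_id}_run_ids"] = bs.run_ids
        arrays[f"roi{roi_id}_trial_ids"] = bs.trial_ids
    pid = next(iter(beta.values())).participant_id if beta else "sub-00"
    np.savez_compressed(path, participant_id=np.array(pid), **arrays)


def read_beta_series(path) -> dict[int, BetaSeries]:
    with np.load(path, allow_pickle=False) as z:
        pid = str(z["participant_id"])
        roi_ids = sorted({int(k[3:].split("_")[0])
                          for k in z.files if k.startswith("roi")})
        return {
            r: BetaSeries(roi_id=r, matrix=z[f"roi{r}_matrix"],
                          run_ids=z[f"roi{r}_run_ids"],
                          trial_ids=z[f"roi{r}_trial_ids"],
                          participant_id=pid)
            for r in roi_ids
        }


def write_atlas(atlas: ROIAtlas, path) -> None:
    rows = []
    for roi in atlas:
        rows.append({"roi_id": roi.roi_id, "name": roi.name,
                     "network": roi.network,
                     "voxel_ids": ",".join(map(str, roi.voxel_ids))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_atlas(path) -> ROIAtlas:
    df = pd.read_csv(path, sep="\t")
    rois = {}
    for _, r in df.iterrows():
        vox = np.array([int(v) for v in str(r["voxel_ids"]).split(",")])
        rois[int(r["roi_id"])] = ROI(int(r["roi_id"]), str(r["name"]),
                                     str(r["network"]), vox)
    return ROIAtlas(rois)


def beta_series_to_nifti(beta: dict[int, BetaSeries], atlas: ROIAtlas,
                         path, label_path=None):
    """Export patterns as a 4-D NIfTI (voxels laid out along x, trials on
    the 4th axis) with an integer ROI label volume alongside."""
    import nibabel as nib

    n_vox = atlas.n_voxels
    n_trials = next(iter(beta.values())).n_trials
    vol = np.zeros((n_vox, 1, 1, n_trials))
    labels = np.zeros((n_vox, 1, 1), dtype=np.int16)
    for roi in atlas:
        if roi.roi_id in beta:
            vol[roi.voxel_ids, 0, 0, :] = beta[roi.roi_id].matrix.T
        labels[roi.voxel_ids, 0, 0] = roi.roi_id + 1
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.to_filename(str(path))
    if label_path is not None:
        nib.Nifti1Image(labels, affine).to_filename(str(label_path))
    return img


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, stage: str, config: dict, seeds: dict,
                   outputs: list, warnings_list: list[str] | None = None) -> Path:
    """Atomically write a per-stage manifest JSON."""
    out_dir = Path(out_dir)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = {
        "stage": stage,
        "config_hash": cfg_hash,
        "seeds": seeds,
        "outputs": {str(Path(p).name): _checksum(Path(p)) for p in outputs},
        "warnings": warnings_list or [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"manifest_{stage}.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(path)
    return path
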