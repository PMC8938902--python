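"""File formats: NIfTI volumes, BIDS-style events TSV, JSON/CSV tables.

Simulated runs are written as 4-D NIfTI with the sheet's voxels laid out on
a 1 x 1 x P grid plus an events TSV (onset, duration, trial_type) per run;
the axis coordinate of every voxel lives in a sidecar table. RDMs go to
long-format CSV and square-matrix JSON. All CSV floats use a fixed format so
re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .rsa import RDM, PatternSet
from .sheet import CorticalSheet, NoiseConfig, SomatotopyConfig
from .simulate import Cohort, HemisphereData, RunData, Subject
from .tasks import SessionRecipe, make_task

FLOAT_FMT = "%.10g"


def save_run(run: RunData, nifti_path: Path, events_path: Path) -> None:
    """Write a run as 4-D NIfTI (1 x 1 x P x T) plus an events TSV."""
    data = np.asarray(run.timeseries.T, dtype=np.float32)[np.newaxis, np.newaxis]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr_s))
    nib.save(img, str(nifti_path))
    pd.DataFrame(
        {
            "onset": run.onsets_s,
            "duration": run.durations_s,
            "trial_type": run.sequence,
        }
    ).to_csv(events_path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_run(nifti_path: Path, events_path: Path, run_index: int = 0) -> RunData:
    """Read a 4-D NIfTI run and its events TSV back into a RunData."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4-D image")
    ts = data.reshape(-1, data.shape[-1]).T.astype(float)  # volumes x voxels
    tr = float(img.header.get_zooms()[3])
    ev = pd.read_csv(events_path, sep="\t")
    return RunData(
        timeseries=ts,
        sequence=tuple(ev["trial_type"].astype(str)),
        onsets_s=tuple(float(x) for x in ev["onset"]),
        durations_s=tuple(float(x) for x in ev["duration"]),
        tr_s=tr,
        run_index=run_index,
    )


def _sheet_frame(sheet: CorticalSheet) -> pd.DataFrame:
    df = pd.DataFrame({"coord_mm": sheet.coords_mm, "voxel_sd": sheet.voxel_sd})
    for i, c in enumerate(sheet.conditions):
        df[f"mean:{c}"] = sheet.mean_maps[i]
        df[f"distributed:{c}"] = sheet.distributed_maps[i]
    for p, mask in sheet.zone_masks.items():
        df[f"zone:{p}"] = mask.astype(int)
    return df


def _sheet_from_frame(df: pd.DataFrame, config: SomatotopyConfig, conditions, centers) -> CorticalSheet:
    mean_maps = np.stack([df[f"mean:{c}"].to_numpy() for c in conditions])
    dist = np.stack([df[f"distributed:{c}"].to_numpy() for c in conditions])
    zones = {
        col.split(":", 1)[1]: df[col].to_numpy().astype(bool)
        for col in df.columns
        if col.startswith("zone:")
    }
    return CorticalSheet(
        coords_mm=df["coord_mm"].to_numpy(),
        conditions=tuple(conditions),
        mean_maps=mean_maps,
        distributed_maps=dist,
        zone_masks=zones,
        zone_centers=dict(centers),
        voxel_sd=df["voxel_sd"].to_numpy(),
        config=config,
    )


def config_to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return clean(d)


def somatotopy_from_dict(d: Mapping) -> SomatotopyConfig:
    d = dict(d)
    noise = d.pop("noise", {})
    if isinstance(noise, Mapping):
        noise = dict(noise)
        if "voxel_sd_range" in noise:
            noise["voxel_sd_range"] = tuple(noise["voxel_sd_range"])
        noise = NoiseConfig(**noise)
    return SomatotopyConfig(noise=noise, **d)


def save_cohort(cohort: Cohort, out_dir: Path) -> None:
    """Write a simulated cohort: NIfTI + events per run, ground truth, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subj in cohort.subjects:
        for hemi, hd in subj.hemispheres.items():
            d = out_dir / f"sub-{subj.subject_id:02d}" / f"hemi-{hemi}"
            d.mkdir(parents=True, exist_ok=True)
            _sheet_frame(hd.sheet).to_csv(d / "sheet.csv", index=False, float_format="%.17g")
            for kind, runs in (("task", hd.task_runs), ("localizer", hd.localizer_runs)):
                for r, run in enumerate(runs):
                    save_run(run, d / f"{kind}_run-{r:02d}.nii.gz", d / f"{kind}_run-{r:02d}_events.tsv")
    meta = {
        "task_id": cohort.task_id,
        "n_subjects": cohort.n_subjects,
        "hemispheres": list(cohort.subjects[0].hemispheres),
        "recipe": config_to_dict(cohort.recipe),
        "somatotopy": config_to_dict(cohort.config),
        "zone_centers": {
            k: float(v) for k, v in cohort.subjects[0].hemispheres[
                list(cohort.subjects[0].hemispheres)[0]
            ].sheet.zone_centers.items()
        },
        "manifest": cohort.manifest,
    }
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2))


def load_cohort(in_dir: Path) -> Cohort:
    """Read back a cohort written by :func:`save_cohort`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "cohort.json").read_text())
    cset = make_task(meta["task_id"])
    config = somatotopy_from_dict(meta["somatotopy"])
    recipe = SessionRecipe(**meta["recipe"])
    centers = meta["zone_centers"]
    loc_conditions = None
    subjects = []
    for sid in range(meta["n_subjects"]):
        hemis = {}
        for hemi in meta["hemispheres"]:
            d = in_dir / f"sub-{sid:02d}" / f"hemi-{hemi}"
            df = pd.read_csv(d / "sheet.csv")
            sheet = _sheet_from_frame(df, config, cset.conditions, centers)
            task_runs = []
            for r, p in enumerate(sorted(d.glob("task_run-*.nii.gz"))):
                ev = Path(str(p).replace(".nii.gz", "_events.tsv"))
                task_runs.append(load_run(p, ev, r))
            loc_runs = []
            for r, p in enumerate(sorted(d.glob("localizer_run-*.nii.gz"))):
                ev = Path(str(p).replace(".nii.gz", "_events.tsv"))
                loc_runs.append(load_run(p, ev, r))
            hemis[hemi] = HemisphereData(sheet=sheet, task_runs=task_runs, localizer_runs=loc_runs)
        subjects.append(Subject(subject_id=sid, hemispheres=hemis))
    return Cohort(
        task_id=meta["task_id"],
        condition_set=cset,
        recipe=recipe,
        config=config,
        subjects=subjects,
        manifest=meta.get("manifest", {}),
    )


def patterns_from_nifti(beta_path: Path, labels: pd.DataFrame | Path, voxel_idx=None) -> PatternSet:
    """User-supplied beta patterns: 4-D NIfTI + condition/run label table.

    The table needs columns ``condition`` and ``run``, one row per volume of
    the image, in volume order.
    """
    img = nib.load(str(beta_path))
    data = np.asarray(img.dataobj, dtype=float)
    flat = data.reshape(-1, data.shape[-1]).T  # volumes x voxels
    if not isinstance(labels, pd.DataFrame):
        labels = pd.read_csv(labels, sep=None, engine="python")
    if len(labels) != flat.shape[0]:
        raise ValueError("label table rows must match image volumes")
    if voxel_idx is not None:
        flat = flat[:, np.asarray(voxel_idx, int)]
    conditions = tuple(dict.fromkeys(labels["condition"].astype(str)))
    runs = sorted(labels["run"].unique())
    C, M = len(conditions), len(runs)
    P = flat.shape[1]
    out = np.full((C, M, P), np.nan)
    for v, (cond, run) in enumerate(zip(labels["condition"].astype(str), labels["run"])):
        out[conditions.index(cond), runs.index(run)] = flat[v]
    return PatternSet(out, conditions)


def rdm_to_long(rdm: RDM, subject=None, region=None) -> pd.DataFrame:
    rows = []
    C = len(rdm.conditions)
    for i in range(C):
        for j in range(i + 1, C):
            rows.append(
                {
                    "subject": subject,
                    "region": region,
                    "condition_i": rdm.conditions[i],
                    "condition_j": rdm.conditions[j],
                    "distance": rdm.values[i, j],
                }
            )
    return pd.DataFrame(rows)


def rdm_to_json_dict(rdm: RDM) -> dict:
    return {
        "conditions": list(rdm.conditions),
        "estimator": rdm.estimator,
        "values": [[float(v) for v in row] for row in rdm.values],
        "meta": {k: (v if isinstance(v, (str, int, float)) else str(v)) for k, v in rdm.meta.items()},
    }


def write_csv(df: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
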