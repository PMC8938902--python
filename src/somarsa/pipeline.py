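"""End-to-end experiments: simulate -> GLM -> RSA -> regions -> stats -> report.

An :class:`ExperimentConfig` (YAML round-trippable) fixes the task, cohort,
geometry and analysis switches plus one master seed; :func:`run_experiment`
executes every stage, writes tidy CSV/JSON outputs and a manifest with
config hash and per-file checksums, and summarises whether the expected
qualitative result pattern held:

* primary-only univariate significance in each ROI;
* above-zero crossnobis dissimilarities for non-primary pairs;
* adjacent < non-adjacent dissimilarity (subpart tasks);
* action dissociation at non-primary band peaks (body task with bands).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    AnalysisOptions,
    CohortAnalysis,
    analyze_cohort,
    band_group_stats,
    body_group_stats,
    subpart_group_stats,
)
from .io import (
    config_to_dict,
    file_checksum,
    rdm_to_json_dict,
    rdm_to_long,
    save_cohort,
    somatotopy_from_dict,
    write_csv,
)
from .rsa import average_rdms, classical_mds
from .sheet import SomatotopyConfig
from .simulate import Cohort, simulate_cohort
from .tasks import DEFAULT_RECIPES, SessionRecipe

logger = logging.getLogger(__name__)

ROI_NAMES = ("leg", "hand", "face")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    task: str = "body"
    n_subjects: int = 22
    n_hemispheres: int | None = None
    seed: int = 7
    somatotopy: SomatotopyConfig = field(default_factory=SomatotopyConfig)
    recipe: SessionRecipe | None = None
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n_subjects": self.n_subjects,
            "n_hemispheres": self.n_hemispheres,
            "seed": self.seed,
            "somatotopy": config_to_dict(self.somatotopy),
            "recipe": config_to_dict(self.recipe) if self.recipe else None,
            "analysis": config_to_dict(self.analysis),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        soma = d.get("somatotopy")
        recipe = d.get("recipe")
        analysis = d.get("analysis")
        return cls(
            task=d.get("task", "body"),
            n_subjects=int(d.get("n_subjects", 22)),
            n_hemispheres=d.get("n_hemispheres"),
            seed=int(d.get("seed", 7)),
            somatotopy=somatotopy_from_dict(soma) if soma else SomatotopyConfig(),
            recipe=SessionRecipe(**recipe) if recipe else None,
            analysis=AnalysisOptions(**analysis) if analysis else AnalysisOptions(),
        )

    def save(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    """In-memory result of one experiment run."""

    config: ExperimentConfig
    cohort: Cohort | None
    analysis: CohortAnalysis
    group: object  # BodyGroupResults | SubpartGroupResults
    bands: object | None
    summary: dict
    manifest: dict


def _summarize_body(group, bands) -> dict:
    uni = group.univariate_tests
    dis = group.dissimilarity_tests
    primary_sig = bool(uni[uni["primary"]]["significant"].all())
    nonprimary_ns = bool(~uni[~uni["primary"]]["significant"].any())
    nonprim = dis[~dis["involves_primary"]]
    nonprimary_dis = bool(nonprim["significant"].all())
    out = {
        "primary_univariate_significant": primary_sig,
        "nonprimary_univariate_not_significant": nonprimary_ns,
        "primary_only_univariate_selectivity": primary_sig and nonprimary_ns,
        "nonprimary_dissimilarities_positive": nonprimary_dis,
        "n_nonprimary_pairs_significant": int(nonprim["significant"].sum()),
        "n_nonprimary_pairs": int(len(nonprim)),
    }
    if bands is not None:
        pk = bands.peak_tests
        out["action_dissociation_at_nonprimary_peaks"] = bool(pk["significant"].all())
        out["n_peak_tests_significant"] = int(pk["significant"].sum())
        out["n_peak_tests"] = int(len(pk))
        out["peak_bands"] = {p: [int(b) for b in v] for p, v in bands.peak_bands.items()}
    return out


def _summarize_subparts(group, task: str) -> dict:
    uni = group.univariate_tests
    primary_roi = "face" if task == "face" else "hand"
    prim = uni[(uni["region"] == primary_roi)]
    paired = group.paired_tests
    prim_paired = paired[paired["region"] == primary_roi].iloc[0]
    nonprim_paired = paired[paired["region"] != primary_roi]
    topo_nonprim = bool(
        (
            nonprim_paired["significant"] & (nonprim_paired["mean_difference"] > 0)
        ).any()
    )
    return {
        "primary_roi_all_subparts_significant": bool(prim["significant"].all()),
        "adjacent_lt_nonadjacent_primary": bool(
            prim_paired["significant"] and prim_paired["mean_difference"] > 0
        ),
        "adjacent_lt_nonadjacent_any_nonprimary": topo_nonprim,
        "adjacency_dissimilarities_positive": bool(
            group.adjacency_tests["significant"].all()
        ),
        "hemisphere_effect_detected": bool(group.hemisphere_gate.any_significant),
    }


def run_experiment(
    config: ExperimentConfig,
    out_dir: Path | None = None,
    save_volumes: bool = False,
) -> ResultBundle:
    """Execute all stages for one config; write tables and a manifest.

    Any stage failure propagates with the stage named; outputs written by
    earlier stages are retained.
    """
    t0 = time.time()
    stage = "simulate"
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")
    try:
        cohort = simulate_cohort(
            config.task,
            config.n_subjects,
            config.somatotopy,
            config.recipe or DEFAULT_RECIPES[config.task],
            seed=config.seed,
            n_hemispheres=config.n_hemispheres,
        )
        manifest["stages"]["simulate"] = round(time.time() - t0, 3)
        if out and save_volumes:
            save_cohort(cohort, out / "sim")

        stage = "analysis"
        t1 = time.time()
        ca = analyze_cohort(cohort, config.analysis)
        manifest["stages"]["analysis"] = round(time.time() - t1, 3)

        stage = "stats"
        t1 = time.time()
        bands = None
        if config.task == "body":
            group = body_group_stats(ca)
            if config.analysis.compute_bands:
                bands = band_group_stats(ca)
            summary = _summarize_body(group, bands)
        else:
            group = subpart_group_stats(ca)
            summary = _summarize_subparts(group, config.task)
        summary["task"] = config.task
        summary["n_subjects"] = config.n_subjects
        manifest["stages"]["stats"] = round(time.time() - t1, 3)
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    bundle = ResultBundle(
        config=config,
        cohort=cohort,
        analysis=ca,
        group=group,
        bands=bands,
        summary=summary,
        manifest=manifest,
    )
    if out:
        _write_bundle(bundle, out)
    return bundle


def _flatten_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if isinstance(out.columns[0], tuple):
        out.columns = [f"{a}:{b}" for a, b in out.columns]
    out.insert(0, "subject", range(len(out)))
    return out


def _write_bundle(bundle: ResultBundle, out: Path) -> None:
    group = bundle.group
    ca = bundle.analysis
    task = bundle.config.task
    write_csv(group.univariate_tests, out / "univariate_tests.csv")
    if task == "body":
        write_csv(_flatten_columns(group.levels), out / "levels.csv")
        write_csv(_flatten_columns(group.part_dissimilarity), out / "part_dissimilarity.csv")
        write_csv(group.dissimilarity_tests, out / "dissimilarity_tests.csv")
        write_csv(_flatten_columns(group.action_dissimilarity), out / "action_dissimilarity.csv")
        write_csv(group.action_tests, out / "action_tests.csv")
    else:
        write_csv(_flatten_columns(group.levels), out / "levels.csv")
        write_csv(_flatten_columns(group.adjacency), out / "adjacency.csv")
        write_csv(group.adjacency_tests, out / "adjacency_tests.csv")
        write_csv(group.paired_tests, out / "paired_tests.csv")

    # subject-level RDMs (long CSV + JSON) and ROI definitions
    hemi0 = ca.hemispheres[0]
    rdm_frames, rdm_json, roi_json = [], {}, {}
    for i, subj in enumerate(ca.subjects):
        for roi in ROI_NAMES:
            rdm = average_rdms([subj[h].rdms[roi] for h in ca.hemispheres])
            rdm_frames.append(rdm_to_long(rdm, subject=i, region=roi))
            rdm_json[f"sub-{i:02d}_{roi}"] = rdm_to_json_dict(rdm)
        roi_json[f"sub-{i:02d}"] = {
            roi: [int(v) for v in subj[hemi0].rois[roi]] for roi in ROI_NAMES
        }
    write_csv(pd.concat(rdm_frames, ignore_index=True), out / "rdms.csv")
    (out / "rdms.json").write_text(json.dumps(rdm_json))
    (out / "rois.json").write_text(json.dumps(roi_json, indent=2))

    # group-mean RDM MDS coordinates per ROI
    mds_rows = []
    for roi in ROI_NAMES:
        rdms = [
            average_rdms([subj[h].rdms[roi] for h in ca.hemispheres])
            for subj in ca.subjects
        ]
        gmean = average_rdms(rdms)
        coords = classical_mds(gmean, n_dims=2)
        for cond, (x, y) in zip(gmean.conditions, coords):
            mds_rows.append({"region": roi, "condition": cond, "dim1": x, "dim2": y})
    write_csv(pd.DataFrame(mds_rows), out / "mds_coordinates.csv")

    if bundle.bands is not None:
        b = bundle.bands
        rows = []
        for pos, (bid, c_mm) in enumerate(zip(b.band_ids, b.centers_mm)):
            for part in b.level_curves:
                rows.append(
                    {
                        "band": bid,
                        "center_mm": c_mm,
                        "part": part,
                        "mean_z": b.level_curves[part][pos],
                        "action_dissimilarity": b.action_curves[part][pos],
                    }
                )
        write_csv(pd.DataFrame(rows), out / "band_profiles.csv")
        write_csv(b.peak_tests, out / "band_peak_tests.csv")
        (out / "band_exclusions.json").write_text(
            json.dumps([{"band": b_, "reason": r} for b_, r in b.excluded], indent=2)
        )

    (out / "summary.json").write_text(json.dumps(bundle.summary, indent=2, sort_keys=True))
    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        bundle.manifest["outputs"][p.name] = file_checksum(p)
    bundle.manifest["cohort"] = bundle.cohort.manifest if bundle.cohort else None
    bundle.manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))


def render_report(out_dir: Path) -> str:
    """Human-readable markdown summary of a written result bundle."""
    out = Path(out_dir)
    missing = [n for n in ("summary.json", "univariate_tests.csv") if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(f"bundle incomplete; missing {missing}")
    summary = json.loads((out / "summary.json").read_text())
    lines = [f"# somarsa experiment report ({summary.get('task')} task)", ""]
    lines.append(f"Subjects: {summary.get('n_subjects')}")
    lines.append("")
    lines.append("## Qualitative pattern checks")
    for key, val in sorted(summary.items()):
        if isinstance(val, bool):
            lines.append(f"- {key}: {'PASS' if val else 'FAIL'}")
    lines.append("")
    for name, title in [
        ("univariate_tests.csv", "Univariate activity levels"),
        ("dissimilarity_tests.csv", "Body-part dissimilarities"),
        ("action_tests.csv", "Action dissimilarities"),
        ("adjacency_tests.csv", "Adjacency-class dissimilarities"),
        ("paired_tests.csv", "Adjacent vs non-adjacent"),
        ("band_peak_tests.csv", "Band peak tests"),
    ]:
        p = out / name
        if p.exists():
            df = pd.read_csv(p)
            cols = [c for c in ("region", "comparison", "test", "statistic", "p", "d", "significant", "trend") if c in df.columns]
            lines.append(f"## {title}")
            lines.append("")
            lines.append(df[cols].to_string(index=False))
            lines.append("")
    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
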