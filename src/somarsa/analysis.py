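"""Subject- and group-level analysis of simulated (or supplied) cohorts.

Per subject-hemisphere: GLM on the localizer defines the three selectivity
ROIs; GLM on the task runs yields per-run condition patterns, fixed-effects
z maps, univariate ROI levels and noise-normalized crossnobis RDMs, plus
optional band profiles along the strip. Group level applies the
inference scheme: Bonferroni-corrected one-sample tests of activity levels
(two-tailed) and dissimilarities (one-tailed), adjacency contrasts, and the
hemisphere rmANOVA gate before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import ContrastSpec, build_design, contrast_stat, fit_run
from .regions import (
    PRIMARY_BODY_PART,
    BandProfile,
    ROISet,
    band_profiles,
    define_rois,
    find_peak_bands,
    make_bands,
    masks_from_coords,
)
from .rsa import RDM, PatternSet, average_rdms, crossnobis_rdm, noise_covariance, prewhiten, reduce_rdm
from .simulate import Cohort, HemisphereData, Subject
from .stats import (
    SubpartLayout,
    TestResult,
    adjacency_pairs,
    bonferroni_alpha,
    hemisphere_average,
    one_sample_test,
    paired_test,
)
from .tasks import ACTIONS, BODY_PARTS, ConditionSet, DEFAULT_HP_CUTOFF_S, localizer_conditions

ROI_NAMES = ("leg", "hand", "face")
BODY_PART_PAIRS = (("feet", "hand"), ("feet", "lips"), ("hand", "lips"))


@dataclass
class AnalysisOptions:
    """Switches of the analysis stage (sizes, cutoffs, alphas)."""

    roi_k: int = 50
    hp_cutoff_s: float | None = None  # task default when None
    localizer_hp_cutoff_s: float = 280.0
    shrinkage: str | float = "auto"
    compute_bands: bool = False
    n_bands: int = 30
    min_band_voxels: int = 5
    family_alpha: float = 0.05
    peak_rel_threshold: float = 0.9


@dataclass
class HemiAnalysis:
    """One hemisphere's ROI-level results."""

    rois: ROISet
    levels: dict[str, dict[str, float]]  # roi -> condition -> mean z
    rdms: dict[str, RDM]  # roi -> crossnobis RDM
    bands: BandProfile | None = None


def analyze_hemisphere(
    hemi: HemisphereData,
    condition_set: ConditionSet,
    options: AnalysisOptions | None = None,
) -> HemiAnalysis:
    """Full single-hemisphere pipeline: localizer ROIs, GLM, RSA, bands."""
    opts = options or AnalysisOptions()
    sheet = hemi.sheet
    task_hp = opts.hp_cutoff_s or DEFAULT_HP_CUTOFF_S.get(condition_set.task_id, 150.0)

    # --- localizer: vs-all-others selectivity maps -> ROIs
    loc_set = localizer_conditions()
    loc_fits = [
        fit_run(r, build_design(r, opts.localizer_hp_cutoff_s)) for r in hemi.localizer_runs
    ]
    loc_maps = {
        c: contrast_stat(loc_fits, ContrastSpec.vs_all_others(c, loc_set.conditions)).z
        for c in loc_set.conditions
    }
    masks = masks_from_coords(sheet.coords_mm)
    rois = define_rois(loc_maps, masks, k=opts.roi_k)

    # --- task GLM
    fits = [fit_run(r, build_design(r, task_hp)) for r in hemi.task_runs]
    conditions = condition_set.conditions
    z_maps = {
        c: contrast_stat(fits, ContrastSpec.vs_rest(c)).z for c in conditions
    }
    patterns = np.stack([f.condition_betas(conditions) for f in fits], axis=1)  # C,M,P
    residuals = [f.residuals for f in fits]
    dofs = [f.dof for f in fits]

    levels: dict[str, dict[str, float]] = {}
    rdms: dict[str, RDM] = {}
    for roi_name in rois.names:
        vox = rois[roi_name]
        levels[roi_name] = {c: float(np.mean(z_maps[c][vox])) for c in conditions}
        cov = noise_covariance([R[:, vox] for R in residuals], dofs, opts.shrinkage)
        ps = PatternSet(patterns[:, :, vox], conditions, meta={"roi": roi_name})
        rdms[roi_name] = crossnobis_rdm(prewhiten(ps, cov))

    bands = None
    if opts.compute_bands:
        partition = make_bands(sheet.coords_mm, n_bands=opts.n_bands)
        bands = band_profiles(
            patterns, z_maps, residuals, dofs, partition, conditions, opts.min_band_voxels
        )
    return HemiAnalysis(rois=rois, levels=levels, rdms=rdms, bands=bands)


@dataclass
class CohortAnalysis:
    """Per-subject hemisphere analyses for one cohort."""

    condition_set: ConditionSet
    options: AnalysisOptions
    subjects: list[dict[str, HemiAnalysis]]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple(self.subjects[0])


def analyze_cohort(cohort: Cohort, options: AnalysisOptions | None = None) -> CohortAnalysis:
    opts = options or AnalysisOptions()
    subjects = [
        {h: analyze_hemisphere(hd, cohort.condition_set, opts) for h, hd in s.hemispheres.items()}
        for s in cohort.subjects
    ]
    return CohortAnalysis(condition_set=cohort.condition_set, options=opts, subjects=subjects)


# ---------------------------------------------------------------------------
# group-level statistics


def _result_row(region: str, comparison: str, res: TestResult) -> dict:
    return {
        "region": region,
        "comparison": comparison,
        "n": res.n,
        "test": res.test_used,
        "tail": res.tail,
        "statistic": res.statistic,
        "p": res.p,
        "d": res.d,
        "d_ci_low": res.d_ci[0],
        "d_ci_high": res.d_ci[1],
        "alpha": round(res.alpha_corrected, 3),
        "significant": res.significant,
        "trend": res.trend,
        "shapiro_p": res.shapiro_p,
    }


def body_part_levels(hemi: HemiAnalysis, condition_set: ConditionSet) -> dict[str, dict[str, float]]:
    """ROI -> body part -> mean z, averaged over the part's two actions."""
    out: dict[str, dict[str, float]] = {}
    for roi, lv in hemi.levels.items():
        out[roi] = {
            p: float(np.mean([lv[c] for c in condition_set.conditions_of_part(p)]))
            for p in condition_set.subpart_order
        }
    return out


def body_pair_grouping(condition_set: ConditionSet) -> dict[str, list[tuple[str, str]]]:
    """Same-action condition pairs per body-part pair (averaged across actions)."""
    grouping: dict[str, list[tuple[str, str]]] = {}
    for pi, pj in BODY_PART_PAIRS:
        grouping[f"{pi}-{pj}"] = [(f"{pi}_{a}", f"{pj}_{a}") for a in ACTIONS]
    return grouping


def action_grouping(condition_set: ConditionSet) -> dict[str, list[tuple[str, str]]]:
    return {
        p: [(f"{p}_{ACTIONS[0]}", f"{p}_{ACTIONS[1]}")] for p in condition_set.subpart_order
    }


@dataclass
class BodyGroupResults:
    levels: pd.DataFrame  # subject x (roi, part) mean z
    univariate_tests: pd.DataFrame
    part_dissimilarity: pd.DataFrame  # subject x (roi, pair)
    dissimilarity_tests: pd.DataFrame
    action_dissimilarity: pd.DataFrame  # subject x (roi, part)
    action_tests: pd.DataFrame


def body_group_stats(ca: CohortAnalysis) -> BodyGroupResults:
    """Group inference for the body task (contralateral hemisphere).

    Activity levels: two-tailed one-sample vs zero, alpha corrected for the
    three body parts per ROI. Dissimilarities (part pairs averaged across
    actions, and within-part action pairs): one-tailed vs zero, same
    correction.
    """
    cset = ca.condition_set
    hemi0 = ca.hemispheres[0]
    alpha_raw, _ = bonferroni_alpha(ca.options.family_alpha, 3)

    lvl_rows, part_rows, act_rows = [], [], []
    pair_grouping = body_pair_grouping(cset)
    act_group = action_grouping(cset)
    for subj in ca.subjects:
        h = subj[hemi0]
        pl = body_part_levels(h, cset)
        lvl_rows.append({(roi, p): pl[roi][p] for roi in ROI_NAMES for p in BODY_PARTS})
        part_rows.append(
            {
                (roi, name): reduce_rdm(h.rdms[roi], pair_grouping)[name]
                for roi in ROI_NAMES
                for name in pair_grouping
            }
        )
        act_rows.append(
            {
                (roi, p): reduce_rdm(h.rdms[roi], act_group)[p]
                for roi in ROI_NAMES
                for p in BODY_PARTS
            }
        )
    levels = pd.DataFrame(lvl_rows)
    part_d = pd.DataFrame(part_rows)
    act_d = pd.DataFrame(act_rows)

    uni_tests = []
    for roi in ROI_NAMES:
        for p in BODY_PARTS:
            res = one_sample_test(levels[(roi, p)], "two-sided", alpha_raw)
            row = _result_row(roi, f"level:{p}", res)
            row["primary"] = PRIMARY_BODY_PART[roi] == p
            uni_tests.append(row)
    dis_tests = []
    for roi in ROI_NAMES:
        for name in pair_grouping:
            res = one_sample_test(part_d[(roi, name)], "greater", alpha_raw)
            row = _result_row(roi, f"dissimilarity:{name}", res)
            row["involves_primary"] = PRIMARY_BODY_PART[roi] in name.split("-")
            dis_tests.append(row)
    act_tests = []
    for roi in ROI_NAMES:
        for p in BODY_PARTS:
            res = one_sample_test(act_d[(roi, p)], "greater", alpha_raw)
            row = _result_row(roi, f"action_dissimilarity:{p}", res)
            row["primary"] = PRIMARY_BODY_PART[roi] == p
            act_tests.append(row)
    return BodyGroupResults(
        levels=levels,
        univariate_tests=pd.DataFrame(uni_tests),
        part_dissimilarity=part_d,
        dissimilarity_tests=pd.DataFrame(dis_tests),
        action_dissimilarity=act_d,
        action_tests=pd.DataFrame(act_tests),
    )


@dataclass
class SubpartGroupResults:
    levels: pd.DataFrame  # subject x (roi, subpart), hemisphere-averaged
    univariate_tests: pd.DataFrame
    adjacency: pd.DataFrame  # subject x (roi, class)
    adjacency_tests: pd.DataFrame
    paired_tests: pd.DataFrame
    hemisphere_gate: object


def subpart_group_stats(ca: CohortAnalysis) -> SubpartGroupResults:
    """Group inference for the face / finger tasks.

    Levels and RDMs are averaged across hemispheres after the rmANOVA
    hemisphere gate (factors hemisphere x ROI x subpart). Two-tailed level
    tests use alpha corrected for the number of subparts; adjacency-class
    dissimilarities use one-tailed tests corrected for the two classes, and
    adjacent vs non-adjacent is a paired test.
    """
    cset = ca.condition_set
    subparts = cset.subpart_order
    m = len(subparts)
    alpha_levels, _ = bonferroni_alpha(ca.options.family_alpha, m)
    alpha_adj, _ = bonferroni_alpha(ca.options.family_alpha, 2)
    adj, nonadj = adjacency_pairs(SubpartLayout(subparts))
    grouping = {"adjacent": list(adj), "non_adjacent": list(nonadj)}

    # hemisphere-wise level arrays: subject x roi x subpart
    by_hemi = {}
    for hname in ca.hemispheres:
        by_hemi[hname] = np.array(
            [
                [[subj[hname].levels[roi][c] for c in subparts] for roi in ROI_NAMES]
                for subj in ca.subjects
            ]
        )
    avg_levels, gate = hemisphere_average(by_hemi, factor_names=["roi", "subpart"])

    adj_rows = []
    for subj in ca.subjects:
        rdms = {roi: average_rdms([subj[h].rdms[roi] for h in ca.hemispheres]) for roi in ROI_NAMES}
        adj_rows.append(
            {
                (roi, cls): reduce_rdm(rdms[roi], grouping)[cls]
                for roi in ROI_NAMES
                for cls in grouping
            }
        )
    adjacency = pd.DataFrame(adj_rows)
    levels = pd.DataFrame(
        [
            {(roi, c): avg_levels[i, r, j] for r, roi in enumerate(ROI_NAMES) for j, c in enumerate(subparts)}
            for i in range(len(ca.subjects))
        ]
    )

    uni_tests = []
    primary_roi = "face" if cset.task_id == "face" else "hand"
    for roi in ROI_NAMES:
        for c in subparts:
            res = one_sample_test(levels[(roi, c)], "two-sided", alpha_levels)
            row = _result_row(roi, f"level:{c}", res)
            row["primary_roi"] = roi == primary_roi
            uni_tests.append(row)
    adj_tests = []
    for roi in ROI_NAMES:
        for cls in grouping:
            res = one_sample_test(adjacency[(roi, cls)], "greater", alpha_adj)
            adj_tests.append(_result_row(roi, f"dissimilarity:{cls}", res))
    paired = []
    for roi in ROI_NAMES:
        res = paired_test(
            adjacency[(roi, "non_adjacent")],
            adjacency[(roi, "adjacent")],
            "two-sided",
            ca.options.family_alpha,
        )
        row = _result_row(roi, "non_adjacent_minus_adjacent", res)
        row["mean_difference"] = float(
            (adjacency[(roi, "non_adjacent")] - adjacency[(roi, "adjacent")]).mean()
        )
        paired.append(row)
    return SubpartGroupResults(
        levels=levels,
        univariate_tests=pd.DataFrame(uni_tests),
        adjacency=adjacency,
        adjacency_tests=pd.DataFrame(adj_tests),
        paired_tests=pd.DataFrame(paired),
        hemisphere_gate=gate,
    )


@dataclass
class BandGroupResults:
    band_ids: list[int]
    centers_mm: np.ndarray
    level_curves: dict[str, np.ndarray]  # part -> group-mean z curve
    action_curves: dict[str, np.ndarray]  # part -> group-mean action dissimilarity
    peak_bands: dict[str, list[int]]  # primary part -> positions into retained bands
    peak_tests: pd.DataFrame
    excluded: list[tuple[int, str]]


def band_group_stats(ca: CohortAnalysis) -> BandGroupResults:
    """Strip profiles and the peak-band action-dissociation tests (body task).

    For each body part, the group-mean action-dissimilarity curve over
    retained bands is profiled; at the peak band(s) of each primary body
    part, the action dissimilarities of the two non-primary parts are tested
    one-tailed against zero with alpha corrected for the two comparisons.
    """
    cset = ca.condition_set
    hemi0 = ca.hemispheres[0]
    analyses = [s[hemi0] for s in ca.subjects]
    if analyses[0].bands is None:
        raise ValueError("band profiles were not computed; enable compute_bands")
    band_ids = analyses[0].bands.band_ids
    for a in analyses:
        if a.bands.band_ids != band_ids:
            raise ValueError("subjects disagree on retained bands")
    act_group = action_grouping(cset)
    # subject x retained-band x part action dissimilarities
    act = np.array(
        [
            [[reduce_rdm(rdm, act_group)[p] for p in BODY_PARTS] for rdm in a.bands.rdms]
            for a in analyses
        ]
    )
    level_curves = {}
    for p in BODY_PARTS:
        conds = cset.conditions_of_part(p)
        curves = np.array(
            [
                a.bands.levels[:, [cset.conditions.index(c) for c in conds]].mean(axis=1)
                for a in analyses
            ]
        )
        level_curves[p] = curves.mean(axis=0)
    action_curves = {p: act[:, :, i].mean(axis=0) for i, p in enumerate(BODY_PARTS)}

    alpha_raw, _ = bonferroni_alpha(ca.options.family_alpha, 2)
    peak_bands: dict[str, list[int]] = {}
    rows = []
    for i, p in enumerate(BODY_PARTS):
        peaks = find_peak_bands(action_curves[p], rel_threshold=ca.options.peak_rel_threshold)
        peak_bands[p] = peaks
        for pos in peaks:
            for j, other in enumerate(BODY_PARTS):
                if other == p:
                    continue
                res = one_sample_test(act[:, pos, j], "greater", alpha_raw)
                row = _result_row(f"band{band_ids[pos]}", f"action_dissimilarity:{other}", res)
                row["peak_of"] = p
                rows.append(row)
    centers = analyses[0].bands.partition.centers_mm()[band_ids]
    return BandGroupResults(
        band_ids=band_ids,
        centers_mm=centers,
        level_curves=level_curves,
        action_curves=action_curves,
        peak_bands=peak_bands,
        peak_tests=pd.DataFrame(rows),
        excluded=analyses[0].bands.excluded,
    )
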