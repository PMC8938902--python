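"""Simulation of block-design BOLD runs from a ground-truth sheet.

The noise-free part of every run is exactly the HRF-convolved boxcar design
times the sheet's condition patterns — the same convolution the GLM uses, so
noiseless simulations are recovered to machine precision. Noise adds
spatially correlated, heteroscedastic Gaussian innovations (smooth
squared-exponential field plus a white floor, sampled by circulant
embedding) with an AR(1) structure in time whose stationary covariance is
the sheet's ``true_noise_cov``.

A cohort bundles per-subject (and optionally per-hemisphere) sheets, task
runs and a body-part localizer run; all randomness flows from one master
seed through ``numpy.random.SeedSequence`` spawning, recorded in a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from . import glm as _glm
from .sheet import CorticalSheet, SomatotopyConfig, NoiseConfig, build_sheet, default_zone_centers
from .tasks import (
    DEFAULT_RECIPES,
    BlockTimeline,
    ConditionSet,
    SessionRecipe,
    balanced_sequence,
    layout_run,
    localizer_conditions,
    make_task,
)

__all__ = ["RunData", "simulate_run", "HemisphereData", "Subject", "Cohort", "simulate_cohort"]


@dataclass
class RunData:
    """One simulated (or loaded) BOLD run."""

    timeseries: np.ndarray  # volumes x voxels
    sequence: tuple[str, ...]  # movement block labels, in order
    onsets_s: tuple[float, ...]
    durations_s: tuple[float, ...]
    tr_s: float
    run_index: int = 0

    def __post_init__(self) -> None:
        ons = np.asarray(self.onsets_s)
        if ons.size and np.any(np.diff(ons) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if ons.size and np.any(ons[1:] < ons[:-1] + np.asarray(self.durations_s)[:-1]):
            raise ValueError("blocks must not overlap")

    @property
    def n_volumes(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.timeseries.shape[1]


_SMOOTH_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def _smooth_basis(coords: np.ndarray, length_mm: float) -> np.ndarray:
    """Factor B (rank x P) of the squared-exponential kernel, K = B'B.

    The Gaussian kernel's spectrum decays super-exponentially, so a truncated
    eigenbasis reproduces K to near machine precision at a small rank; the
    basis depends only on the grid geometry and is cached across subjects.
    """
    key = (coords.size, round(float(coords[-1] - coords[0]), 9), round(length_mm, 9))
    B = _SMOOTH_BASIS_CACHE.get(key)
    if B is None:
        d2 = (coords[:, None] - coords[None, :]) ** 2
        K = np.exp(-d2 / (2 * length_mm**2))
        w, V = np.linalg.eigh(K)
        keep = w > 1e-7 * w[-1]
        B = (V[:, keep] * np.sqrt(w[keep])).T
        _SMOOTH_BASIS_CACHE[key] = B
    return B


def _smooth_field(rng: np.random.Generator, n_samples: int, coords: np.ndarray, length_mm: float) -> np.ndarray:
    """Unit-variance stationary Gaussian field samples on the sheet grid."""
    B = _smooth_basis(coords, length_mm)
    return rng.standard_normal((n_samples, B.shape[0])) @ B


def _noise_innovations(
    rng: np.random.Generator, n_samples: int, sheet: CorticalSheet, noise: NoiseConfig
) -> np.ndarray:
    """Innovations with the sheet's stationary spatial covariance."""
    P = sheet.n_voxels
    mix = noise.spatial_mix if noise.spatial_kernel_mm > 0 else 0.0
    out = np.zeros((n_samples, P))
    if mix > 0:
        out += np.sqrt(mix) * _smooth_field(rng, n_samples, sheet.coords_mm, noise.spatial_kernel_mm)
    if mix < 1:
        out += np.sqrt(1 - mix) * rng.standard_normal((n_samples, P))
    return out * (noise.scanner_sd * sheet.voxel_sd)


def simulate_noise(
    rng: np.random.Generator, n_volumes: int, sheet: CorticalSheet, noise: NoiseConfig
) -> np.ndarray:
    """AR(1)-in-time noise whose stationary spatial covariance is true_noise_cov."""
    if noise.scanner_sd == 0:
        return np.zeros((n_volumes, sheet.n_voxels))
    eps = _noise_innovations(rng, n_volumes, sheet, noise)
    phi = noise.temporal_ar1
    if phi == 0:
        return eps
    w = np.sqrt(1 - phi**2)
    scaled = w * eps
    scaled[0] = eps[0]  # start the recursion at the stationary distribution
    return lfilter([1.0], [1.0, -phi], scaled, axis=0)


def simulate_run(
    sheet: CorticalSheet,
    sequence: Sequence[str],
    recipe: SessionRecipe,
    noise_config: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
    run_index: int = 0,
    timeline: BlockTimeline | None = None,
) -> RunData:
    """Simulate one run: convolved design times patterns, plus scanner noise."""
    unknown = [c for c in sequence if c not in sheet.conditions]
    if unknown:
        raise ValueError(f"sequence contains conditions not on the sheet: {unknown}")
    noise = noise_config if noise_config is not None else sheet.config.noise
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if timeline is None:
        timeline = layout_run(sequence, recipe)
    n_vol = recipe.n_volumes_per_run
    X = _glm._convolved_boxcars(
        sheet.conditions,
        timeline.labels,
        timeline.onsets_s,
        timeline.durations_s,
        n_vol,
        recipe.tr_s,
    )
    patterns = sheet.mean_maps + sheet.distributed_maps
    Y = X @ patterns
    Y += simulate_noise(rng, n_vol, sheet, noise)
    return RunData(
        timeseries=Y,
        sequence=timeline.labels,
        onsets_s=timeline.onsets_s,
        durations_s=timeline.durations_s,
        tr_s=recipe.tr_s,
        run_index=run_index,
    )


def localizer_sheet(sheet: CorticalSheet) -> CorticalSheet:
    """Localizer view of a hemisphere: body-part mean maps, no distributed signal.

    Shares coordinates, noise properties and zone geometry with the task
    sheet; used to simulate the independent ROI-defining localizer run.
    """
    cset = localizer_conditions()
    centers = default_zone_centers("localizer", sheet.config.axis_length_mm)
    sigma = sheet.config.tuning_width_mm
    a = sheet.config.primary_amplitude
    mean_maps = np.stack(
        [a * np.exp(-((sheet.coords_mm - centers[c]) ** 2) / (2 * sigma**2)) for c in cset.conditions]
    )
    return CorticalSheet(
        coords_mm=sheet.coords_mm,
        conditions=cset.conditions,
        mean_maps=mean_maps,
        distributed_maps=np.zeros_like(mean_maps),
        zone_masks=sheet.zone_masks,
        zone_centers=dict(centers),
        voxel_sd=sheet.voxel_sd,
        config=sheet.config,
    )


@dataclass
class HemisphereData:
    """One hemisphere of one subject: ground truth plus simulated runs."""

    sheet: CorticalSheet
    task_runs: list[RunData]
    localizer_runs: list[RunData]


@dataclass
class Subject:
    subject_id: int
    hemispheres: dict[str, HemisphereData]


@dataclass
class Cohort:
    task_id: str
    condition_set: ConditionSet
    recipe: SessionRecipe
    config: SomatotopyConfig
    subjects: list[Subject]
    manifest: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _hemisphere_names(n: int) -> list[str]:
    return ["L", "R"][:n]


def simulate_subject(
    condition_set: ConditionSet,
    config: SomatotopyConfig,
    recipe: SessionRecipe,
    subject_ss: np.random.SeedSequence,
    subject_id: int,
    n_hemispheres: int = 1,
    with_localizer: bool = True,
    localizer_recipe: SessionRecipe | None = None,
) -> Subject:
    """Simulate one subject: independent sheets and noise per hemisphere."""
    loc_recipe = localizer_recipe or DEFAULT_RECIPES["localizer"]
    hemis: dict[str, HemisphereData] = {}
    for hemi, hemi_ss in zip(_hemisphere_names(n_hemispheres), subject_ss.spawn(n_hemispheres)):
        sheet_ss, seq_ss, noise_ss, loc_ss = hemi_ss.spawn(4)
        sheet = build_sheet(condition_set, config, np.random.default_rng(sheet_ss))
        sequences = balanced_sequence(
            condition_set, recipe, seed=int(seq_ss.generate_state(1)[0] % (2**31))
        )
        noise_rng = np.random.default_rng(noise_ss)
        task_runs = [
            simulate_run(sheet, seq, recipe, seed=noise_rng, run_index=r)
            for r, seq in enumerate(sequences)
        ]
        loc_runs: list[RunData] = []
        if with_localizer:
            lsheet = localizer_sheet(sheet)
            lset = localizer_conditions()
            loc_sequences = balanced_sequence(
                lset, loc_recipe, seed=int(loc_ss.generate_state(1)[0] % (2**31))
            )
            loc_rng = np.random.default_rng(loc_ss.spawn(1)[0])
            loc_runs = [
                simulate_run(lsheet, seq, loc_recipe, seed=loc_rng, run_index=r)
                for r, seq in enumerate(loc_sequences)
            ]
        hemis[hemi] = HemisphereData(sheet=sheet, task_runs=task_runs, localizer_runs=loc_runs)
    return Subject(subject_id=subject_id, hemispheres=hemis)


def simulate_cohort(
    task_id: str,
    n_subjects: int,
    somatotopy_config: SomatotopyConfig | None = None,
    recipe: SessionRecipe | None = None,
    seed: int = 0,
    n_hemispheres: int | None = None,
    with_localizer: bool = True,
) -> Cohort:
    """Simulate a cohort of independent participants for one task.

    Defaults follow the emulated protocol: 22 subjects, one (contralateral)
    hemisphere for the body task; two hemispheres for the bilateral face and
    finger tasks. Every subject gets independent distributed patterns and
    noise; zone geometry is shared.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cset = make_task(task_id)
    config = somatotopy_config or SomatotopyConfig()
    recipe = recipe or DEFAULT_RECIPES[task_id]
    recipe.validate_for(cset.n_conditions)
    if n_hemispheres is None:
        n_hemispheres = 1 if task_id == "body" else 2
    master = np.random.SeedSequence(seed)
    subject_ss = master.spawn(n_subjects)
    subjects = [
        simulate_subject(cset, config, recipe, ss, sid, n_hemispheres, with_localizer)
        for sid, ss in enumerate(subject_ss)
    ]
    manifest = {
        "task_id": task_id,
        "n_subjects": n_subjects,
        "n_hemispheres": n_hemispheres,
        "master_seed": seed,
        "subject_entropy": [list(map(int, ss.entropy if isinstance(ss.entropy, tuple) else [ss.entropy])) for ss in subject_ss],
        "subject_spawn_keys": [list(map(int, ss.spawn_key)) for ss in subject_ss],
    }
    return Cohort(
        task_id=task_id,
        condition_set=cset,
        recipe=recipe,
        config=config,
        subjects=subjects,
        manifest=manifest,
    )
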