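"""Selectivity-based ROIs and band-wise strip profiling.

ROIs are winner-takes-all: within an anatomical mask (an axis interval on
the synthetic sheet), the K voxels most activated by the matching localizer
contrast form the region — leg ROI from the toe contrast in the medial mask,
hand ROI in the central mask, face ROI from the lip contrast in the lateral
mask, each of fixed size K (default 50).

Band profiling segments the strip into equal-height medio-lateral bands
(default 30) and repeats the univariate and crossnobis analyses in each
band, excluding bands with too few voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .rsa import RDM, PatternSet, crossnobis_rdm, noise_covariance, prewhiten
from .sheet import default_anatomical_intervals

__all__ = [
    "AnatomicalMask",
    "masks_from_coords",
    "select_top_voxels",
    "ROISet",
    "define_rois",
    "BandPartition",
    "make_bands",
    "BandProfile",
    "band_profiles",
    "find_peak_bands",
]

#: anatomical mask -> (localizer contrast condition, ROI name)
ROI_RECIPE: dict[str, tuple[str, str]] = {
    "medial": ("toes", "leg"),
    "central": ("hand", "hand"),
    "lateral": ("lips", "face"),
}

#: ROI name -> its primary body part in the body task
PRIMARY_BODY_PART: dict[str, str] = {"leg": "feet", "hand": "hand", "face": "lips"}


@dataclass(frozen=True)
class AnatomicalMask:
    """Named axis interval with its member voxel indices."""

    name: str
    interval_mm: tuple[float, float]
    voxel_idx: np.ndarray

    def __len__(self) -> int:
        return self.voxel_idx.size


def masks_from_coords(
    coords_mm: np.ndarray,
    intervals: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, AnatomicalMask]:
    """Medial/central/lateral masks as intervals on the sheet axis.

    Defaults follow the reference geometry: a hand interval around the strip
    centre with a 1 cm gap above and below separating the medial and lateral
    masks.
    """
    if intervals is None:
        intervals = default_anatomical_intervals(float(coords_mm[-1]))
    out: dict[str, AnatomicalMask] = {}
    for name, (lo, hi) in intervals.items():
        idx = np.flatnonzero((coords_mm >= lo) & (coords_mm <= hi))
        out[name] = AnatomicalMask(name=name, interval_mm=(lo, hi), voxel_idx=idx)
    return out


def select_top_voxels(stat_values: np.ndarray, mask_idx: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most activated mask voxels, ties to the lower index.

    ``stat_values`` is a full-sheet statistic map (z); the result is sorted
    by voxel index and deterministic.
    """
    mask_idx = np.asarray(mask_idx, dtype=int)
    if mask_idx.size < k:
        raise ValueError(
            f"mask has {mask_idx.size} voxels but k={k} were requested"
        )
    z = np.asarray(stat_values, float)[mask_idx]
    order = np.lexsort((mask_idx, -z))  # highest z first, lower index on ties
    return np.sort(mask_idx[order[:k]])


@dataclass
class ROISet:
    """Fixed-size selectivity ROIs keyed by region name."""

    rois: dict[str, np.ndarray]
    k: int
    source_contrasts: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.rois[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.rois)


def define_rois(
    localizer_statmaps: Mapping[str, np.ndarray],
    masks: Mapping[str, AnatomicalMask],
    k: int = 50,
) -> ROISet:
    """Winner-takes-all ROIs from localizer vs-all-others selectivity maps.

    ``localizer_statmaps`` maps localizer conditions (toes, hand, lips) to
    full-sheet z maps of their vs-all-others contrast.
    """
    rois: dict[str, np.ndarray] = {}
    sources: dict[str, str] = {}
    for mask_name, (contrast_cond, roi_name) in ROI_RECIPE.items():
        z = localizer_statmaps[contrast_cond]
        z = z.z if hasattr(z, "z") else np.asarray(z, float)
        rois[roi_name] = select_top_voxels(z, masks[mask_name].voxel_idx, k)
        sources[roi_name] = f"{contrast_cond}_vs_others"
    return ROISet(rois=rois, k=k, source_contrasts=sources)


@dataclass
class BandPartition:
    """Equal-height medio-lateral bands over the strip interval."""

    edges_mm: np.ndarray  # n_bands + 1 edges
    band_voxels: list[np.ndarray]

    @property
    def n_bands(self) -> int:
        return len(self.band_voxels)

    @property
    def band_height_mm(self) -> float:
        return float(self.edges_mm[1] - self.edges_mm[0])

    def centers_mm(self) -> np.ndarray:
        return (self.edges_mm[:-1] + self.edges_mm[1:]) / 2.0


def make_bands(
    coords_mm: np.ndarray,
    strip_interval: tuple[float, float] | None = None,
    n_bands: int = 30,
) -> BandPartition:
    """Segment the strip into ``n_bands`` equal-height bands.

    Bands are half-open ``[e_i, e_{i+1})`` with the last band closed; every
    strip voxel belongs to exactly one band.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if strip_interval is None:
        strip_interval = (float(coords_mm[0]), float(coords_mm[-1]))
    lo, hi = strip_interval
    if not hi > lo:
        raise ValueError("empty strip interval")
    edges = np.linspace(lo, hi, n_bands + 1)
    in_strip = (coords_mm >= lo) & (coords_mm <= hi)
    which = np.clip(np.searchsorted(edges, coords_mm, side="right") - 1, 0, n_bands - 1)
    band_voxels = [
        np.flatnonzero(in_strip & (which == b)) for b in range(n_bands)
    ]
    return BandPartition(edges_mm=edges, band_voxels=band_voxels)


@dataclass
class BandProfile:
    """Per-band univariate levels and RDMs for one subject-hemisphere."""

    band_ids: list[int]
    voxel_counts: list[int]
    levels: np.ndarray  # retained band x condition mean z
    rdms: list[RDM]
    conditions: tuple[str, ...]
    excluded: list[tuple[int, str]]
    partition: BandPartition

    def level_curve(self, condition: str) -> np.ndarray:
        return self.levels[:, self.conditions.index(condition)]


def band_profiles(
    patterns: np.ndarray,
    z_maps: Mapping[str, np.ndarray],
    residuals_by_run: Sequence[np.ndarray],
    dofs: Sequence[int],
    partition: BandPartition,
    conditions: Sequence[str],
    min_voxels: int = 5,
) -> BandProfile:
    """Univariate and crossnobis analyses repeated in every retained band.

    ``patterns`` is the full-sheet (condition, run, voxel) beta array;
    ``z_maps`` maps each condition to its full-sheet fixed-effects z map.
    Bands with fewer than ``min_voxels`` voxels are excluded and recorded.
    """
    conditions = tuple(conditions)
    band_ids: list[int] = []
    counts: list[int] = []
    levels: list[np.ndarray] = []
    rdms: list[RDM] = []
    excluded: list[tuple[int, str]] = []
    for b, vox in enumerate(partition.band_voxels):
        if vox.size < min_voxels:
            excluded.append((b, f"{vox.size} voxels < min_voxels={min_voxels}"))
            continue
        band_ids.append(b)
        counts.append(int(vox.size))
        levels.append(np.array([float(np.mean(np.asarray(z_maps[c])[vox])) for c in conditions]))
        cov = noise_covariance([R[:, vox] for R in residuals_by_run], dofs)
        ps = PatternSet(patterns[:, :, vox], conditions, meta={"band": b})
        rdms.append(crossnobis_rdm(prewhiten(ps, cov)))
    if not band_ids:
        raise ValueError("all bands excluded; nothing to profile")
    return BandProfile(
        band_ids=band_ids,
        voxel_counts=counts,
        levels=np.vstack(levels),
        rdms=rdms,
        conditions=conditions,
        excluded=excluded,
        partition=partition,
    )


def find_peak_bands(
    curve: np.ndarray,
    restrict: np.ndarray | None = None,
    rel_threshold: float = 0.9,
) -> list[int]:
    """Peak positions of a group-mean band curve (0-based, into ``curve``).

    Returns the global maximum within the restricted positions plus any local
    maximum (strictly greater than both retained neighbours) whose value is
    at least ``rel_threshold`` times the global maximum.
    """
    curve = np.asarray(curve, float)
    if restrict is None:
        pos = np.arange(curve.size)
    else:
        restrict = np.asarray(restrict)
        pos = np.flatnonzero(restrict) if restrict.dtype == bool else restrict.astype(int)
    if pos.size == 0:
        raise ValueError("empty restriction interval")
    sub = curve[pos]
    gmax_at = int(pos[int(np.argmax(sub))])
    gmax = float(curve[gmax_at])
    peaks = {gmax_at}
    for i, p in enumerate(pos):
        left = sub[i - 1] if i > 0 else -np.inf
        right = sub[i + 1] if i < pos.size - 1 else -np.inf
        if sub[i] > left and sub[i] > right and sub[i] >= rel_threshold * gmax:
            peaks.add(int(p))
    return sorted(peaks)
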