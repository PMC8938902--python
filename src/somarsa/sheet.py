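"""Ground-truth somatotopic cortical sheet.

The simulator reduces the postcentral strip to a one-dimensional sheet of P
voxels along the medio-lateral axis (feet medial, face lateral): every
analysis downstream — zone masks, 50-voxel ROIs, equal-height bands — is an
interval operation on this axis.

Each condition contributes two signal components:

* a *mean map*: a Gaussian bump of amplitude ``a`` centred on the condition's
  body-part zone (tuning width ``sigma_mm``) — the classical somatotopic
  activation that univariate mapping sees;
* a *distributed pattern*: a mean-free voxel pattern of amplitude ``eps``
  present across the whole sheet — information without activation. Patterns
  of neighbouring subparts are correlated (``neighbor_corr ** rank_distance``)
  so that adjacent subparts are more similar than non-adjacent ones
  everywhere on the sheet.

For the body task, action-specific mean-free patterns (amplitude
``action_amplitude``) are shared across body parts, so two actions of the
same part are discriminable anywhere while same-action part pairs differ only
through the part patterns.

Noise is heteroscedastic, spatially correlated (squared-exponential kernel
plus a white thermal floor) and AR(1) in time; the sheet can reproduce the
exact voxel-by-voxel noise covariance for oracle computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .tasks import (
    ACTIONS,
    BODY_PARTS,
    ConditionSet,
    FACE_SUBPARTS,
    FINGERS,
    LOCALIZER_CONDITIONS,
)

__all__ = [
    "NoiseConfig",
    "SomatotopyConfig",
    "CorticalSheet",
    "build_sheet",
    "true_pattern_distance",
    "default_zone_centers",
    "default_anatomical_intervals",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Scanner-noise model: AR(1) in time, correlated + heteroscedastic in space.

    ``spatial_mix`` is the variance fraction carried by the smooth
    (squared-exponential, length scale ``spatial_kernel_mm``) component; the
    remainder is white thermal noise, which also keeps the spatial covariance
    well conditioned.
    """

    temporal_ar1: float = 0.3
    spatial_kernel_mm: float = 1.5
    voxel_sd_range: tuple[float, float] = (0.7, 1.3)
    scanner_sd: float = 3.5
    spatial_mix: float = 0.75

    def __post_init__(self) -> None:
        if not abs(self.temporal_ar1) < 1:
            raise ValueError("temporal_ar1 must satisfy |phi| < 1")
        lo, hi = self.voxel_sd_range
        if lo <= 0 or hi < lo:
            raise ValueError("voxel_sd_range must be positive with min <= max")
        if self.scanner_sd < 0:
            raise ValueError("scanner_sd must be >= 0")
        if not 0.0 <= self.spatial_mix <= 1.0:
            raise ValueError("spatial_mix must lie in [0, 1]")
        if self.spatial_kernel_mm < 0:
            raise ValueError("spatial_kernel_mm must be >= 0")


def default_zone_centers(task_id: str, axis_length_mm: float = 62.7) -> dict[str, float]:
    """Canonical zone centres (mm) along the medio-lateral axis.

    Body parts sit at 15% / 50% / 85% of the strip (feet medial, lips
    lateral); face subparts tile the lateral zone, digits the central hand
    zone in D1..D5 order.
    """
    L = axis_length_mm
    feet, hand, lips = 0.15 * L, 0.5 * L, 0.85 * L
    if task_id in ("body", "localizer"):
        parts = BODY_PARTS if task_id == "body" else LOCALIZER_CONDITIONS
        return dict(zip(parts, (feet, hand, lips)))
    if task_id == "face":
        step = 0.035 * L
        start = lips - 1.5 * step
        return {p: start + i * step for i, p in enumerate(FACE_SUBPARTS)}
    if task_id == "finger":
        step = 0.032 * L
        start = hand - 2 * step
        return {d: start + i * step for i, d in enumerate(FINGERS)}
    raise ValueError(f"no default zone centers for task {task_id!r}")


def default_anatomical_intervals(
    axis_length_mm: float = 62.7, gap_mm: float = 10.0, hand_halfwidth_mm: float = 8.0
) -> dict[str, tuple[float, float]]:
    """Medial / central / lateral mask intervals with a gap around the hand zone."""
    L = axis_length_mm
    hand = 0.5 * L
    central = (hand - hand_halfwidth_mm, hand + hand_halfwidth_mm)
    return {
        "medial": (0.0, central[0] - gap_mm),
        "central": central,
        "lateral": (central[1] + gap_mm, L),
    }


@dataclass(frozen=True)
class SomatotopyConfig:
    """Geometry and effect amplitudes of the synthetic sheet.

    Defaults: P=1500 voxels over a 62.7 mm strip, 4 mm tuning width, peak
    mean response a=3, distributed amplitude eps=0.3, neighbour correlation
    rho=0.6 — amplitudes in the arbitrary units of GLM response estimates.
    """

    n_voxels: int = 1500
    axis_length_mm: float = 62.7
    zone_centers: Mapping[str, float] | None = None
    tuning_width_mm: float = 4.0
    primary_amplitude: float = 3.0
    distributed_amplitude: float = 0.3
    neighbor_corr: float = 0.6
    action_amplitude: float = 0.3
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.tuning_width_mm <= 0:
            raise ValueError("tuning_width_mm must be > 0")
        if self.distributed_amplitude < 0 or self.action_amplitude < 0:
            raise ValueError("pattern amplitudes must be >= 0")
        if not 0.0 <= self.neighbor_corr < 1.0:
            raise ValueError("neighbor_corr must lie in [0, 1)")
        if self.zone_centers is not None:
            for part, mu in self.zone_centers.items():
                if not 0.0 <= mu <= self.axis_length_mm:
                    raise ValueError(f"zone center for {part!r} outside the strip")


@dataclass
class CorticalSheet:
    """Noise-free ground truth for one simulated hemisphere.

    ``mean_maps`` and ``distributed_maps`` are condition x voxel;
    ``zone_masks`` are boolean ground-truth primary zones per subpart.
    ``voxel_sd`` holds the per-voxel noise standard deviations drawn for this
    sheet; with the config's kernel they determine the exact noise covariance.
    """

    coords_mm: np.ndarray
    conditions: tuple[str, ...]
    mean_maps: np.ndarray
    distributed_maps: np.ndarray
    zone_masks: dict[str, np.ndarray]
    zone_centers: dict[str, float]
    voxel_sd: np.ndarray
    config: SomatotopyConfig

    @property
    def n_voxels(self) -> int:
        return self.coords_mm.size

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None

    def pattern(self, condition: str) -> np.ndarray:
        i = self.condition_index(condition)
        return self.mean_maps[i] + self.distributed_maps[i]

    def true_noise_cov(self, voxel_idx: Sequence[int] | None = None) -> np.ndarray:
        """Stationary spatial noise covariance (optionally a voxel subset)."""
        nc = self.config.noise
        idx = np.arange(self.n_voxels) if voxel_idx is None else np.asarray(voxel_idx)
        x = self.coords_mm[idx]
        if nc.spatial_kernel_mm > 0 and nc.spatial_mix > 0:
            d2 = (x[:, None] - x[None, :]) ** 2
            corr = nc.spatial_mix * np.exp(-d2 / (2 * nc.spatial_kernel_mm**2))
        else:
            corr = np.zeros((idx.size, idx.size))
        corr[np.diag_indices_from(corr)] = 1.0
        sd = nc.scanner_sd * self.voxel_sd[idx]
        return sd[:, None] * corr * sd[None, :]


def _correlated_subpart_patterns(
    rng: np.random.Generator, n_subparts: int, n_voxels: int, rho: float
) -> np.ndarray:
    """Unit-variance voxel patterns with corr(g_i, g_j) = rho**|i-j| across ranks."""
    g = np.empty((n_subparts, n_voxels))
    g[0] = rng.standard_normal(n_voxels)
    for k in range(1, n_subparts):
        g[k] = rho * g[k - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_voxels)
    return g


def build_sheet(
    condition_set: ConditionSet,
    config: SomatotopyConfig,
    rng: np.random.Generator | None = None,
) -> CorticalSheet:
    """Draw one participant-hemisphere's ground-truth sheet.

    Mean maps are Gaussian bumps ``a * exp(-(x - mu_c)^2 / (2 sigma^2))``;
    distributed patterns are drawn once per sheet with neighbour correlation
    ``rho**rank_distance`` and mean-centred per condition.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    P = config.n_voxels
    coords = np.linspace(0.0, config.axis_length_mm, P)
    centers = dict(
        config.zone_centers
        if config.zone_centers is not None
        else default_zone_centers(condition_set.task_id, config.axis_length_mm)
    )
    missing = [p for p in condition_set.subpart_order if p not in centers]
    if missing:
        raise ValueError(f"zone_centers missing subparts {missing}")

    sigma = config.tuning_width_mm
    conditions = condition_set.conditions
    C = len(conditions)

    mean_maps = np.zeros((C, P))
    for i, cond in enumerate(conditions):
        mu = centers[condition_set.part_of(cond)]
        mean_maps[i] = config.primary_amplitude * np.exp(-((coords - mu) ** 2) / (2 * sigma**2))

    subparts = condition_set.subpart_order
    g = _correlated_subpart_patterns(rng, len(subparts), P, config.neighbor_corr)
    part_pattern = {p: g[k] for k, p in enumerate(subparts)}

    distributed = np.zeros((C, P))
    eps = config.distributed_amplitude
    if condition_set.action_factor is not None:
        # action patterns shared across body parts so that same-action part
        # pairs differ only through the part patterns (and vice versa)
        action_patterns = {a: rng.standard_normal(P) for a in ACTIONS}
        for i, cond in enumerate(conditions):
            part, action = condition_set.action_factor[cond]
            distributed[i] = (
                eps * part_pattern[part]
                + config.action_amplitude * action_patterns[action]
            )
    else:
        for i, cond in enumerate(conditions):
            distributed[i] = eps * part_pattern[cond]
    distributed -= distributed.mean(axis=1, keepdims=True)

    half = 2.0 * sigma
    zone_masks = {
        p: (np.abs(coords - centers[p]) <= half) for p in subparts
    }
    lo, hi = config.noise.voxel_sd_range
    voxel_sd = rng.uniform(lo, hi, size=P)
    return CorticalSheet(
        coords_mm=coords,
        conditions=tuple(conditions),
        mean_maps=mean_maps,
        distributed_maps=distributed,
        zone_masks={k: v.copy() for k, v in zone_masks.items()},
        zone_centers=centers,
        voxel_sd=voxel_sd,
        config=config,
    )


def true_pattern_distance(
    sheet: CorticalSheet,
    condition_pair: tuple[str, str],
    voxel_set: Sequence[int],
) -> float:
    """Ground-truth whitened squared pattern distance per voxel.

    ``||Sigma^{-1/2} (p_i - p_j)||^2 / P`` over the voxel set, with Sigma the
    true noise covariance restricted to those voxels. Oracle for crossnobis
    parameter-recovery tests.
    """
    idx = np.asarray(voxel_set, dtype=int)
    if idx.size == 0:
        raise ValueError("voxel_set must be non-empty")
    i = sheet.condition_index(condition_pair[0])
    j = sheet.condition_index(condition_pair[1])
    if i == j:
        return 0.0
    delta = (
        sheet.mean_maps[i]
        + sheet.distributed_maps[i]
        - sheet.mean_maps[j]
        - sheet.distributed_maps[j]
    )[idx]
    cov = sheet.true_noise_cov(idx)
    return float(delta @ np.linalg.solve(cov, delta) / idx.size)
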