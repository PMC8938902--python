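"""Cross-validated Mahalanobis (crossnobis) representational dissimilarity.

The crossnobis estimator computes, for each condition pair (i, j), the
squared Mahalanobis distance between their multivoxel response patterns with
the inner product cross-validated over independent runs:

    d_ij = 1 / (M (M-1) P) * sum_{m != n} (b_im - b_jm) . (b_in - b_jn)

on prewhitened patterns (right-multiplied by the inverse square root of the
voxel noise covariance, estimated from GLM residuals with shrinkage toward
its diagonal). Cross-validation makes the estimator unbiased: distances are
expected zero — and may be negative — when two patterns differ only by
noise, so above-zero distances index true information content. Division by
the voxel count P makes values comparable across region sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseCov",
    "ShrunkNoiseCovariance",
    "noise_covariance",
    "PatternSet",
    "prewhiten",
    "RDM",
    "crossnobis_rdm",
    "reduce_rdm",
    "ClassicalMDS",
    "classical_mds",
]


@dataclass
class NoiseCov:
    """Voxel noise covariance with diagonal shrinkage."""

    covariance: np.ndarray
    shrinkage: float
    source_dof: int

    def whitener(self) -> np.ndarray:
        """Symmetric inverse square root of the covariance."""
        w, V = np.linalg.eigh(self.covariance)
        if w.min() <= 0:
            raise np.linalg.LinAlgError("noise covariance is not positive definite")
        return (V * (1.0 / np.sqrt(w))) @ V.T


def _shrinkage_lambda(rows: np.ndarray) -> float:
    """Schafer-Strimmer analytic shrinkage intensity toward the diagonal."""
    n, P = rows.shape
    if n < 2:
        return 1.0
    wbar = rows.T @ rows / n
    w2 = (rows**2).T @ (rows**2)
    var_s = n / (n - 1) ** 3 * (w2 - n * wbar**2)
    s = n / (n - 1) * wbar
    off = ~np.eye(P, dtype=bool)
    denom = float((s[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_s[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


class ShrunkNoiseCovariance(BaseEstimator, TransformerMixin):
    """Run-pooled residual covariance, shrunk toward its diagonal.

    Per-run covariances R_m' R_m / dof_m are averaged across runs and shrunk
    as ``(1 - lam) * S + lam * diag(S)``; ``shrinkage='auto'`` picks lam by
    the Ledoit-Wolf-style analytic formula on the pooled residual rows.
    Shrinking toward the full diagonal (not a scaled identity) preserves the
    down-weighting of noisy voxels while guaranteeing invertibility when the
    voxel count exceeds the residual dof.

    transform(X) prewhitens row-vector patterns with the inverse square root
    of the fitted covariance.
    """

    def __init__(self, shrinkage: str | float = "auto"):
        self.shrinkage = shrinkage

    def fit(self, residuals_by_run: Sequence[np.ndarray], dofs: Sequence[int] | None = None):
        if isinstance(residuals_by_run, np.ndarray) and residuals_by_run.ndim == 2:
            residuals_by_run = [residuals_by_run]
        if len(residuals_by_run) == 0:
            raise ValueError("at least one run of residuals is required")
        if dofs is None:
            dofs = [r.shape[0] for r in residuals_by_run]
        covs = []
        for R, dof in zip(residuals_by_run, dofs):
            R = np.asarray(R, float)
            if dof <= 0:
                raise ValueError("residual dof must be positive")
            covs.append(R.T @ R / dof)
        S = np.mean(covs, axis=0)
        if not np.any(S):
            raise ValueError("degenerate all-zero residuals")
        if self.shrinkage == "auto":
            pooled = np.vstack(residuals_by_run)
            lam = _shrinkage_lambda(pooled)
        else:
            lam = float(self.shrinkage)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("shrinkage must lie in [0, 1]")
        d = np.diag(np.diag(S))
        self.covariance_ = (1.0 - lam) * S + lam * d
        self.shrinkage_ = lam
        self.dof_ = int(sum(dofs))
        nc = NoiseCov(self.covariance_, lam, self.dof_)
        self.whitener_ = nc.whitener()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return X @ self.whitener_

    def to_noise_cov(self) -> NoiseCov:
        return NoiseCov(self.covariance_, self.shrinkage_, self.dof_)


def noise_covariance(
    residuals_by_run: Sequence[np.ndarray],
    dofs: Sequence[int] | None = None,
    lambda_mode: str | float = "auto",
) -> NoiseCov:
    """Shrunk voxel noise covariance from per-run GLM residuals."""
    est = ShrunkNoiseCovariance(shrinkage=lambda_mode).fit(residuals_by_run, dofs)
    return est.to_noise_cov()


@dataclass
class PatternSet:
    """Condition x run x voxel response estimates for one voxel set."""

    patterns: np.ndarray  # (C, M, P)
    conditions: tuple[str, ...]
    whitened: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (conditions, runs, voxels)")
        if self.patterns.shape[0] != len(self.conditions):
            raise ValueError("condition axis does not match labels")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain missing cells")

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]


def prewhiten(pattern_set: PatternSet, noise_cov: NoiseCov) -> PatternSet:
    """Multivariate noise normalization: patterns times Sigma^{-1/2}."""
    if noise_cov.covariance.shape[0] != pattern_set.n_voxels:
        raise ValueError("voxel sets of patterns and covariance do not match")
    W = noise_cov.whitener()
    return PatternSet(
        patterns=pattern_set.patterns @ W,
        conditions=pattern_set.conditions,
        whitened=True,
        meta=dict(pattern_set.meta),
    )


@dataclass
class RDM:
    """Symmetric condition x condition dissimilarity matrix (a.u.).

    Crossnobis values may legitimately be negative; the diagonal is exactly
    zero.
    """

    values: np.ndarray
    conditions: tuple[str, ...]
    estimator: str = "crossnobis"
    meta: dict = field(default_factory=dict)

    def get(self, ci: str, cj: str) -> float:
        i = self.conditions.index(ci)
        j = self.conditions.index(cj)
        return float(self.values[i, j])


def crossnobis_rdm(pattern_set: PatternSet) -> RDM:
    """Cross-validated squared Mahalanobis distances between all condition pairs.

    Expects prewhitened patterns; the estimate averages the pattern-difference
    inner products over all ordered pairs of distinct runs and divides by the
    voxel count.
    """
    B = pattern_set.patterns
    C, M, P = B.shape
    if M < 2:
        raise ValueError(
            "crossnobis needs at least two runs to cross-validate the inner product"
        )
    S = B.sum(axis=1)  # (C, P)
    G_sum = S @ S.T
    G_within = np.einsum("imp,jmp->ij", B, B)
    cross = G_sum - G_within  # sum over m != n of b_im . b_jn
    dc = np.diag(cross)
    d = (dc[:, None] + dc[None, :] - cross - cross.T) / (M * (M - 1) * P)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(values=d, conditions=pattern_set.conditions, meta=dict(pattern_set.meta))


def reduce_rdm(
    rdm: RDM, grouping: Mapping[str, Sequence[tuple[str, str]]]
) -> dict[str, float]:
    """Arithmetic mean of named RDM cells per group.

    Used for the standard reductions: body-part pairs averaged across actions,
    hemisphere averaging, and adjacent / non-adjacent pair classes.
    """
    out: dict[str, float] = {}
    for name, pairs in grouping.items():
        if len(pairs) == 0:
            raise ValueError(f"empty group {name!r}")
        out[name] = float(np.mean([rdm.get(ci, cj) for ci, cj in pairs]))
    return out


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Cell-wise mean of RDMs over the same conditions (e.g. hemispheres)."""
    first = rdms[0]
    for r in rdms[1:]:
        if r.conditions != first.conditions:
            raise ValueError("RDMs must share condition labels")
    vals = np.mean([r.values for r in rdms], axis=0)
    return RDM(values=vals, conditions=first.conditions, meta=dict(first.meta))


class ClassicalMDS(BaseEstimator):
    """Torgerson classical scaling of a squared-distance matrix.

    fit_transform(D) double-centres the (negative-rectified) matrix,
    eigendecomposes, and returns the top ``n_components`` coordinates.
    Dimensions beyond the positive-eigenvalue count are zero-filled with a
    warning; sign indeterminacy is fixed by making the first condition's
    coordinate non-negative on every axis.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit_transform(self, D: np.ndarray, y=None) -> np.ndarray:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        D = np.asarray(D, float).copy()
        if np.any(D < 0):
            warnings.warn("negative dissimilarities rectified to 0 for MDS")
            D[D < 0] = 0.0
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        n_pos = int((w > 1e-12 * max(w.max(), 1.0)).sum())
        k = self.n_components
        if k > n_pos:
            warnings.warn(
                f"only {n_pos} positive eigenvalues; extra dimensions zero-filled"
            )
        coords = np.zeros((n, k))
        kk = min(k, n_pos)
        coords[:, :kk] = V[:, :kk] * np.sqrt(w[:kk])
        for dim in range(kk):
            pivot = coords[:, dim][np.abs(coords[:, dim]) > 0]
            if pivot.size and coords[0, dim] < 0:
                coords[:, dim] *= -1.0
        self.embedding_ = coords
        self.eigenvalues_ = w
        return coords

    def fit(self, D: np.ndarray, y=None) -> "ClassicalMDS":
        self.fit_transform(D)
        return self


def classical_mds(rdm: RDM, n_dims: int = 2) -> np.ndarray:
    """Condition coordinates from classical (Torgerson) scaling of an RDM."""
    return ClassicalMDS(n_components=n_dims).fit_transform(rdm.values)
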