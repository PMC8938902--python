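"""Crossnobis core: shrinkage covariance, prewhitening, distances, MDS."""

import numpy as np
import pytest

from somarsa.glm import build_design, fit_run
from somarsa.rsa import (
    ClassicalMDS,
    NoiseCov,
    PatternSet,
    RDM,
    ShrunkNoiseCovariance,
    average_rdms,
    classical_mds,
    crossnobis_rdm,
    noise_covariance,
    prewhiten,
    reduce_rdm,
)
from somarsa.sheet import NoiseConfig, SomatotopyConfig, build_sheet, true_pattern_distance
from somarsa.simulate import simulate_run
from somarsa.tasks import balanced_sequence


def crossnobis_double_sum(B):
    """Independent oracle: explicit double sum over ordered run pairs."""
    C, M, P = B.shape
    d = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            acc = 0.0
            for m in range(M):
                for n in range(M):
                    if m != n:
                        acc += (B[i, m] - B[j, m]) @ (B[i, n] - B[j, n])
            d[i, j] = acc / (M * (M - 1) * P)
    return d


class TestNoiseCovariance:
    def test_hand_computed_toy_residuals(self):
        """R = ((1,0),(0,1),(-1,0),(0,-1)), dof 4: R'R/4 = diag(0.5, 0.5)."""
        R = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        nc = noise_covariance([R], dofs=[4], lambda_mode=0.0)
        np.testing.assert_allclose(nc.covariance, np.diag([0.5, 0.5]), atol=1e-12)

    def test_full_shrinkage_is_exactly_diagonal(self, rng):
        R = rng.standard_normal((30, 6))
        nc = noise_covariance([R], lambda_mode=1.0)
        off = nc.covariance[~np.eye(6, dtype=bool)]
        assert np.all(off == 0.0)

    def test_white_residuals_large_t(self, rng):
        """Huge-sample white residuals: off-diagonals below 5% of sigma^2."""
        R = 2.0 * rng.standard_normal((50000, 8))
        nc = noise_covariance([R])
        off = np.abs(nc.covariance[~np.eye(8, dtype=bool)])
        assert off.max() <= 0.05 * 4.0
        np.testing.assert_allclose(np.diag(nc.covariance), 4.0, rtol=0.05)

    def test_auto_shrinkage_grows_when_underdetermined(self, rng):
        A = rng.standard_normal((30, 30))
        cov = A @ A.T / 30 + np.eye(30)
        L = np.linalg.cholesky(cov)
        few = ShrunkNoiseCovariance().fit([rng.standard_normal((10, 30)) @ L.T])
        many = ShrunkNoiseCovariance().fit([rng.standard_normal((5000, 30)) @ L.T])
        assert few.shrinkage_ > many.shrinkage_
        assert many.shrinkage_ < 0.2
        assert np.linalg.eigvalsh(few.covariance_).min() > 0

    def test_all_zero_residuals_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            noise_covariance([np.zeros((10, 3))])


class TestPrewhiten:
    def _ps(self, B):
        return PatternSet(B, tuple(f"c{i}" for i in range(B.shape[0])))

    def test_identity_covariance_is_noop(self, rng):
        B = rng.standard_normal((3, 2, 4))
        out = prewhiten(self._ps(B), NoiseCov(np.eye(4), 0.0, 10))
        np.testing.assert_allclose(out.patterns, B)

    def test_diagonal_covariance_scales_voxels(self, rng):
        B = rng.standard_normal((2, 2, 2))
        out = prewhiten(self._ps(B), NoiseCov(np.diag([4.0, 1.0]), 0.0, 10))
        np.testing.assert_allclose(out.patterns[..., 0], B[..., 0] / 2.0)
        np.testing.assert_allclose(out.patterns[..., 1], B[..., 1])

    def test_whitened_residuals_have_identity_covariance(self, rng):
        A = rng.standard_normal((4, 4))
        cov_true = A @ A.T + 0.5 * np.eye(4)
        R = rng.standard_normal((40000, 4)) @ np.linalg.cholesky(cov_true).T
        est = ShrunkNoiseCovariance(shrinkage=0.0).fit([R])
        W = est.whitener_
        emp = W @ (R.T @ R / R.shape[0]) @ W
        np.testing.assert_allclose(emp, np.eye(4), atol=0.05)

    def test_non_positive_definite_rejected(self, rng):
        bad = NoiseCov(np.diag([1.0, -1.0]), 0.0, 10)
        with pytest.raises(np.linalg.LinAlgError):
            prewhiten(self._ps(rng.standard_normal((2, 2, 2))), bad)


class TestCrossnobis:
    def test_identical_conditions_give_exact_zero(self, rng):
        b = rng.standard_normal((3, 5))
        B = np.stack([b, b])
        rdm = crossnobis_rdm(PatternSet(B, ("a", "b")))
        assert rdm.values[0, 1] == 0.0

    def test_hand_computed_two_run_case(self):
        """b_i=(1,0), b_j=(0,1) in both runs: 2 ordered pairs x dot 2 / (2*1*2) = 1."""
        B = np.array([[[1.0, 0.0], [1.0, 0.0]], [[0.0, 1.0], [0.0, 1.0]]])
        rdm = crossnobis_rdm(PatternSet(B, ("i", "j")))
        assert rdm.values[0, 1] == pytest.approx(1.0)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError, match="two runs"):
            crossnobis_rdm(PatternSet(rng.standard_normal((2, 1, 3)), ("a", "b")))

    def test_matches_double_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            C = rng.integers(2, 5)
            M = rng.integers(2, 5)
            P = rng.integers(1, 7)
            B = rng.standard_normal((C, M, P))
            rdm = crossnobis_rdm(PatternSet(B, tuple(f"c{i}" for i in range(C))))
            assert np.abs(rdm.values - crossnobis_double_sum(B)).max() <= 1e-10

    def test_voxel_permutation_equivariance(self, rng):
        B = rng.standard_normal((4, 3, 20))
        perm = rng.permutation(20)
        a = crossnobis_rdm(PatternSet(B, ("a", "b", "c", "d"))).values
        b = crossnobis_rdm(PatternSet(B[:, :, perm], ("a", "b", "c", "d"))).values
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-14)

    def test_symmetry_and_zero_diagonal(self, rng):
        B = rng.standard_normal((5, 4, 8))
        rdm = crossnobis_rdm(PatternSet(B, tuple("abcde")))
        np.testing.assert_array_equal(rdm.values, rdm.values.T)
        assert np.all(np.diag(rdm.values) == 0.0)

    def test_null_distribution_unbiased(self):
        """Identical true patterns + independent run noise: mean d within 3 SE of 0."""
        rng = np.random.default_rng(7)
        d = np.empty(1000)
        for i in range(1000):
            base = rng.standard_normal(20)
            B = base + rng.standard_normal((2, 4, 20))
            d[i] = crossnobis_rdm(PatternSet(B, ("a", "b"))).values[0, 1]
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) <= 3 * se

    def test_signal_recovery_at_vanishing_noise(self, body_set, body_recipe):
        """As noise sd -> 0, crossnobis (whitened with the true covariance)
        converges to the ground-truth whitened squared distance per voxel."""
        cfg = SomatotopyConfig(
            n_voxels=90,
            seed=12,
            noise=NoiseConfig(temporal_ar1=0.0, spatial_mix=0.0, scanner_sd=1e-6),
        )
        sheet = build_sheet(body_set, cfg)
        seqs = balanced_sequence(body_set, body_recipe, seed=4)
        fits = [
            fit_run(simulate_run(sheet, s, body_recipe, seed=r), build_design(
                simulate_run(sheet, s, body_recipe, seed=r), 150.0))
            for r, s in enumerate(seqs)
        ]
        vox = np.arange(30, 60)
        B = np.stack([f.condition_betas(sheet.conditions)[:, vox] for f in fits], axis=1)
        nc = NoiseCov(sheet.true_noise_cov(vox), 0.0, 999)
        rdm = crossnobis_rdm(prewhiten(PatternSet(B, sheet.conditions), nc))
        i, j = 0, 5
        truth = true_pattern_distance(sheet, (sheet.conditions[i], sheet.conditions[j]), vox)
        assert abs(rdm.values[i, j] - truth) / truth <= 1e-6


class TestReduceRDM:
    def _rdm(self):
        conds = ("feet_squeeze", "feet_push", "lips_squeeze", "lips_push")
        v = np.zeros((4, 4))
        v[0, 2] = v[2, 0] = 0.2  # feet-lips squeeze
        v[1, 3] = v[3, 1] = 0.4  # feet-lips push
        return RDM(values=v, conditions=conds)

    def test_body_pair_averaged_across_actions(self):
        rdm = self._rdm()
        out = reduce_rdm(
            rdm,
            {"feet-lips": [("feet_squeeze", "lips_squeeze"), ("feet_push", "lips_push")]},
        )
        assert out["feet-lips"] == pytest.approx(0.3)

    def test_single_cell_group_unchanged(self):
        rdm = self._rdm()
        out = reduce_rdm(rdm, {"one": [("feet_squeeze", "lips_squeeze")]})
        assert out["one"] == pytest.approx(0.2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            reduce_rdm(self._rdm(), {"nothing": []})

    def test_hemisphere_average(self):
        a = self._rdm()
        b = RDM(values=2 * a.values, conditions=a.conditions)
        avg = average_rdms([a, b])
        assert avg.get("feet_squeeze", "lips_squeeze") == pytest.approx(0.3)


class TestClassicalMDS:
    def test_two_conditions_d4_are_two_apart(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        xy = ClassicalMDS(n_components=1).fit_transform(D)
        assert abs(xy[0, 0] - xy[1, 0]) == pytest.approx(2.0)
        assert xy[0, 0] >= 0  # sign convention

    def test_equal_distances_give_equilateral_triangle(self):
        D = np.full((3, 3), 1.0) - np.eye(3)
        xy = ClassicalMDS(n_components=2).fit_transform(D)
        dists = [np.linalg.norm(xy[i] - xy[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert max(dists) - min(dists) <= 1e-8

    def test_negative_cell_rectified_with_warning(self):
        D = np.array([[0.0, -0.01], [-0.01, 0.0]])
        with pytest.warns(UserWarning, match="rectified"):
            xy = ClassicalMDS(n_components=1).fit_transform(D)
        assert np.allclose(xy, 0.0)

    def test_excess_dimensions_zero_filled(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-filled"):
            xy = ClassicalMDS(n_components=3).fit_transform(D)
        assert np.all(xy[:, 1:] == 0.0)

    def test_classical_mds_on_rdm(self):
        rdm = RDM(values=np.array([[0.0, 4.0], [4.0, 0.0]]), conditions=("a", "b"))
        xy = classical_mds(rdm, n_dims=1)
        assert xy.shape == (2, 1)
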