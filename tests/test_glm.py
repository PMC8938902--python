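"""GLM: HRF kernel, design construction, OLS fits, contrasts."""

import numpy as np
import pytest

from somarsa.glm import (
    ContrastSpec,
    RunGLM,
    build_design,
    contrast_stat,
    dct_drift_basis,
    fit_run,
    hrf_double_gamma,
    t_to_z,
)
from somarsa.sheet import NoiseConfig, SomatotopyConfig, build_sheet
from somarsa.simulate import RunData, simulate_run
from somarsa.tasks import balanced_sequence


class TestHRF:
    def test_peak_between_5_and_6_seconds(self):
        dt = 0.01
        k = hrf_double_gamma(dt)
        assert 5.0 <= np.argmax(k) * dt <= 6.0

    def test_starts_at_zero_and_peaks_at_one(self):
        k = hrf_double_gamma(0.1)
        assert k[0] == 0.0
        assert k.max() == pytest.approx(1.0)

    def test_has_undershoot(self):
        k = hrf_double_gamma(0.1)
        assert k.min() < 0

    @pytest.mark.parametrize("kw", [{"dt_s": 0}, {"dt_s": 0.1, "peak_delay_s": -1}])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            hrf_double_gamma(**kw)


def _mini_run(n_vol=60, tr=1.0, sequence=("a", "b", "a", "b")):
    onsets = tuple(5.0 + 12.0 * i for i in range(len(sequence)))
    return RunData(
        timeseries=np.zeros((n_vol, 3)),
        sequence=tuple(sequence),
        onsets_s=onsets,
        durations_s=tuple(8.0 for _ in sequence),
        tr_s=tr,
    )


class TestBuildDesign:
    def test_drift_column_count(self):
        """300 s run, 150 s cutoff: k <= 2*300/150 = 4 cosine columns."""
        drift = dct_drift_basis(300, 1.0, 150.0)
        assert drift.shape[1] == 4

    def test_cutoff_shorter_than_two_tr_rejected(self):
        with pytest.raises(ValueError):
            build_design(_mini_run(), hp_cutoff_s=1.5)

    def test_no_events_gives_drift_and_intercept_only(self):
        run = RunData(
            timeseries=np.zeros((60, 2)), sequence=(), onsets_s=(), durations_s=(), tr_s=1.0
        )
        d = build_design(run, 30.0)
        assert set(d.regressor_kinds) == {"drift", "intercept"}

    def test_condition_and_derivative_regressors_differ(self):
        d = build_design(_mini_run(), 150.0)
        c = d.matrix[:, d.condition_column("a")]
        dv = d.matrix[:, list(d.regressor_labels).index("a_derivative")]
        r = np.corrcoef(c, dv)[0, 1]
        assert abs(r) < 1.0

    def test_events_beyond_run_rejected(self):
        run = _mini_run(n_vol=20)
        with pytest.raises(ValueError):
            build_design(run, 30.0)


class TestRunGLM:
    def test_hand_solved_toy_system(self):
        """X=[[1,0],[0,1],[1,1]], y = X @ (1,2): OLS recovers beta=(1,2)."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = (X @ np.array([1.0, 2.0]))[:, None]
        est = RunGLM().fit(X, y)
        np.testing.assert_allclose(est.coef_.ravel(), [1.0, 2.0], atol=1e-12)

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank-deficient"):
            RunGLM().fit(X, np.zeros((5, 1)))

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 7))
        est = RunGLM().fit(X, Y)
        scale = np.linalg.norm(X) * np.linalg.norm(est.residuals_)
        assert np.abs(X.T @ est.residuals_).max() <= 1e-8 * scale


@pytest.fixture(scope="module")
def noiseless_fit(body_set, body_recipe):
    cfg = SomatotopyConfig(n_voxels=80, seed=3, noise=NoiseConfig(scanner_sd=0.0))
    sheet = build_sheet(body_set, cfg)
    seq = balanced_sequence(body_set, body_recipe, seed=1)[0]
    run = simulate_run(sheet, seq, body_recipe, seed=0)
    design = build_design(run, 150.0)
    return sheet, run, design, fit_run(run, design)


class TestFitRun:
    def test_noiseless_beta_recovery(self, noiseless_fit):
        sheet, run, design, fit = noiseless_fit
        truth = sheet.mean_maps + sheet.distributed_maps
        est = fit.condition_betas(sheet.conditions)
        rel = np.abs(est - truth).max() / np.abs(truth).max()
        assert rel <= 1e-8

    def test_orthogonal_drift_leaves_betas_unchanged(self, noiseless_fit):
        sheet, run, design, fit = noiseless_fit
        refit = fit_run(run, build_design(run, 75.0))  # more drift columns
        np.testing.assert_allclose(
            fit.condition_betas(sheet.conditions),
            refit.condition_betas(sheet.conditions),
            atol=1e-8,
        )

    def test_dof_accounting(self, noiseless_fit):
        _, run, design, fit = noiseless_fit
        assert fit.dof == run.n_volumes - design.matrix.shape[1]


class TestContrasts:
    def test_vs_all_others_weights(self):
        conds = [f"c{i}" for i in range(5)]
        spec = ContrastSpec.vs_all_others("c0", conds)
        assert spec.weights["c0"] == 1.0
        assert all(spec.weights[c] == pytest.approx(-0.25) for c in conds[1:])
        assert sum(spec.weights.values()) == pytest.approx(0.0)

    def test_zero_effect_gives_zero_t_and_z(self, rng):
        X = np.column_stack([rng.standard_normal(30), np.ones(30)])
        Y = rng.standard_normal((30, 4))
        class _D:
            pass
        run = RunData(timeseries=Y, sequence=("a",), onsets_s=(1.0,), durations_s=(5.0,), tr_s=1.0)
        design = build_design(run, 20.0)
        fit = fit_run(run, design)
        fit.betas[design.condition_column("a")] = 0.0
        sm = contrast_stat([fit], ContrastSpec.vs_rest("a"))
        assert np.all(sm.t == 0.0) and np.all(sm.z == 0.0)

    def test_fixed_effects_doubles_t_over_four_identical_runs(self, noiseless_fit, rng):
        sheet, run, design, _ = noiseless_fit
        noisy = RunData(
            timeseries=run.timeseries + rng.standard_normal(run.timeseries.shape),
            sequence=run.sequence,
            onsets_s=run.onsets_s,
            durations_s=run.durations_s,
            tr_s=run.tr_s,
        )
        fit = fit_run(noisy, design)
        c = ContrastSpec.vs_rest(sheet.conditions[0])
        single = contrast_stat([fit], c, mode="run")
        fixed = contrast_stat([fit] * 4, c, mode="fixed_effects")
        np.testing.assert_allclose(fixed.t, 2.0 * single.t, rtol=1e-10)
        np.testing.assert_allclose(fixed.effect, single.effect, rtol=1e-12)

    def test_fixed_effects_of_one_run_is_identity(self, noiseless_fit):
        sheet, _, _, fit = noiseless_fit
        c = ContrastSpec.vs_rest(sheet.conditions[0])
        one = contrast_stat([fit], c, mode="run")
        fx = contrast_stat([fit], c, mode="fixed_effects")
        np.testing.assert_allclose(one.effect, fx.effect)
        np.testing.assert_allclose(one.variance, fx.variance)

    def test_z_clipping(self):
        z, n_clip = t_to_z(np.array([500.0, -500.0, 1.0]), dof=100)
        assert z[0] == 8.2 and z[1] == -8.2
        assert n_clip == 2
        assert 0 < z[2] < 1.2
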