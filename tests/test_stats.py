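"""Inference machinery: gated tests, effect sizes, Bonferroni, rmANOVA."""

import itertools
import json
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from somarsa.stats import (
    SubpartLayout,
    adjacency_pairs,
    bonferroni_alpha,
    cohens_d_ci,
    hemisphere_average,
    one_sample_test,
    paired_test,
    rm_anova_gg,
    univariate_content,
    univariate_level,
)


class TestAdjacency:
    @pytest.mark.parametrize(
        "subparts,n_adj,n_nonadj",
        [
            (("D1", "D2", "D3", "D4", "D5"), 4, 6),
            (("forehead", "nose", "lips", "tongue"), 3, 3),
            (("a", "b", "c"), 2, 1),
        ],
    )
    def test_pair_counts(self, subparts, n_adj, n_nonadj):
        adj, nonadj = adjacency_pairs(subparts)
        assert len(adj) == n_adj and len(nonadj) == n_nonadj
        assert set(adj).isdisjoint(nonadj)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            adjacency_pairs(("a", "b"))


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,reported", [(3, 0.017), (4, 0.013), (5, 0.010), (1, 0.05)]
    )
    def test_reported_alphas(self, m, reported):
        raw, rep = bonferroni_alpha(0.05, m)
        assert rep == reported
        assert raw == pytest.approx(0.05 / m)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestOneSample:
    def test_closed_form_example(self):
        """values (1..5): t = mean/(sd/sqrt(5)) = 4.2426, d = mean/sd = 1.8974."""
        res = one_sample_test([1, 2, 3, 4, 5], "two-sided", 0.05)
        assert res.statistic == pytest.approx(4.2426, abs=1e-4)
        assert res.d == pytest.approx(1.8974, abs=1e-4)
        assert res.test_used == "t"

    def test_all_zero_is_degenerate_without_decision(self):
        res = one_sample_test([0.0, 0.0, 0.0, 0.0], "two-sided", 0.05)
        assert res.degenerate and not res.significant and not res.trend

    def test_one_tailed_against_negative_mean(self, rng):
        res = one_sample_test(-1.0 + 0.1 * rng.standard_normal(20), "greater", 0.05)
        assert res.p > 0.5

    def test_normality_gate_routes_to_wilcoxon(self, rng):
        x = np.concatenate([rng.standard_normal(15), [40.0, 55.0]])
        res = one_sample_test(x, "two-sided", 0.05)
        assert res.shapiro_p < 0.05
        assert res.test_used == "wilcoxon"

    def test_flags_consistent_with_p_and_alpha(self, rng):
        for _ in range(50):
            res = one_sample_test(rng.standard_normal(12), "two-sided", 0.3)
            assert res.significant == (res.p < res.alpha_corrected)
            assert res.trend == (res.alpha_corrected <= res.p < 2 * res.alpha_corrected)


class TestPaired:
    def test_reduces_to_one_sample_on_differences(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        pa = paired_test(a, b, "two-sided", 0.05)
        os = one_sample_test(a - b, "two-sided", 0.05)
        assert pa.statistic == os.statistic and pa.p == os.p

    def test_worked_difference_example(self):
        b = np.zeros(5)
        res = paired_test([1, 2, 3, 4, 5], b, "two-sided", 0.05)
        assert res.statistic == pytest.approx(4.2426, abs=1e-4)

    def test_identical_samples_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_test(a, a, "two-sided", 0.05)
        assert res.degenerate and not res.significant

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], "two-sided", 0.05)
        assert res.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_test([1, 2, 3], [1, 2], "two-sided", 0.05)


class TestCohensDCI:
    def test_ci_inverts_noncentral_t(self):
        t, n = 4.2426, 5
        lo, hi = cohens_d_ci(t, n, "two-sided")
        assert sps.nct.cdf(t, n - 1, lo * np.sqrt(n)) == pytest.approx(0.975, abs=1e-6)
        assert sps.nct.cdf(t, n - 1, hi * np.sqrt(n)) == pytest.approx(0.025, abs=1e-6)
        assert lo < t / np.sqrt(n) < hi

    def test_one_tailed_bound_is_one_sided(self):
        lo, hi = cohens_d_ci(3.0, 10, "greater")
        assert np.isinf(hi) and np.isfinite(lo)


@pytest.fixture(scope="module")
def r_results():
        rng = np.random.default_rng(11)
        vectors = [np.round(rng.standard_normal(12) + 0.4, 6) for _ in range(4)]
        rcode = """
        suppressWarnings({
        vs <- list(%s)
        out <- lapply(vs, function(x) {
          t <- t.test(x)
          w <- wilcox.test(x, exact=TRUE)
          s <- shapiro.test(x)
          list(t=t$statistic[[1]], tp=t$p.value, w=w$statistic[[1]], wp=w$p.value, sp=s$p.value)
        })
        cat(jsonlite::toJSON(out, auto_unbox=TRUE, digits=12))
        })
        """ % ",".join("c(" + ",".join(map(str, v)) + ")" for v in vectors)
        try:
            res = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        if res.returncode != 0:
            pytest.skip(f"Rscript failed: {res.stderr[:200]}")
        return vectors, json.loads(res.stdout)


def test_t_wilcoxon_shapiro_match_r_reference(r_results):
    """scipy-backed machinery agrees with R's t.test/wilcox.test/shapiro.test."""
    vectors, ref = r_results
    for x, r in zip(vectors, ref):
        t = sps.ttest_1samp(x, 0.0)
        assert t.statistic == pytest.approx(r["t"], abs=1e-6)
        assert t.pvalue == pytest.approx(r["tp"], abs=1e-6)
        w = sps.wilcoxon(x, method="exact")
        assert w.pvalue == pytest.approx(r["wp"], abs=1e-6)
        assert sps.shapiro(x).pvalue == pytest.approx(r["sp"], abs=1e-4)


def _brute_force_rm_anova(data):
    """Independent oracle: inclusion-exclusion sums of squares from cell totals."""
    n = data.shape[0]
    levels = data.shape[1:]
    k = len(levels)
    N = data.size
    axes = {"s": 0, **{i: i + 1 for i in range(k)}}

    def U(margin):
        keep = tuple(sorted(axes[m] for m in margin))
        drop = tuple(a for a in range(data.ndim) if a not in keep)
        totals = data.sum(axis=drop) if drop else data
        per_cell = N / np.prod([data.shape[a] for a in keep]) if keep else N
        return float((np.asarray(totals) ** 2).sum() / per_cell)

    def ss(effect):
        total = 0.0
        for r in range(len(effect) + 1):
            for sub in itertools.combinations(effect, r):
                total += (-1) ** (len(effect) - len(sub)) * U(sub)
        return total

    out = {}
    for r in range(1, k + 1):
        for eff in itertools.combinations(range(k), r):
            ss_eff = ss(eff)
            ss_err = ss(tuple(eff) + ("s",))
            df1 = int(np.prod([levels[i] - 1 for i in eff]))
            df2 = df1 * (n - 1)
            F = (ss_eff / df1) / (ss_err / df2)
            out["*".join(f"F{i + 1}" for i in eff)] = (ss_eff, ss_err, df1, df2, F)
    return out


class TestRmAnovaGG:
    def test_matches_brute_force_oracle_on_toy_table(self, rng):
        """4-subject 2x2x2 table: SS and F equal the direct cell-total oracle."""
        data = rng.standard_normal((4, 2, 2, 2)) + rng.standard_normal((4, 1, 1, 1))
        table = rm_anova_gg(data)
        oracle = _brute_force_rm_anova(data)
        for name, (ss_eff, ss_err, df1, df2, F) in oracle.items():
            eff = table[name]
            assert eff.ss == pytest.approx(ss_eff, abs=1e-8)
            assert eff.ss_error == pytest.approx(ss_err, abs=1e-8)
            assert (eff.df, eff.df_error) == (df1, df2)
            assert eff.F == pytest.approx(F, abs=1e-8)

    def test_matches_oracle_with_three_levels(self, rng):
        data = rng.standard_normal((6, 3, 2))
        table = rm_anova_gg(data)
        oracle = _brute_force_rm_anova(data)
        for name, (_, _, _, _, F) in oracle.items():
            assert table[name].F == pytest.approx(F, abs=1e-8)

    def test_matches_statsmodels_anovarm(self, rng):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        data = rng.standard_normal((8, 2, 3, 2))
        rows = []
        for s in range(8):
            for a in range(2):
                for b in range(3):
                    for c in range(2):
                        rows.append({"subject": s, "A": a, "B": b, "D": c, "y": data[s, a, b, c]})
        ref = AnovaRM(pd.DataFrame(rows), "y", "subject", within=["A", "B", "D"]).fit()
        table = rm_anova_gg(data, factor_names=["A", "B", "D"])
        name_map = {"A": "A", "B": "B", "D": "D", "A:B": "A*B", "A:D": "A*D",
                    "B:D": "B*D", "A:B:D": "A*B*D"}
        for rname, mine in name_map.items():
            F_ref = float(ref.anova_table.loc[rname, "F Value"])
            assert table[mine].F == pytest.approx(F_ref, rel=1e-8)

    def test_two_level_effect_has_epsilon_one(self, rng):
        table = rm_anova_gg(rng.standard_normal((6, 2, 2)))
        for eff in table.effects.values():
            assert eff.epsilon_gg == 1.0
            assert eff.p_gg == eff.p_uncorrected

    def test_epsilon_bounds(self, rng):
        table = rm_anova_gg(rng.standard_normal((8, 4)))
        eff = table["F1"]
        assert 1.0 / 3 <= eff.epsilon_gg <= 1.0

    def test_epsilon_matches_pingouin_for_main_effect(self, rng):
        import pandas as pd

        pg = pytest.importorskip("pingouin")
        data = rng.standard_normal((10, 4))
        eps_ref = float(pg.epsilon(pd.DataFrame(data), correction="gg"))
        table = rm_anova_gg(data)
        assert table["F1"].epsilon_gg == pytest.approx(eps_ref, abs=1e-10)

    def test_missing_cells_rejected(self, rng):
        data = rng.standard_normal((4, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(data)

    def test_null_type_one_rate(self):
        """Pure subject noise: GG-corrected main effect rejects at ~5%."""
        rng = np.random.default_rng(3)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            data = rng.standard_normal((10, 3, 2)) + rng.standard_normal((10, 1, 1))
            hits += int(rm_anova_gg(data)["F1"].p_gg < 0.05)
        assert abs(hits / n_sims - 0.05) <= 0.02


class TestHemisphereAverage:
    def test_simple_mean(self):
        vals = {"L": np.full((5, 2, 2), 0.2), "R": np.full((5, 2, 2), 0.4)}
        avg, gate = hemisphere_average(vals)
        assert np.allclose(avg, 0.3)

    def test_identical_hemispheres_report_no_effect(self, rng):
        x = rng.standard_normal((8, 2, 2))
        avg, gate = hemisphere_average({"L": x, "R": x.copy()})
        assert not gate.any_significant

    def test_injected_offset_flags_hemisphere_effect(self, rng):
        x = rng.standard_normal((12, 2, 2))
        avg, gate = hemisphere_average({"L": x, "R": x + 3.0})
        assert gate.any_significant
        assert any("hemisphere" == k for k in gate.hemisphere_effects)

    def test_single_hemisphere_passthrough(self, rng):
        x = rng.standard_normal((5, 2))
        avg, gate = hemisphere_average({"L": x})
        np.testing.assert_array_equal(avg, x)
        assert "passthrough" in gate.note


class TestUnivariate:
    def test_level_is_mean_z(self):
        assert univariate_level(np.array([1.0, 2.0, 3.0]), [0, 1, 2]) == 2.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            univariate_level(np.ones(5), [])

    def test_content_absolute_difference(self):
        assert univariate_content({"a": 3.0, "b": 1.0}, [("a", "b")]) == 2.0

    def test_content_averages_across_pairs(self):
        levels = {"fs": 3.0, "ls": 1.0, "fp": 5.0, "lp": 1.0}
        out = univariate_content(levels, [("fs", "ls"), ("fp", "lp")])
        assert out == 3.0  # mean of |2| and |4|

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            univariate_content({"a": 1.0}, [("a", "zz")])
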