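"""Group-level inference: tests, effect sizes, adjacency grouping, rmANOVA.

One-sample and paired comparisons follow a gated decision policy: a
Shapiro-Wilk normality gate (p < 0.05) routes to a Wilcoxon signed-rank test
instead of the t-test; alphas are Bonferroni-corrected per family (reported
rounded to 3 decimals, decisions taken on the raw value); "trend" flags
p-values below twice the corrected alpha. Cohen's d is mean/sd with a
confidence interval from noncentral-t inversion.

The repeated-measures ANOVA handles fully-within factorial designs of any
order with Greenhouse-Geisser sphericity correction, used here as the gate
for averaging across hemispheres.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SubpartLayout",
    "adjacency_pairs",
    "TestResult",
    "one_sample_test",
    "paired_test",
    "bonferroni_alpha",
    "AnovaTable",
    "rm_anova_gg",
    "hemisphere_average",
    "univariate_level",
    "univariate_content",
    "cohens_d_ci",
]


@dataclass(frozen=True)
class SubpartLayout:
    """Ordered subparts with derived adjacent / non-adjacent pair classes."""

    subparts: tuple[str, ...]

    @property
    def adjacent(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.subparts[:-1], self.subparts[1:]))

    @property
    def non_adjacent(self) -> tuple[tuple[str, str], ...]:
        adj = set(self.adjacent)
        allp = itertools.combinations(self.subparts, 2)
        return tuple(p for p in allp if p not in adj)


def adjacency_pairs(layout: SubpartLayout | Sequence[str]) -> tuple[tuple, tuple]:
    """Adjacent (consecutive) and non-adjacent pair sets of a subpart order."""
    if not isinstance(layout, SubpartLayout):
        layout = SubpartLayout(tuple(layout))
    if len(layout.subparts) < 3:
        raise ValueError(
            "adjacency grouping needs >= 3 subparts (no non-adjacent class otherwise)"
        )
    return layout.adjacent, layout.non_adjacent


def bonferroni_alpha(family_alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni-corrected alpha: (raw value, 3-decimal reporting value)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    raw = family_alpha / m
    return raw, round(raw, 3)


@dataclass
class TestResult:
    """Outcome of one one-sample or paired comparison."""

    statistic: float
    p: float
    tail: str
    n: int
    d: float
    d_ci: tuple[float, float]
    alpha_corrected: float
    test_used: str  # t | wilcoxon
    significant: bool
    trend: bool
    degenerate: bool = False
    shapiro_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.degenerate:
            return
        assert self.significant == (self.p < self.alpha_corrected)
        assert self.trend == (self.alpha_corrected <= self.p < 2 * self.alpha_corrected)


def cohens_d_ci(
    t_stat: float, n: int, tail: str = "two-sided", conf: float = 0.95
) -> tuple[float, float]:
    """CI for Cohen's d via noncentral-t inversion (d = ncp / sqrt(n)).

    Two-sided tails give a central CI; one-sided gives a lower (greater) or
    upper (less) bound with the other side infinite, matching the usual
    "[x, inf]" style for one-tailed dissimilarity tests.
    """
    df = n - 1
    sqn = np.sqrt(n)

    def ncp_for(prob: float) -> float:
        # ncp such that P(T_{df,ncp} > t_stat) = prob  (cdf decreasing in ncp)
        def f(nc: float) -> float:
            return stats.nct.cdf(t_stat, df, nc) - (1.0 - prob)

        lo, hi = t_stat - 50 - 10 * abs(t_stat), t_stat + 50 + 10 * abs(t_stat)
        try:
            return optimize.brentq(f, lo, hi, xtol=1e-10)
        except ValueError:
            return np.inf if f(lo) < 0 else -np.inf

    if tail == "two-sided":
        a = (1 - conf) / 2
        return ncp_for(a) / sqn, ncp_for(1 - a) / sqn
    if tail == "greater":
        return ncp_for(1 - conf) / sqn, np.inf
    if tail == "less":
        return -np.inf, ncp_for(conf) / sqn
    raise ValueError(f"unknown tail {tail!r}")


def _wilcoxon(values: np.ndarray, tail: str) -> tuple[float, float]:
    n = values.size
    has_zero_or_tie = np.any(values == 0) or (
        np.unique(np.abs(values[values != 0])).size < np.count_nonzero(values)
    )
    method = "exact" if (n <= 25 and not has_zero_or_tie) else "approx"
    res = stats.wilcoxon(
        values, alternative=tail, method=method, correction=(method == "approx")
    )
    return float(res.statistic), float(res.pvalue)


def one_sample_test(
    values: Sequence[float],
    tail: str = "two-sided",
    alpha_corrected: float = 0.05,
) -> TestResult:
    """One-sample comparison against zero with the gated decision policy.

    Shapiro-Wilk at p < 0.05 routes to the Wilcoxon signed-rank test, else a
    one-sample t-test; tails: 'two-sided' | 'greater' | 'less'.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    if sd == 0.0:
        return TestResult(
            statistic=np.nan, p=np.nan, tail=tail, n=n, d=np.nan,
            d_ci=(np.nan, np.nan), alpha_corrected=alpha_corrected,
            test_used="t", significant=False, trend=False, degenerate=True,
        )
    sw_p = float(stats.shapiro(x).pvalue)
    d = mean / sd
    t_stat = mean / (sd / np.sqrt(n))
    if sw_p < 0.05:
        statistic, p = _wilcoxon(x, tail)
        test_used = "wilcoxon"
    else:
        res = stats.ttest_1samp(x, 0.0, alternative=tail)
        statistic, p = float(res.statistic), float(res.pvalue)
        test_used = "t"
    ci = cohens_d_ci(t_stat, n, tail)
    return TestResult(
        statistic=statistic,
        p=p,
        tail=tail,
        n=n,
        d=d,
        d_ci=ci,
        alpha_corrected=alpha_corrected,
        test_used=test_used,
        significant=bool(p < alpha_corrected),
        trend=bool(alpha_corrected <= p < 2 * alpha_corrected),
        shapiro_p=sw_p,
    )


def paired_test(
    a: Sequence[float],
    b: Sequence[float],
    tail: str = "two-sided",
    alpha_corrected: float = 0.05,
) -> TestResult:
    """Paired comparison as a one-sample test on the differences a - b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return one_sample_test(a - b, tail=tail, alpha_corrected=alpha_corrected)


def univariate_level(stat_map, roi: Sequence[int]) -> float:
    """Mean z over ROI voxels — the classical activation measure."""
    idx = np.asarray(roi, dtype=int)
    if idx.size == 0:
        raise ValueError("empty ROI")
    z = stat_map.z if hasattr(stat_map, "z") else np.asarray(stat_map, float)
    return float(np.mean(z[idx]))


def univariate_content(
    levels: Mapping[str, float],
    pairs: Sequence[tuple[str, str]],
) -> float:
    """Univariate information content: |level_i - level_j| averaged over pairs.

    For the body task pass the two same-action pairs of a body-part pair (the
    absolute differences are averaged across actions); for subpart analyses
    pass an adjacency class.
    """
    vals = []
    for ci, cj in pairs:
        if ci not in levels or cj not in levels:
            raise KeyError(f"unknown labels in pair ({ci}, {cj})")
        vals.append(abs(levels[ci] - levels[cj]))
    return float(np.mean(vals))


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    ss_error: float
    df_error: int
    F: float
    p_uncorrected: float
    epsilon_gg: float
    p_gg: float


@dataclass
class AnovaTable:
    effects: dict[str, AnovaEffect]

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


def _normalized_helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows, orthogonal to the unit vector."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def rm_anova_gg(data: np.ndarray, factor_names: Sequence[str] | None = None) -> AnovaTable:
    """Fully-within repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` has shape (n_subjects, l1, ..., lk) for k within-subject
    factors; all cells must be present (no imputation). For every main
    effect and interaction the error term is its interaction with subjects;
    epsilon is computed from the covariance of the effect's orthonormal
    contrast scores and applied to both dfs. Two-level effects have
    epsilon = 1 exactly.
    """
    data = np.asarray(data, float)
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    n = data.shape[0]
    levels = data.shape[1:]
    k = len(levels)
    if n < 2 or k < 1 or any(l < 2 for l in levels):
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    names = list(factor_names) if factor_names else [f"F{i + 1}" for i in range(k)]
    Y = data.reshape(n, -1)

    # orthonormal per-factor contrast and mean rows
    contrasts = [_normalized_helmert(l) for l in levels]
    means = [np.full((1, l), 1.0 / np.sqrt(l)) for l in levels]

    effects: dict[str, AnovaEffect] = {}
    for effect in itertools.chain.from_iterable(
        itertools.combinations(range(k), r) for r in range(1, k + 1)
    ):
        mats = [contrasts[i] if i in effect else means[i] for i in range(k)]
        C = mats[0]
        for M in mats[1:]:
            C = np.kron(C, M)
        scores = Y @ C.T  # n x d effect scores
        d = scores.shape[1]
        zbar = scores.mean(axis=0)
        ss_effect = float(n * (zbar**2).sum())
        ss_error = float(((scores - zbar) ** 2).sum())
        df1, df2 = d, d * (n - 1)
        if ss_error == 0.0:
            # perfectly consistent effect across subjects (degenerate error)
            F = np.inf if ss_effect > 0 else 0.0
            p_unc = 0.0 if ss_effect > 0 else 1.0
        else:
            F = (ss_effect / df1) / (ss_error / df2)
            p_unc = float(stats.f.sf(F, df1, df2))
        if d == 1 or ss_error == 0.0:
            eps = 1.0
        else:
            S = np.cov(scores, rowvar=False)
            eps = float(np.trace(S) ** 2 / (d * (S * S).sum()))
            eps = min(max(eps, 1.0 / d), 1.0)
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps)) if eps < 1 else p_unc
        name = "*".join(names[i] for i in effect)
        effects[name] = AnovaEffect(
            name=name, ss=ss_effect, df=df1, ss_error=ss_error, df_error=df2,
            F=F, p_uncorrected=p_unc, epsilon_gg=eps, p_gg=p_gg,
        )
    return AnovaTable(effects=effects)


@dataclass
class HemisphereGate:
    """Outcome of the hemisphere-effect check preceding averaging."""

    anova: AnovaTable | None
    hemisphere_effects: dict[str, tuple[float, float]]  # effect -> (F, p_gg)
    any_significant: bool
    note: str = ""


def hemisphere_average(
    values_by_hemisphere: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    factor_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, HemisphereGate]:
    """Average subject data across hemispheres, gated by an rmANOVA check.

    ``values_by_hemisphere`` maps hemisphere name to arrays of shape
    (n_subjects, ...); the hemisphere factor and any remaining axes enter a
    fully-within ANOVA whose hemisphere main effect and interactions are
    recorded. Averaging proceeds regardless, with the gate outcome reported
    (the intended regime is one without major hemisphere differences).
    """
    hemis = list(values_by_hemisphere)
    arrays = [np.asarray(values_by_hemisphere[h], float) for h in hemis]
    if len(hemis) == 1:
        gate = HemisphereGate(None, {}, False, note="single hemisphere: passthrough")
        return arrays[0], gate
    stacked = np.stack(arrays, axis=1)  # n x hemi x ...
    names = ["hemisphere"] + (
        list(factor_names) if factor_names else [f"F{i + 1}" for i in range(stacked.ndim - 2)]
    )
    table = rm_anova_gg(stacked, factor_names=names)
    hemi_effects = {
        name: (eff.F, eff.p_gg)
        for name, eff in table.effects.items()
        if "hemisphere" in name.split("*")
    }
    any_sig = any(p < alpha for _, p in hemi_effects.values())
    if any_sig:
        logger.warning("hemisphere effect detected (p < %.3f); averaging anyway", alpha)
    gate = HemisphereGate(table, hemi_effects, any_sig)
    return stacked.mean(axis=1), gate
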