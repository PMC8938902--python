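"""Replication checks: does the default pipeline reproduce the target pattern?

These functions run the full simulate -> GLM -> RSA -> stats pipeline under
the default experimental conditions (22-subject body cohorts, 19-subject finger
cohorts) and score the qualitative result pattern:

* primary-only univariate selectivity with above-zero crossnobis
  dissimilarities for non-primary body-part pairs, abolished when the
  distributed signal amplitude is set to zero;
* adjacent < non-adjacent dissimilarity (topographic gradient) in primary
  and non-primary ROIs;

plus calibration checks of the estimator itself (null unbiasedness, type-I
rate of the testing machinery).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .analysis import analyze_cohort, body_group_stats, subpart_group_stats
from .rsa import PatternSet, crossnobis_rdm
from .sheet import SomatotopyConfig
from .simulate import simulate_cohort
from .stats import one_sample_test
from .tasks import DEFAULT_RECIPES

__all__ = [
    "headline_pattern_replicates",
    "adjacency_power",
    "crossnobis_null",
    "one_sample_type1_rate",
]


def _spawned_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class HeadlineReplicate:
    primary_selective: bool
    nonprimary_not_significant: bool
    nonprimary_dissimilar: bool
    control_abolished: bool

    @property
    def holds(self) -> bool:
        return (
            self.primary_selective
            and self.nonprimary_not_significant
            and self.nonprimary_dissimilar
            and self.control_abolished
        )


def _body_replicate(seed: int, n_subjects: int, config: SomatotopyConfig) -> HeadlineReplicate:
    cohort = simulate_cohort("body", n_subjects, config, seed=seed)
    g = body_group_stats(analyze_cohort(cohort))
    uni = g.univariate_tests
    dis = g.dissimilarity_tests
    primary_ok = bool(uni[uni["primary"]]["significant"].all())
    nonprimary_ok = bool(~uni[~uni["primary"]]["significant"].any())
    nonprim_dis = dis[~dis["involves_primary"]]
    dis_ok = bool(nonprim_dis["significant"].all())

    control_cfg = dataclasses.replace(config, distributed_amplitude=0.0, action_amplitude=0.0)
    ctrl = simulate_cohort("body", n_subjects, control_cfg, seed=seed)
    gc = body_group_stats(analyze_cohort(ctrl))
    ctrl_dis = gc.dissimilarity_tests
    ctrl_nonprim = ctrl_dis[~ctrl_dis["involves_primary"]]
    abolished = not bool(ctrl_nonprim["significant"].all())
    return HeadlineReplicate(primary_ok, nonprimary_ok, dis_ok, abolished)


def headline_pattern_replicates(
    n_replicates: int = 20,
    seed: int = 0,
    n_subjects: int = 22,
    config: SomatotopyConfig | None = None,
) -> dict:
    """Score the headline pattern over replicate default body-task cohorts.

    Each replicate simulates an independent 22-subject cohort plus its
    zero-distributed-signal control and checks: (i) primary body parts
    univariately significant and non-primary not (two-tailed, alpha 0.05/3);
    (ii) all non-primary body-part dissimilarities above zero (one-tailed,
    same alpha); (iii) the control abolishes (ii).
    """
    cfg = config or SomatotopyConfig()
    reps = [
        _body_replicate(s, n_subjects, cfg)
        for s in _spawned_seeds(seed, n_replicates)
    ]
    return {
        "n_replicates": n_replicates,
        "n_holds": sum(r.holds for r in reps),
        "n_primary_selective": sum(r.primary_selective for r in reps),
        "n_nonprimary_not_significant": sum(r.nonprimary_not_significant for r in reps),
        "n_nonprimary_dissimilar": sum(r.nonprimary_dissimilar for r in reps),
        "n_control_abolished": sum(r.control_abolished for r in reps),
        "replicates": reps,
    }


def adjacency_power(
    n_replicates: int = 50,
    seed: int = 0,
    n_subjects: int = 19,
    config: SomatotopyConfig | None = None,
) -> dict:
    """Power of the adjacent < non-adjacent paired test over finger cohorts.

    A replicate counts as a detection in a ROI when the paired test is
    significant with non-adjacent dissimilarity exceeding adjacent.
    """
    cfg = config or SomatotopyConfig()
    primary_hits = 0
    nonprimary_hits = 0
    per_roi = {"leg": 0, "hand": 0, "face": 0}
    for s in _spawned_seeds(seed, n_replicates):
        cohort = simulate_cohort("finger", n_subjects, cfg, seed=s)
        g = subpart_group_stats(analyze_cohort(cohort))
        hit = {}
        for _, row in g.paired_tests.iterrows():
            hit[row["region"]] = bool(row["significant"] and row["mean_difference"] > 0)
            per_roi[row["region"]] += int(hit[row["region"]])
        primary_hits += int(hit["hand"])
        nonprimary_hits += int(hit["leg"] or hit["face"])
    return {
        "n_replicates": n_replicates,
        "power_primary": primary_hits / n_replicates,
        "power_any_nonprimary": nonprimary_hits / n_replicates,
        "power_per_roi": {k: v / n_replicates for k, v in per_roi.items()},
    }


def crossnobis_null(
    n_subjects: int = 1000,
    n_runs: int = 4,
    n_voxels: int = 50,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> dict:
    """Monte-Carlo null of the crossnobis estimator (identical true patterns).

    Each simulated subject shares one true pattern across two conditions;
    run-wise estimates add independent noise. Returns the mean distance, its
    standard error and the mean/SE ratio (expected |ratio| < 3).
    """
    rng = np.random.default_rng(seed)
    d = np.empty(n_subjects)
    for i in range(n_subjects):
        base = rng.standard_normal(n_voxels)
        B = base + noise_sd * rng.standard_normal((2, n_runs, n_voxels))
        rdm = crossnobis_rdm(PatternSet(B, ("a", "b"), whitened=True))
        d[i] = rdm.values[0, 1]
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n_subjects))
    return {"mean": mean, "se": se, "mean_over_se": mean / se, "n": n_subjects}


def one_sample_type1_rate(
    n_draws: int = 10000,
    n: int = 22,
    alpha: float = 0.05 / 3,
    seed: int = 0,
) -> dict:
    """Empirical type-I rate of the gated one-sample test on Gaussian nulls."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        res = one_sample_test(rng.standard_normal(n), "two-sided", alpha)
        hits += int(res.significant)
    return {"rate": hits / n_draws, "n_draws": n_draws, "alpha": alpha}
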