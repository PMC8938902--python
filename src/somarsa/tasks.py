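"""Task definitions and block-design sequencing.

Three sensorimotor block-design tasks drive the analyses:

* ``body``   — 3 body parts (feet, hand, lips) x 2 actions (squeeze, push),
  6 conditions, 8 s blocks, 4 runs.
* ``face``   — 4 face subparts (forehead, nose, lips, tongue), 8 s blocks,
  3 runs.
* ``finger`` — 5 digits (D1..D5), 9 s blocks, 4 runs.

A separate body-part localizer (toes / hand / lips, 12 s blocks) is used to
define selectivity-based regions of interest; it is not one of the three
analysis tasks and has its own constructor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TASK_IDS = ("body", "face", "finger")

BODY_PARTS = ("feet", "hand", "lips")
ACTIONS = ("squeeze", "push")
FACE_SUBPARTS = ("forehead", "nose", "lips", "tongue")
FINGERS = ("D1", "D2", "D3", "D4", "D5")
LOCALIZER_CONDITIONS = ("toes", "hand", "lips")


class UnknownTaskError(ValueError):
    """Raised for a task identifier outside {body, face, finger}."""


@dataclass(frozen=True)
class ConditionSet:
    """Ordered conditions of a task plus the cortical subpart layout.

    ``subpart_order`` lists the subparts in their medio-lateral cortical
    order; consecutive entries are "adjacent" for topographic analyses.
    For the body task each condition maps to a (body_part, action) pair via
    ``action_factor``.
    """

    task_id: str
    conditions: tuple[str, ...]
    subpart_order: tuple[str, ...]
    action_factor: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def part_of(self, condition: str) -> str:
        """Subpart (body part / face part / digit) a condition belongs to."""
        if self.action_factor is not None:
            return self.action_factor[condition][0]
        return condition

    def action_of(self, condition: str) -> str | None:
        if self.action_factor is None:
            return None
        return self.action_factor[condition][1]

    def conditions_of_part(self, part: str) -> list[str]:
        return [c for c in self.conditions if self.part_of(c) == part]


def make_task(task_id: str) -> ConditionSet:
    """Canonical condition set of one of the three analysis tasks."""
    if task_id == "body":
        conditions = tuple(f"{p}_{a}" for p in BODY_PARTS for a in ACTIONS)
        factor = {f"{p}_{a}": (p, a) for p in BODY_PARTS for a in ACTIONS}
        return ConditionSet("body", conditions, BODY_PARTS, factor)
    if task_id == "face":
        return ConditionSet("face", FACE_SUBPARTS, FACE_SUBPARTS)
    if task_id == "finger":
        return ConditionSet("finger", FINGERS, FINGERS)
    raise UnknownTaskError(
        f"unknown task_id {task_id!r}; expected one of {TASK_IDS}"
    )


def localizer_conditions() -> ConditionSet:
    """Body-part localizer used for ROI definition (toes, hand, lips)."""
    return ConditionSet("localizer", LOCALIZER_CONDITIONS, LOCALIZER_CONDITIONS)


@dataclass(frozen=True)
class SessionRecipe:
    """Timing of a block-design scanning session."""

    tr_s: float = 1.45
    block_s: float = 8.0
    blocks_per_condition_per_run: int = 4
    rest_blocks_per_run: int = 5
    n_runs: int = 4
    n_volumes_per_run: int = 216

    def __post_init__(self) -> None:
        for name in (
            "blocks_per_condition_per_run",
            "n_runs",
            "n_volumes_per_run",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rest_blocks_per_run < 0:
            raise ValueError("rest_blocks_per_run must be non-negative")
        if self.tr_s <= 0 or self.block_s <= 0:
            raise ValueError("tr_s and block_s must be positive")

    def n_blocks(self, n_conditions: int) -> int:
        return n_conditions * self.blocks_per_condition_per_run + self.rest_blocks_per_run

    def run_duration_s(self) -> float:
        return self.n_volumes_per_run * self.tr_s

    def validate_for(self, n_conditions: int) -> None:
        total_block_s = self.n_blocks(n_conditions) * self.block_s
        if self.n_volumes_per_run < math.ceil(total_block_s / self.tr_s):
            raise ValueError(
                f"n_volumes_per_run={self.n_volumes_per_run} cannot hold "
                f"{total_block_s:.1f}s of blocks at TR={self.tr_s}s"
            )


#: Study timing per task: TR 1.45 s throughout; body/face use 8 s blocks with
#: 4 blocks/condition/run and 5 rest blocks; fingers use 9 s blocks; run
#: volume counts 216 (body), 172 (face), 346 (finger); 4 runs except the
#: 3-run face session. Localizer: 12 s blocks, 4 repeats, rest interleaved.
DEFAULT_RECIPES: dict[str, SessionRecipe] = {
    "body": SessionRecipe(tr_s=1.45, block_s=8.0, n_runs=4, n_volumes_per_run=216),
    "face": SessionRecipe(tr_s=1.45, block_s=8.0, n_runs=3, n_volumes_per_run=172),
    "finger": SessionRecipe(tr_s=1.45, block_s=9.0, n_runs=4, n_volumes_per_run=346),
    "localizer": SessionRecipe(
        tr_s=1.45,
        block_s=12.0,
        blocks_per_condition_per_run=4,
        rest_blocks_per_run=0,
        n_runs=1,
        n_volumes_per_run=213,
    ),
}

#: High-pass cutoffs (s) used in the GLM drift model, per task.
DEFAULT_HP_CUTOFF_S: dict[str, float] = {
    "body": 150.0,
    "face": 119.0,
    "finger": 150.0,
    "localizer": 280.0,
}


def _transition_counts(runs: Sequence[Sequence[str]], labels: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for seq in runs:
        for a, b in zip(seq[:-1], seq[1:]):
            counts[idx[a], idx[b]] += 1
    return counts


def balanced_sequence(
    condition_set: ConditionSet,
    recipe: SessionRecipe,
    seed: int,
    max_restarts: int = 2000,
) -> list[list[str]]:
    """Per-run block orders with first-order counterbalancing.

    Every condition appears exactly ``blocks_per_condition_per_run`` times in
    each run, no condition immediately repeats, and over the whole session the
    ordered transition counts c_i -> c_j (i != j) differ by at most one — the
    "each condition equally preceded by all other conditions" constraint.
    Built by a seeded greedy packer with restarts; deterministic given seed.
    """
    labels = list(condition_set.conditions)
    k = len(labels)
    reps = recipe.blocks_per_condition_per_run
    if reps < 1:
        raise ValueError("blocks_per_condition_per_run must be >= 1")
    if k == 1:
        logger.warning(
            "single-condition sequence cannot satisfy the transition balance; "
            "falling back to simple repetition"
        )
        return [[labels[0]] * reps for _ in range(recipe.n_runs)]

    rng = np.random.default_rng(seed)
    best: list[list[str]] | None = None
    best_spread = np.inf
    for _ in range(max_restarts):
        counts = np.zeros((k, k), dtype=int)
        runs: list[list[str]] = []
        failed = False
        for _run in range(recipe.n_runs):
            remaining = np.full(k, reps)
            seq: list[int] = []
            prev = -1
            for _ in range(k * reps):
                cand = [c for c in range(k) if remaining[c] > 0 and c != prev]
                if not cand:
                    failed = True
                    break
                if prev < 0:
                    c = int(rng.choice(cand))
                else:
                    tc = np.array([counts[prev, c] for c in cand])
                    pool = [c for c, t in zip(cand, tc) if t == tc.min()]
                    c = int(pool[rng.integers(len(pool))])
                if prev >= 0:
                    counts[prev, c] += 1
                remaining[c] -= 1
                seq.append(c)
                prev = c
            if failed:
                break
            runs.append([labels[c] for c in seq])
        if failed:
            continue
        off = counts[~np.eye(k, dtype=bool)]
        spread = int(off.max() - off.min())
        if spread < best_spread:
            best, best_spread = runs, spread
        if spread <= 1:
            return runs
    logger.warning(
        "transition balance not achieved (spread=%s) after %d restarts; "
        "returning the best sequence found",
        best_spread,
        max_restarts,
    )
    assert best is not None
    return best


@dataclass(frozen=True)
class BlockTimeline:
    """Onsets/durations of one run's blocks, rest included as gaps."""

    labels: tuple[str, ...]
    onsets_s: tuple[float, ...]
    durations_s: tuple[float, ...]


def layout_run(
    sequence: Sequence[str],
    recipe: SessionRecipe,
    start_delay_s: float = 10.0,
    end_pad_s: float = 14.0,
) -> BlockTimeline:
    """Place movement and rest blocks evenly over the run duration.

    Rest blocks are interleaved at evenly spaced positions among the movement
    blocks; any run time left over (runs are longer than the sum of
    block durations) is distributed as equal inter-block gaps after an initial
    delay, leaving room at the end for the hemodynamic tail.
    """
    n_move = len(sequence)
    n_rest = recipe.rest_blocks_per_run
    if n_rest:
        n_total = n_move + n_rest
        # evenly spaced, collision-free rest positions
        raw = np.linspace(0, n_total - 1, n_rest + 2)[1:-1]
        rest_slots: set[int] = set()
        for r in raw:
            s = int(round(r))
            while s in rest_slots:
                s += 1
            rest_slots.add(s % n_total)
        it = iter(sequence)
        order = ["rest" if slot in rest_slots else next(it) for slot in range(n_total)]
    else:
        order = list(sequence)
    n_blocks = len(order)
    total_block_s = n_blocks * recipe.block_s
    slack = recipe.run_duration_s() - total_block_s - start_delay_s - end_pad_s
    if slack < 0:
        start_delay_s = max(0.0, start_delay_s + slack)
        slack = recipe.run_duration_s() - total_block_s - start_delay_s - end_pad_s
        if slack < 0:
            end_pad_s = max(0.0, end_pad_s + slack)
            slack = max(0.0, recipe.run_duration_s() - total_block_s - start_delay_s - end_pad_s)
    gap = slack / max(n_blocks - 1, 1)
    labels, onsets = [], []
    t = start_delay_s
    for lab in order:
        labels.append(lab)
        onsets.append(round(t, 6))
        t += recipe.block_s + gap
    keep = [i for i, lab in enumerate(labels) if lab != "rest"]
    return BlockTimeline(
        labels=tuple(labels[i] for i in keep),
        onsets_s=tuple(onsets[i] for i in keep),
        durations_s=tuple(recipe.block_s for _ in keep),
    )
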