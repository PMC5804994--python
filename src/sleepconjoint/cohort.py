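"""Synthetic respondents: ground-truth utilities, choice behaviour, cohort
traits, exclusion rules and summary-statistic group comparisons.

The behavioural model is the Luce/logit rule: a compliant respondent judges
scenario *a* the better night of sleep with probability
``sigmoid((U_a - U_b) / noise_scale)``, where ``U`` is a linear utility over
part-worths (log-odds per parameter level, reference level 1 fixed at 0) plus
optional pairwise interactions restricted to the during-sleep x next-day
crossing, optional question-type shifts and optional sleeper-group shifts.
This rule is what makes the human-in-the-loop Markov chain's stationary
distribution proportional to ``exp(U)`` (Barker acceptance), and it is exactly
the data-generating process the logistic choice model assumes.

On "worse"-question trials the respondent *chooses* the scenario they judge
worse; the recorded ``judged_better`` label is the other scenario.
Noncompliant respondents choose uniformly at random and answer fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .scenario_space import Scenario, ScenarioSpace, canonical_space

__all__ = [
    "DURING_SLEEP_PARAMS",
    "NEXT_DAY_PARAMS",
    "UtilityWeights",
    "Agent",
    "CohortConfig",
    "utility",
    "choose",
    "apply_exclusions",
    "welch_t",
    "pooled_t",
    "simulate_cohort",
    "simulate_random_choices",
    "default_true_weights",
]

#: The four during-sleep parameters eligible for pairwise interactions ...
DURING_SLEEP_PARAMS: tuple[str, ...] = (
    "sleep_onset_latency",
    "wake_after_sleep_onset",
    "total_sleep_time",
    "dream",
)
#: ... crossed with the seven upon-waking / day-after parameters.
NEXT_DAY_PARAMS: tuple[str, ...] = (
    "feeling_refreshed",
    "motivated_to_get_up",
    "alertness",
    "thinking",
    "mood_day_after",
    "sociability",
    "physical_activity",
)

LevelKey = tuple[str, int]
PairKey = tuple[LevelKey, LevelKey]


@dataclass(frozen=True)
class UtilityWeights:
    """Part-worth utilities on the log-odds scale.

    ``part_worths[name]`` is a sequence of per-level utilities (1-based level
    ``i`` at position ``i - 1``); the reference level 1 must be exactly 0.
    ``interaction_weights`` maps ``((param_i, level_i), (param_j, level_j))``
    to a weight, with ``param_i`` during-sleep and ``param_j`` next-day and
    both levels non-reference. ``question_shifts`` apply only on "worse"
    trials; ``sleeper_shifts`` only to the named sleeper group.
    """

    part_worths: Mapping[str, tuple[float, ...]]
    interaction_weights: Mapping[PairKey, float] = field(default_factory=dict)
    question_shifts: Mapping[LevelKey, float] = field(default_factory=dict)
    sleeper_shifts: Mapping[LevelKey, float] = field(default_factory=dict)
    sleeper_shift_group: str = "good"

    def validate(self, space: ScenarioSpace) -> None:
        for p in space.parameters:
            if p.name not in self.part_worths:
                raise ValueError(f"no part-worths for parameter {p.name!r}")
            w = self.part_worths[p.name]
            if len(w) != p.n_levels:
                raise ValueError(
                    f"{p.name!r}: {len(w)} weights for {p.n_levels} levels"
                )
            if w[0] != 0.0:
                raise ValueError(f"{p.name!r}: reference level weight must be 0")
        for (pi, li), (pj, lj) in self.interaction_weights:
            if pi not in DURING_SLEEP_PARAMS or pj not in NEXT_DAY_PARAMS:
                raise ValueError(
                    f"interaction ({pi!r}, {pj!r}) outside the during-sleep x "
                    "next-day crossing"
                )
            if li < 2 or lj < 2:
                raise ValueError("interaction levels must be non-reference (>= 2)")

    def with_offset(self, c: float) -> "UtilityWeights":
        """Shift every non-reference part-worth by ``c`` (for tests of
        translation behaviour; reference levels stay pinned at 0)."""
        shifted = {
            name: tuple(0.0 if i == 0 else w + c for i, w in enumerate(ws))
            for name, ws in self.part_worths.items()
        }
        return replace(self, part_worths=shifted)


@dataclass
class Agent:
    """A simulated respondent."""

    participant_id: str
    sleeper_group: Literal["good", "poor"]
    weights: UtilityWeights
    noise_scale: float = 1.0
    compliant: bool = True

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")


def utility(
    agent: Agent, scenario: Scenario, question_type: Literal["better", "worse"] = "better"
) -> float:
    """Deterministic utility of a scenario for one agent.

    Sum of part-worths at the scenario's levels, plus interaction weights
    whose two (parameter, level) pins both match, plus question-type shifts
    (on "worse" trials) and sleeper-group shifts (if the agent belongs to the
    shifted group).
    """
    space = canonical_space() if len(scenario.levels) == 17 else None
    w = agent.weights
    total = 0.0
    names = list(w.part_worths)
    if space is not None and space.n_parameters == len(scenario.levels):
        names = list(space.names)
    if len(names) != len(scenario.levels):
        raise ValueError("weights do not cover the scenario's parameters")
    levels = dict(zip(names, scenario.levels))
    for name, lv in levels.items():
        try:
            total += w.part_worths[name][lv - 1]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"no weight for ({name!r}, level {lv})") from exc
    for ((pi, li), (pj, lj)), g in w.interaction_weights.items():
        if levels.get(pi) == li and levels.get(pj) == lj:
            total += g
    if question_type == "worse":
        for (name, lv), s in w.question_shifts.items():
            if levels.get(name) == lv:
                total += s
    if agent.sleeper_group == w.sleeper_shift_group:
        for (name, lv), s in w.sleeper_shifts.items():
            if levels.get(name) == lv:
                total += s
    return total


def choose(
    agent: Agent,
    scenario_a: Scenario,
    scenario_b: Scenario,
    question_type: Literal["better", "worse"],
    rng: np.random.Generator,
) -> tuple[str, str]:
    """One paired-comparison choice. Returns ``(chosen, judged_better)``,
    each ``"a"`` or ``"b"``.

    A compliant agent judges *a* better with probability
    ``sigmoid((U_a - U_b)/noise_scale)``; on a "worse" question it *chooses*
    the scenario judged worse. A noncompliant agent picks uniformly.
    """
    if not agent.compliant:
        chosen = "a" if rng.random() < 0.5 else "b"
        # A random chooser still implies a judgment consistent with the question.
        judged_better = chosen if question_type == "better" else ("b" if chosen == "a" else "a")
        return chosen, judged_better
    ua = utility(agent, scenario_a, question_type)
    ub = utility(agent, scenario_b, question_type)
    p_a_better = 1.0 / (1.0 + math.exp(-(ua - ub) / agent.noise_scale))
    judged_better = "a" if rng.random() < p_a_better else "b"
    if question_type == "better":
        chosen = judged_better
    else:
        chosen = "b" if judged_better == "a" else "a"
    return chosen, judged_better


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Trait distributions per sleeper group: (mean, sd, low, high). Defaults are
#: centred on the study cohort's printed group summaries; draws are truncated
#: to plausible ranges (and to the ISI group cut-offs: good <= 7, poor >= 8).
DEFAULT_TRAITS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "good": {
        "age": (22.6, 2.6, 18.0, 30.0),
        "bmi": (21.7, 2.8, 14.0, 40.0),
        "isi": (3.61, 2.1, 0.0, 7.0),
        "typical_sol_min": (15.0, 14.0, 0.0, 180.0),
        "typical_waso_min": (3.2, 6.4, 0.0, 120.0),
        "typical_tst_min": (483.0, 78.7, 180.0, 720.0),
    },
    "poor": {
        "age": (22.3, 2.6, 18.0, 30.0),
        "bmi": (21.8, 3.8, 14.0, 40.0),
        "isi": (12.5, 3.5, 8.0, 28.0),
        "typical_sol_min": (35.12, 27.0, 0.0, 180.0),
        "typical_waso_min": (9.9, 12.5, 0.0, 120.0),
        "typical_tst_min": (430.0, 66.5, 180.0, 720.0),
    },
}


@dataclass
class CohortConfig:
    """Sizes, noncompliance and trait distributions of the simulated cohort."""

    n_good: int = 50
    n_poor: int = 50
    n_noncompliant: int = 7
    noise_scale: float = 1.0
    # log-normal response-time medians (seconds) per trial
    rt_median_compliant_s: float = 35.0
    rt_median_noncompliant_s: float = 8.0
    rt_sigma: float = 0.35
    traits: Mapping[str, Mapping[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: DEFAULT_TRAITS
    )

    def validate(self) -> None:
        if self.n_good < 0 or self.n_poor < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_noncompliant > self.n_good + self.n_poor:
            raise ValueError("more noncompliant participants than participants")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Seeded truncated-normal draws."""
    from scipy.stats import truncnorm

    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    config: CohortConfig,
    weights: UtilityWeights,
    rng: np.random.Generator | int,
    n_groups_per_sleeper: int = 3,
) -> tuple[list[Agent], pd.DataFrame]:
    """Draw a cohort of agents and their trait table.

    Participants are assigned round-robin to ``n_groups_per_sleeper`` chain
    groups within their sleeper group, in order of participation. Exactly
    ``n_noncompliant`` participants are flagged noncompliant; they are placed
    away from first-in-group positions so that the fast-responder and
    first-in-chain exclusions do not overlap (the default study-design run then
    retains 100 - 7 - 6 = 87 participants).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    config.validate()
    rows: list[dict] = []
    agents: list[Agent] = []
    pid = 0
    for group, n in (("good", config.n_good), ("poor", config.n_poor)):
        traits = config.traits[group]
        draws = {k: _truncated_normal(rng, *v, size=n) for k, v in traits.items()}
        for i in range(n):
            pid += 1
            chain_group = f"{group}_{i % n_groups_per_sleeper + 1}"
            rows.append(
                {
                    "participant_id": f"P{pid:03d}",
                    "sleeper_group": group,
                    "chain_group": chain_group,
                    "order_in_group": i // n_groups_per_sleeper,
                    "age": float(draws["age"][i]),
                    "bmi": float(draws["bmi"][i]),
                    "isi": float(draws["isi"][i]),
                    "typical_sol_min": float(draws["typical_sol_min"][i]),
                    "typical_waso_min": float(draws["typical_waso_min"][i]),
                    "typical_tst_min": float(draws["typical_tst_min"][i]),
                }
            )
    cohort_cols = [
        "participant_id", "sleeper_group", "chain_group", "order_in_group",
        "age", "bmi", "isi", "typical_sol_min", "typical_waso_min", "typical_tst_min",
    ]
    cohort = pd.DataFrame(rows, columns=cohort_cols)
    n_total = len(cohort)
    eligible = cohort.index[cohort["order_in_group"] > 0].to_numpy()
    k = min(config.n_noncompliant, len(eligible))
    noncomp = set(rng.choice(eligible, size=k, replace=False)) if k else set()
    cohort["compliant"] = [i not in noncomp for i in cohort.index]
    for _, row in cohort.iterrows():
        agents.append(
            Agent(
                participant_id=row["participant_id"],
                sleeper_group=row["sleeper_group"],
                weights=weights,
                noise_scale=config.noise_scale,
                compliant=bool(row["compliant"]),
            )
        )
    assert len(agents) == n_total
    return agents, cohort


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

def apply_exclusions(
    dataset: pd.DataFrame,
    cohort: pd.DataFrame,
    fast_threshold_s: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two analysis exclusions and flag the cohort table.

    1. *fast_responder*: mean trial response time below ``fast_threshold_s``
       seconds (noncompliance heuristic).
    2. *first_in_chain*: the first participant to run each chain group; their
       trials seeded the chains (states are retained) but their records are
       treated as burn-in and dropped.

    A participant matching both rules is counted once, as *fast_responder*.
    Returns ``(retained_dataset, cohort_with_flags)``.
    """
    cohort = cohort.copy()
    cohort["exclusion_reason"] = None
    if len(dataset):
        mean_rt = dataset.groupby("participant_id")["response_time_s"].mean()
        fast = set(mean_rt.index[mean_rt < fast_threshold_s])
    else:
        fast = set()
    first = set(
        cohort.sort_values(["chain_group", "order_in_group"])
        .groupby("chain_group")["participant_id"]
        .first()
    )
    reasons = []
    for pid in cohort["participant_id"]:
        if pid in fast:
            reasons.append("fast_responder")
        elif pid in first:
            reasons.append("first_in_chain")
        else:
            reasons.append(None)
    cohort["exclusion_reason"] = reasons
    cohort["retained"] = cohort["exclusion_reason"].isna()
    keep = set(cohort.loc[cohort["retained"], "participant_id"])
    retained = dataset[dataset["participant_id"].isin(keep)].reset_index(drop=True)
    return retained, cohort


# ---------------------------------------------------------------------------
# Two-sample t statistics from printed summary statistics
# ---------------------------------------------------------------------------

def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t from group summaries.

    Returns ``(t, df)`` with the Welch–Satterthwaite degrees of freedom.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Classic pooled-variance two-sample t; df = n1 + n2 - 2."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, df


# ---------------------------------------------------------------------------
# Vectorised choice simulation on independent random pairs
# ---------------------------------------------------------------------------

def _weights_arrays(space: ScenarioSpace, w: UtilityWeights) -> list[np.ndarray]:
    return [np.asarray(w.part_worths[p.name], dtype=float) for p in space.parameters]


def _utilities_matrix(
    levels: np.ndarray,
    space: ScenarioSpace,
    w: UtilityWeights,
    worse: np.ndarray | None = None,
    sleeper_match: np.ndarray | None = None,
) -> np.ndarray:
    """Utilities for an (n, P) matrix of 1-based levels (vectorised)."""
    arrays = _weights_arrays(space, w)
    total = np.zeros(len(levels))
    for j, arr in enumerate(arrays):
        total += arr[levels[:, j] - 1]
    for ((pi, li), (pj, lj)), g in w.interaction_weights.items():
        i, j = space.index_of(pi), space.index_of(pj)
        total += g * ((levels[:, i] == li) & (levels[:, j] == lj))
    if worse is not None:
        for (name, lv), s in w.question_shifts.items():
            j = space.index_of(name)
            total += s * worse * (levels[:, j] == lv)
    if sleeper_match is not None:
        for (name, lv), s in w.sleeper_shifts.items():
            j = space.index_of(name)
            total += s * sleeper_match * (levels[:, j] == lv)
    return total


def simulate_random_choices(
    space: ScenarioSpace,
    weights: UtilityWeights,
    n: int,
    rng: np.random.Generator | int,
    noise_scale: float = 1.0,
    question_mix: float = 0.5,
) -> pd.DataFrame:
    """Simulate ``n`` paired-comparison trials on independent uniform scenario
    pairs (no chaining), in the dataset schema used across the package.

    Useful for calibration and parameter-recovery studies where a
    well-conditioned design is wanted. Sleeper groups alternate; a fraction
    ``question_mix`` of trials ask the "worse" question. Pairs identical in
    every parameter are redrawn.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = np.asarray(space.level_counts)
    P = space.n_parameters

    def draw(nn: int) -> np.ndarray:
        return rng.integers(1, counts + 1, size=(nn, P))

    a, b = draw(n), draw(n)
    same = (a == b).all(axis=1)
    while same.any():  # negligible probability on the canonical space
        b[same] = draw(int(same.sum()))
        same = (a == b).all(axis=1)

    worse = (rng.random(n) < question_mix).astype(float)
    sleeper_good = np.arange(n) % 2 == 0
    match = (
        sleeper_good
        if weights.sleeper_shift_group == "good"
        else ~sleeper_good
    ).astype(float)
    ua = _utilities_matrix(a, space, weights, worse, match)
    ub = _utilities_matrix(b, space, weights, worse, match)
    p_a_better = 1.0 / (1.0 + np.exp(-(ua - ub) / noise_scale))
    a_better = rng.random(n) < p_a_better
    judged = np.where(a_better, "a", "b")
    chosen = np.where(worse == 1.0, np.where(a_better, "b", "a"), judged)
    first = np.where(rng.random(n) < 0.5, "a", "b")

    data = {
        "participant_id": [f"S{i % 100:03d}" for i in range(n)],
        "sleeper_group": np.where(sleeper_good, "good", "poor"),
        "chain_group": "iid",
        "chain_id": "iid",
        "trial_index": np.arange(1, n + 1),
        "question_type": np.where(worse == 1.0, "worse", "better"),
    }
    for j, name in enumerate(space.names):
        data[f"a_{name}"] = a[:, j]
    for j, name in enumerate(space.names):
        data[f"b_{name}"] = b[:, j]
    data["first_shown"] = first
    data["chosen"] = chosen
    data["judged_better"] = judged
    data["response_time_s"] = np.full(n, 35.0)
    return pd.DataFrame(data)


def default_true_weights(space: ScenarioSpace | None = None) -> UtilityWeights:
    """Synthetic demonstration ground truth (not estimates from any study).

    Magnitudes follow the qualitative importance ordering reported for sleep
    quality judgment — total sleep time, feeling refreshed and day-after mood
    largest; day-before parameters near zero — plus one WASO x refreshed
    interaction and one refreshed x question shift. Values are this package's
    own invention for simulation demos and tests.
    """
    if space is None:
        space = canonical_space()
    pw: dict[str, tuple[float, ...]] = {
        "amount_of_activity": (0.0, 0.05, 0.10),
        "day_went_well": (0.0, 0.02, 0.05),
        "mood_day_before": (0.0, 0.08, 0.15),
        "readiness_to_sleep": (0.0, 0.10, 0.20),
        "cognitive_arousal": (0.0, 0.08, 0.15),
        "physiological_arousal": (0.0, 0.40, 0.80),
        "sleep_onset_latency": (0.0, 0.40, 0.75),
        "wake_after_sleep_onset": (0.0, 0.30, 0.55, 0.75, 0.95),
        "total_sleep_time": (0.0, -0.90, -1.80),
        "dream": (0.0, 0.05, 0.10),
        "feeling_refreshed": (0.0, 0.80, 1.50),
        "motivated_to_get_up": (0.0, 0.55, 1.05),
        "alertness": (0.0, 0.25, 0.50),
        "thinking": (0.0, 0.35, 0.70),
        "mood_day_after": (0.0, 0.70, 1.30),
        "sociability": (0.0, 0.25, 0.45),
        "physical_activity": (0.0, 0.30, 0.60),
    }
    interactions = {
        (("wake_after_sleep_onset", 5), ("feeling_refreshed", 2)): -0.40,
        (("wake_after_sleep_onset", 5), ("feeling_refreshed", 3)): -0.40,
    }
    qshifts = {("feeling_refreshed", 3): -0.40}
    w = UtilityWeights(
        part_worths=pw,
        interaction_weights=interactions,
        question_shifts=qshifts,
    )
    w.validate(space)
    return w
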