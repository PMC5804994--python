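"""Markov Chain Monte Carlo with People (MCMCP): the scenario-sampling engine.

A respondent's binary choices act as the accept/reject step of a Markov
chain over scenarios: the chain's current scenario is mutated by a
truncated-geometric kernel, the respondent chooses between current state and
proposal, and the chosen scenario becomes the next state. With a Luce/logit
chooser this is Barker acceptance, so the chain's stationary distribution is
proportional to ``exp(U)`` on "better"-question chains (and ``exp(-U)`` on
"worse"-question chains, which sample bad nights of sleep).

Session structure mirrors the study design: 48 trials per participant, in 4
interleaved chains of 12 trials (2 chains per question type); chain states
carry over from one participant to the next; 3 chain groups per sleeper type
run in parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Agent, CohortConfig, UtilityWeights, apply_exclusions, choose, default_true_weights, simulate_cohort
from .scenario_space import Scenario, ScenarioSpace, canonical_space, random_scenario

__all__ = [
    "MutationKernelConfig",
    "Chain",
    "ChainGroup",
    "TrialRecord",
    "ExperimentConfig",
    "ExperimentResult",
    "truncated_geometric_pmf",
    "truncated_geometric_mean",
    "calibrate_kernel",
    "propose",
    "init_chain_groups",
    "run_session",
    "run_experiment",
    "dataset_columns",
]


# ---------------------------------------------------------------------------
# Mutation kernel
# ---------------------------------------------------------------------------

def truncated_geometric_pmf(rate: float, truncation_max: int) -> np.ndarray:
    """pmf ``p(k) ∝ (1-r)^(k-1) r`` on support ``{1..truncation_max}``,
    renormalised. Returned as an array indexed by ``k-1``."""
    if not 0 < rate <= 1:
        raise ValueError("rate must lie in (0, 1]")
    if truncation_max < 1:
        raise ValueError("truncation_max must be >= 1")
    k = np.arange(1, truncation_max + 1)
    if rate == 1.0:
        pmf = np.zeros(truncation_max)
        pmf[0] = 1.0
        return pmf
    logp = (k - 1) * math.log1p(-rate)
    p = np.exp(logp - logp.max())
    return p / p.sum()


def truncated_geometric_mean(rate: float, truncation_max: int) -> float:
    pmf = truncated_geometric_pmf(rate, truncation_max)
    return float(pmf @ np.arange(1, truncation_max + 1))


@dataclass(frozen=True)
class MutationKernelConfig:
    """Calibrated truncated-geometric proposal kernel.

    ``rate`` is solved so the mean number of parameters changed per proposal
    equals ``target_mean`` on support ``{1..truncation_max}``. With
    ``allow_self_level=False`` (default) a changed parameter must move to a
    *different* level, so the Hamming distance of each proposal equals the
    sampled change count exactly.
    """

    target_mean: float
    truncation_max: int
    rate: float
    allow_self_level: bool = False

    def pmf(self) -> np.ndarray:
        return truncated_geometric_pmf(self.rate, self.truncation_max)

    @property
    def mean(self) -> float:
        return truncated_geometric_mean(self.rate, self.truncation_max)


def calibrate_kernel(
    target_mean: float = 4.6,
    truncation_max: int = 17,
    allow_self_level: bool = False,
) -> MutationKernelConfig:
    """Solve the kernel rate by bisection so E[changes] = ``target_mean``.

    The mean is monotone decreasing in the rate, from ``(1+K)/2`` (rate -> 0,
    uniform) to 1 (rate = 1), so attainable targets lie in
    ``[1, (1+truncation_max)/2)``.
    """
    K = truncation_max
    if K < 1:
        raise ValueError("truncation_max must be >= 1")
    if K == 1:  # support {1}: mean is forced to 1, any rate valid
        return MutationKernelConfig(1.0, K, 1.0, allow_self_level)
    if target_mean == 1.0:
        return MutationKernelConfig(1.0, K, 1.0, allow_self_level)
    upper = (1 + K) / 2
    if not 1.0 <= target_mean < upper:
        raise ValueError(
            f"target_mean {target_mean} outside attainable range "
            f"[1, {upper}) for truncation_max {K}"
        )
    f = lambda r: truncated_geometric_mean(r, K) - target_mean
    lo = 1e-12
    while f(lo) < 0:  # mean(lo) must exceed target
        lo /= 10
    rate = brentq(f, lo, 1.0, xtol=1e-15, rtol=8.9e-16)
    cfg = MutationKernelConfig(target_mean, K, float(rate), allow_self_level)
    assert abs(cfg.mean - target_mean) < 1e-9
    return cfg


def propose(
    current: Scenario,
    kernel: MutationKernelConfig,
    space: ScenarioSpace,
    rng: np.random.Generator,
) -> Scenario:
    """Mutate ``current``: draw a change count k from the kernel, pick k
    distinct parameters uniformly, and resample each changed parameter's
    level uniformly (excluding the current level unless
    ``allow_self_level``). Each parameter is equally likely to be changed and
    all new options are equally likely, making the proposal symmetric."""
    P = space.n_parameters
    kmax = min(kernel.truncation_max, P)
    pmf = truncated_geometric_pmf(kernel.rate, kmax)
    k = int(rng.choice(np.arange(1, kmax + 1), p=pmf))
    which = rng.choice(P, size=k, replace=False)
    levels = list(current.levels)
    for j in which:
        L = space.parameters[j].n_levels
        if kernel.allow_self_level:
            levels[j] = int(rng.integers(1, L + 1))
        else:
            new = int(rng.integers(1, L))  # uniform over the L-1 other levels
            if new >= levels[j]:
                new += 1
            levels[j] = new
    return Scenario(levels=tuple(levels))


# ---------------------------------------------------------------------------
# Chains and chain groups
# ---------------------------------------------------------------------------

@dataclass
class Chain:
    id: str
    question_type: Literal["better", "worse"]
    sleeper_group: Literal["good", "poor"]
    states: list[Scenario] = field(default_factory=list)
    trial_count: int = 0

    @property
    def current(self) -> Scenario:
        return self.states[-1]


@dataclass
class ChainGroup:
    group_id: str
    sleeper_group: Literal["good", "poor"]
    chains: list[Chain]

    def __post_init__(self) -> None:
        per_q = {"better": 0, "worse": 0}
        for c in self.chains:
            per_q[c.question_type] += 1
        if per_q["better"] != per_q["worse"]:
            raise ValueError("chain group needs equal chains per question type")


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    chain_id: str
    trial_index: int  # 1..48 within the session
    question_type: str
    scenario_current: Scenario
    scenario_proposal: Scenario
    chosen: str  # "current" | "proposal"
    judged_better: str  # "current" | "proposal"
    presentation_order: str  # "current_first" | "proposal_first"
    response_time_s: float


def init_chain_groups(
    space: ScenarioSpace,
    n_groups_per_sleeper: int = 3,
    rng: np.random.Generator | int = 0,
    chains_per_question: int = 2,
) -> list[ChainGroup]:
    """Create ``2 * n_groups_per_sleeper`` groups of 4 chains (2 per question
    type), with uniform-random initial states."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_groups_per_sleeper < 1:
        raise ValueError("n_groups_per_sleeper must be >= 1")
    groups: list[ChainGroup] = []
    for sleeper in ("good", "poor"):
        for g in range(1, n_groups_per_sleeper + 1):
            chains = []
            for q in ("better", "worse"):
                for c in range(1, chains_per_question + 1):
                    chains.append(
                        Chain(
                            id=f"{sleeper}_{g}_{q}_{c}",
                            question_type=q,
                            sleeper_group=sleeper,
                            states=[random_scenario(space, rng)],
                        )
                    )
            groups.append(ChainGroup(f"{sleeper}_{g}", sleeper, chains))
    return groups


def run_session(
    participant: Agent,
    group: ChainGroup,
    kernel: MutationKernelConfig,
    space: ScenarioSpace,
    rng: np.random.Generator,
    trials_per_chain: int = 12,
    rt_median_s: float = 35.0,
    rt_sigma: float = 0.35,
) -> list[TrialRecord]:
    """Run one participant's session on a chain group.

    The session interleaves the group's chains: trials come in blocks of one
    trial per chain, with a seeded shuffle of chain order inside each block,
    hiding the sequential structure. On each trial the kernel proposes a
    mutation of the chain's current state, the participant chooses, and the
    chosen scenario becomes the chain's new state (MCMCP acceptance =
    participant choice). States persist in the group, carrying over to the
    next participant.
    """
    records: list[TrialRecord] = []
    n_chains = len(group.chains)
    trial_index = 0
    for _block in range(trials_per_chain):
        order = rng.permutation(n_chains)
        for ci in order:
            chain = group.chains[ci]
            trial_index += 1
            current = chain.current
            proposal = propose(current, kernel, space, rng)
            first = "current_first" if rng.random() < 0.5 else "proposal_first"
            if first == "current_first":
                chosen_ab, judged_ab = choose(
                    participant, current, proposal, chain.question_type, rng
                )
                label = {"a": "current", "b": "proposal"}
            else:
                chosen_ab, judged_ab = choose(
                    participant, proposal, current, chain.question_type, rng
                )
                label = {"a": "proposal", "b": "current"}
            chosen = label[chosen_ab]
            judged_better = label[judged_ab]
            rt = float(rng.lognormal(math.log(rt_median_s), rt_sigma))
            records.append(
                TrialRecord(
                    participant_id=participant.participant_id,
                    chain_id=chain.id,
                    trial_index=trial_index,
                    question_type=chain.question_type,
                    scenario_current=current,
                    scenario_proposal=proposal,
                    chosen=chosen,
                    judged_better=judged_better,
                    presentation_order=first,
                    response_time_s=rt,
                )
            )
            chain.states.append(current if chosen == "current" else proposal)
            chain.trial_count += 1
    return records


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Defaults reproduce the study design: 100 participants (50 good / 50
    poor sleepers, 7 of them noncompliant), 6 chain groups, 48 trials per
    participant (4 chains x 12), kernel mean 4.6 on support {1..17}, and the
    <20 s mean-response-time exclusion."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_groups_per_sleeper: int = 3
    trials_per_chain: int = 12
    kernel_target_mean: float = 4.6
    kernel_truncation_max: int = 17
    allow_self_level: bool = False
    fast_threshold_s: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if self.n_groups_per_sleeper < 1:
            raise ValueError("n_groups_per_sleeper must be >= 1")
        if self.trials_per_chain < 1:
            raise ValueError("trials_per_chain must be >= 1")


@dataclass
class ExperimentResult:
    raw: pd.DataFrame
    retained: pd.DataFrame
    cohort: pd.DataFrame
    truth: UtilityWeights
    groups: list[ChainGroup]


def dataset_columns(space: ScenarioSpace) -> list[str]:
    """CSV schema of a choice dataset: one row per trial."""
    return (
        ["participant_id", "sleeper_group", "chain_group", "chain_id", "trial_index", "question_type"]
        + [f"a_{n}" for n in space.names]
        + [f"b_{n}" for n in space.names]
        + ["first_shown", "chosen", "judged_better", "response_time_s"]
    )


def _records_to_rows(
    records: Sequence[TrialRecord],
    sleeper_group: str,
    chain_group: str,
    space: ScenarioSpace,
) -> list[dict]:
    """Flatten trial records to the a/b dataset schema (a = current state,
    b = proposal)."""
    rows = []
    for r in records:
        row: dict = {
            "participant_id": r.participant_id,
            "sleeper_group": sleeper_group,
            "chain_group": chain_group,
            "chain_id": r.chain_id,
            "trial_index": r.trial_index,
            "question_type": r.question_type,
        }
        for name, lv in zip(space.names, r.scenario_current.levels):
            row[f"a_{name}"] = lv
        for name, lv in zip(space.names, r.scenario_proposal.levels):
            row[f"b_{name}"] = lv
        row["first_shown"] = "a" if r.presentation_order == "current_first" else "b"
        row["chosen"] = "a" if r.chosen == "current" else "b"
        row["judged_better"] = "a" if r.judged_better == "current" else "b"
        row["response_time_s"] = r.response_time_s
        rows.append(row)
    return rows


def run_experiment(
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    space: ScenarioSpace | None = None,
    weights: UtilityWeights | None = None,
) -> ExperimentResult:
    """Simulate the full experiment and apply the analysis exclusions.

    All randomness flows from one root seed through named child streams
    (cohort, chain initialisation, sessions), so reruns are byte-identical.
    Participants within each chain group run in their order of participation;
    the first participant of each group seeds the chains (their states are
    kept, their records dropped by :func:`apply_exclusions`).
    """
    config = config or ExperimentConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    if space is None:
        space = canonical_space()
    if weights is None:
        weights = default_true_weights(space)
    weights.validate(space)

    root = np.random.SeedSequence(seed)
    ss_cohort, ss_init, ss_sessions = root.spawn(3)
    agents, cohort = simulate_cohort(
        config.cohort,
        weights,
        np.random.default_rng(ss_cohort),
        n_groups_per_sleeper=config.n_groups_per_sleeper,
    )
    groups = {
        g.group_id: g
        for g in init_chain_groups(
            space, config.n_groups_per_sleeper, np.random.default_rng(ss_init)
        )
    }
    kernel = calibrate_kernel(
        config.kernel_target_mean, config.kernel_truncation_max, config.allow_self_level
    )
    agent_by_id = {a.participant_id: a for a in agents}
    rows: list[dict] = []
    order = cohort.sort_values(["chain_group", "order_in_group"], kind="stable")
    session_rng = np.random.default_rng(ss_sessions)
    for _, prow in order.iterrows():
        agent = agent_by_id[prow["participant_id"]]
        group = groups[prow["chain_group"]]
        rt_median = (
            config.cohort.rt_median_compliant_s
            if agent.compliant
            else config.cohort.rt_median_noncompliant_s
        )
        records = run_session(
            agent,
            group,
            kernel,
            space,
            session_rng,
            trials_per_chain=config.trials_per_chain,
            rt_median_s=rt_median,
            rt_sigma=config.cohort.rt_sigma,
        )
        rows.extend(_records_to_rows(records, prow["sleeper_group"], prow["chain_group"], space))

    raw = pd.DataFrame(rows, columns=dataset_columns(space)) if rows else pd.DataFrame(
        columns=dataset_columns(space)
    )
    retained, cohort = apply_exclusions(raw, cohort, config.fast_threshold_s)
    return ExperimentResult(raw=raw, retained=retained, cohort=cohort, truth=weights, groups=list(groups.values()))
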