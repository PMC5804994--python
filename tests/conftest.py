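import itertools

import numpy as np
import pandas as pd
import pytest

from sleepconjoint import canonical_space
from sleepconjoint.cohort import Agent, UtilityWeights
from sleepconjoint.scenario_space import ParameterDef, ScenarioSpace


@pytest.fixture(scope="session")
def space():
    return canonical_space()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_space(level_counts, period="day_after"):
    """Small ad-hoc space with the given per-parameter level counts."""
    params = tuple(
        ParameterDef(
            name=f"p{i}",
            period=period,
            levels=tuple(f"phrase {i}.{j}" for j in range(n)),
        )
        for i, n in enumerate(level_counts)
    )
    return ScenarioSpace(parameters=params)


def enumerate_scenarios(sp):
    """Brute-force enumeration of all scenarios of a small space."""
    ranges = [range(1, p.n_levels + 1) for p in sp.parameters]
    return list(itertools.product(*ranges))


def boltzmann_target(sp, part_worths, sign=+1.0):
    """Exact normalised exp(sign * U) over an enumerated small space."""
    states = enumerate_scenarios(sp)
    u = np.array(
        [sum(part_worths[p.name][lv - 1] for p, lv in zip(sp.parameters, s)) for s in states]
    )
    w = np.exp(sign * u)
    return states, w / w.sum()


@pytest.fixture
def tiny3_space():
    return make_space([3, 3, 3])


@pytest.fixture
def tiny3_agent(tiny3_space):
    pw = {"p0": (0.0, 0.6, -0.4), "p1": (0.0, -0.8, 0.5), "p2": (0.0, 0.3, 0.9)}
    w = UtilityWeights(part_worths=pw)
    w.validate(tiny3_space)
    return Agent("A1", "good", w)


def synthetic_chain_dataset(states_per_chain, question_type="better"):
    """Build a minimal choice dataset carrying prescribed chain state
    sequences (d parameters inferred from the state tuples)."""
    rows = []
    for cid, states in states_per_chain.items():
        for t, s in enumerate(states, start=1):
            row = {
                "participant_id": f"{cid}_p{(t - 1) // 12}",
                "sleeper_group": "good",
                "chain_group": "g",
                "chain_id": cid,
                "trial_index": t,
                "question_type": question_type,
                "first_shown": "a",
                "chosen": "a",
                "judged_better": "a",
                "response_time_s": 30.0,
            }
            for j, lv in enumerate(s):
                row[f"a_p{j}"] = lv
                row[f"b_p{j}"] = lv
            rows.append(row)
    return pd.DataFrame(rows)
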