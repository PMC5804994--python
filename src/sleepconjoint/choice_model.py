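"""The paired-comparison logistic choice model and its inference stack.

Each trial contributes one row: the response is whether the *first-shown*
scenario was judged the better night of sleep, and each scenario column is
the difference of the two scenarios' treatment-coded indicator features
(first minus second). Part-worths estimated this way are log odds: how much
more likely a scenario is to be judged better when it carries a given option
instead of the reference option (level 1).

Model terms:

* 17 main-effect blocks (width = levels - 1; 36 columns on the canonical
  space);
* the 28 during-sleep x next-day pairwise interactions (140 columns);
* sleeper-type modifier interactions — sleeper indicator x each main-effect
  column (36 columns; the sleeper *main* effect is constant within a trial
  and cancels out of the differenced design);
* question-type modifier interactions, likewise (36 columns);
* a constant primacy intercept (order effect; 1 column) — 249 columns in all.

Nested models are compared by likelihood-ratio tests against chi-squared
reference distributions; attribute importance is ranked by BIC of
single-factor models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .cohort import DURING_SLEEP_PARAMS, NEXT_DAY_PARAMS
from .scenario_space import Scenario, ScenarioSpace, render_narrative

__all__ = [
    "TermSpec",
    "ColumnInfo",
    "DesignMatrix",
    "FitResult",
    "LRTResult",
    "BICRanking",
    "BestScenario",
    "canonical_interaction_pairs",
    "encode_features",
    "build_design",
    "fit_logit",
    "lrt_parameter",
    "lrt_interaction",
    "bic_rank",
    "best_scenario",
]


def canonical_interaction_pairs() -> tuple[tuple[str, str], ...]:
    """The 28 during-sleep x upon-waking/day-after parameter pairs."""
    return tuple((d, n) for d in DURING_SLEEP_PARAMS for n in NEXT_DAY_PARAMS)


@dataclass(frozen=True)
class TermSpec:
    """Which terms enter the choice model."""

    interaction_pairs: tuple[tuple[str, str], ...] = field(
        default_factory=canonical_interaction_pairs
    )
    sleeper_interactions: bool = True
    question_interactions: bool = True
    intercept: bool = True
    main_only_params: tuple[str, ...] | None = None  # None = all parameters

    def validate(self, space: ScenarioSpace) -> None:
        allowed = set(canonical_interaction_pairs())
        for pair in self.interaction_pairs:
            if pair not in allowed:
                raise ValueError(
                    f"interaction pair {pair} outside the during-sleep x "
                    "next-day crossing"
                )
        if self.main_only_params is not None:
            for p in self.main_only_params:
                space.index_of(p)


@dataclass(frozen=True)
class ColumnInfo:
    name: str
    term: Literal["intercept", "main", "pair", "sleeper", "question"]
    params: tuple[str, ...]
    levels: tuple[int, ...]

    def involves(self, parameter: str) -> bool:
        return parameter in self.params


@dataclass
class DesignMatrix:
    X: np.ndarray
    y: np.ndarray
    columns: list[ColumnInfo]
    n_obs: int

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def subset(self, keep: Sequence[int]) -> "DesignMatrix":
        keep = list(keep)
        return DesignMatrix(
            X=self.X[:, keep],
            y=self.y,
            columns=[self.columns[i] for i in keep],
            n_obs=self.n_obs,
        )

    def columns_for_parameter(self, parameter: str) -> list[int]:
        """All column indices whose term involves ``parameter`` (main,
        scenario-pair, sleeper and question interactions)."""
        return [i for i, c in enumerate(self.columns) if c.involves(parameter)]


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

def _params_in_model(space: ScenarioSpace, spec: TermSpec) -> list[str]:
    if spec.main_only_params is None:
        return list(space.names)
    return list(spec.main_only_params)


def _main_columns(space: ScenarioSpace, spec: TermSpec) -> list[ColumnInfo]:
    cols = []
    for name in _params_in_model(space, spec):
        p = space[name]
        for lv in range(2, p.n_levels + 1):
            cols.append(ColumnInfo(f"{name}[{lv}]", "main", (name,), (lv,)))
    return cols


def _pair_columns(space: ScenarioSpace, spec: TermSpec) -> list[ColumnInfo]:
    cols = []
    present = set(_params_in_model(space, spec))
    for pi, pj in spec.interaction_pairs:
        if pi not in present or pj not in present:
            continue
        for li in range(2, space[pi].n_levels + 1):
            for lj in range(2, space[pj].n_levels + 1):
                cols.append(
                    ColumnInfo(f"{pi}[{li}]:{pj}[{lj}]", "pair", (pi, pj), (li, lj))
                )
    return cols


def _indicator_matrix(levels: np.ndarray, space: ScenarioSpace, names: list[str]) -> np.ndarray:
    """Treatment-coded indicators for an (n, P) level matrix, restricted to
    ``names``; width = sum(levels - 1)."""
    blocks = []
    for name in names:
        j = space.index_of(name)
        L = space[name].n_levels
        block = np.zeros((len(levels), L - 1))
        for lv in range(2, L + 1):
            block[:, lv - 2] = levels[:, j] == lv
        blocks.append(block)
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((len(levels), 0))


def _scenario_features(
    levels: np.ndarray, space: ScenarioSpace, spec: TermSpec
) -> tuple[np.ndarray, list[ColumnInfo]]:
    """Within-scenario features: main indicators then pairwise products."""
    names = _params_in_model(space, spec)
    main_cols = _main_columns(space, spec)
    main = _indicator_matrix(levels, space, names)
    pair_cols = _pair_columns(space, spec)
    if pair_cols:
        pairs = np.zeros((len(levels), len(pair_cols)))
        for k, c in enumerate(pair_cols):
            (pi, pj), (li, lj) = c.params, c.levels
            i, j = space.index_of(pi), space.index_of(pj)
            pairs[:, k] = (levels[:, i] == li) & (levels[:, j] == lj)
        feats = np.concatenate([main, pairs], axis=1)
    else:
        feats = main
    return feats, main_cols + pair_cols


def encode_features(
    scenario: Scenario, space: ScenarioSpace, spec: TermSpec | None = None
) -> tuple[np.ndarray, list[ColumnInfo]]:
    """Within-scenario feature vector: treatment-coded indicators for each
    non-reference level, then products of indicator pairs for the configured
    interactions. The all-reference scenario encodes to the zero vector."""
    spec = spec or TermSpec()
    scenario.validate(space)
    levels = np.asarray([scenario.levels])
    feats, cols = _scenario_features(levels, space, spec)
    return feats[0], cols


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(
    dataset: pd.DataFrame, space: ScenarioSpace, spec: TermSpec | None = None
) -> DesignMatrix:
    """Build the differenced paired-comparison design.

    Rows are analysed in the *first-shown* frame: the response is 1 when the
    first-shown scenario was judged better, scenario columns are
    ``features(first) - features(second)``, and the intercept is a constant
    primacy column. Modifier columns multiply the scenario-difference main
    columns by a sleeper indicator (good = 1, poor = 0) or a question
    indicator (worse = 1, better = 0); the modifier *main* effects are
    constant within a trial and cancel from the differenced design.
    """
    spec = spec or TermSpec()
    spec.validate(space)
    needed = {"first_shown", "judged_better", "question_type", "sleeper_group"}
    missing = needed - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    a_cols = [f"a_{n}" for n in space.names]
    b_cols = [f"b_{n}" for n in space.names]
    missing = (set(a_cols) | set(b_cols)) - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset is missing scenario columns: {sorted(missing)}")

    a = dataset[a_cols].to_numpy(dtype=int)
    b = dataset[b_cols].to_numpy(dtype=int)
    first_a = (dataset["first_shown"] == "a").to_numpy()
    first = np.where(first_a[:, None], a, b)
    second = np.where(first_a[:, None], b, a)
    y = (dataset["judged_better"] == dataset["first_shown"]).to_numpy(dtype=float)

    f_first, scen_cols = _scenario_features(first, space, spec)
    f_second, _ = _scenario_features(second, space, spec)
    diff = f_first - f_second

    blocks = [diff]
    columns = list(scen_cols)
    n_main = len(_main_columns(space, spec))
    main_diff = diff[:, :n_main]
    if spec.sleeper_interactions:
        s = (dataset["sleeper_group"] == "good").to_numpy(dtype=float)[:, None]
        blocks.append(main_diff * s)
        columns += [
            ColumnInfo(f"sleeper_good:{c.name}", "sleeper", c.params, c.levels)
            for c in scen_cols[:n_main]
        ]
    if spec.question_interactions:
        q = (dataset["question_type"] == "worse").to_numpy(dtype=float)[:, None]
        blocks.append(main_diff * q)
        columns += [
            ColumnInfo(f"question_worse:{c.name}", "question", c.params, c.levels)
            for c in scen_cols[:n_main]
        ]
    if spec.intercept:
        blocks.append(np.ones((len(dataset), 1)))
        columns.append(ColumnInfo("order_intercept", "intercept", (), ()))
    X = np.concatenate(blocks, axis=1) if len(dataset) else np.zeros((0, sum(bk.shape[1] for bk in blocks)))
    return DesignMatrix(X=X, y=y, columns=columns, n_obs=len(dataset))


# ---------------------------------------------------------------------------
# Maximum-likelihood logistic fit (IRLS / Newton)
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    llf: float
    deviance: float
    n_obs: int
    columns: list[ColumnInfo]
    converged: bool
    separation_warning: bool
    n_iter: int

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [c.term for c in self.columns],
                "parameter": ["|".join(c.params) for c in self.columns],
                "levels": ["|".join(map(str, c.levels)) for c in self.columns],
                "estimate": self.params,
                "se": self.bse,
            },
            index=self.names,
        )

    def part_worths(self, space: ScenarioSpace) -> dict[str, np.ndarray]:
        """Estimated per-level utilities (reference level 0) from the
        main-effect coefficients."""
        out: dict[str, np.ndarray] = {}
        est = dict(zip(self.names, self.params))
        for p in space.parameters:
            w = np.zeros(p.n_levels)
            for lv in range(2, p.n_levels + 1):
                key = f"{p.name}[{lv}]"
                if key in est:
                    w[lv - 1] = est[key]
            out[p.name] = w
        return out


def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logit(
    design: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge_on_separation: bool = True,
    ridge: float = 1e-6,
    start: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Converges when the relative deviance change drops below ``tol`` (at most
    ``max_iter`` iterations, with step-halving on deviance increases).
    Separation is flagged when any coefficient exceeds 15 in magnitude; with
    ``ridge_on_separation`` the model is refit with an L2 penalty of
    ``ridge`` and the flag kept. Wald covariance is the inverse observed
    information.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if p == 0:
        raise ValueError("design has no columns")
    if n <= p:
        warnings.warn(f"n_obs ({n}) <= columns ({p}); estimates unreliable", stacklevel=2)

    def _solve(pen: float) -> tuple[np.ndarray, float, int, bool]:
        beta = np.zeros(p) if start is None else start.astype(float).copy()
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev = _bernoulli_deviance(y, mu) + pen * beta @ beta
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = np.clip(mu * (1 - mu), 1e-10, None)
            XtW = X.T * w
            H = XtW @ X
            if pen:
                H = H + 2 * pen * np.eye(p)
            g = X.T @ (y - mu)
            if pen:
                g = g - 2 * pen * beta
            try:
                step = linalg.solve(H, g, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, g)[0]
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                mu_c = 1.0 / (1.0 + np.exp(-(X @ cand)))
                dev_c = _bernoulli_deviance(y, mu_c) + pen * cand @ cand
                if dev_c <= dev + 1e-12:
                    break
                scale *= 0.5
            beta, mu = cand, mu_c
            prev, dev = dev, dev_c
            if abs(prev - dev) <= tol * (abs(prev) + 1e-10):
                converged = True
                break
        return beta, dev, it, converged

    beta, dev_pen, it, converged = _solve(0.0)
    separation = bool(np.max(np.abs(beta)) > 15)
    if separation and ridge_on_separation:
        beta, dev_pen, it, converged = _solve(ridge)
    if not converged and not ridge_on_separation:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(max |coef| = {np.max(np.abs(beta)):.2f})"
        )
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    deviance = _bernoulli_deviance(y, mu)
    llf = -0.5 * deviance
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X.T * w) @ X
    try:
        cov = linalg.inv(H)
    except linalg.LinAlgError:
        cov = linalg.pinv(H)
    bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    return FitResult(
        params=beta,
        bse=bse,
        cov=cov,
        llf=llf,
        deviance=deviance,
        n_obs=n,
        columns=design.columns,
        converged=converged,
        separation_warning=separation,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTResult:
    name: str
    statistic: float
    df: int
    p_value: float
    alpha: float
    dropped_columns: tuple[str, ...]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _lrt_from_designs(
    design: DesignMatrix,
    drop: Sequence[int],
    name: str,
    alpha: float,
    full_fit: FitResult | None = None,
) -> LRTResult:
    if full_fit is None:
        full_fit = fit_logit(design)
    keep = [i for i in range(design.X.shape[1]) if i not in set(drop)]
    if not keep:
        # degenerate: restricted model is the empty (intercept-free) null
        mu0 = np.full(design.n_obs, 0.5)
        dev_r = _bernoulli_deviance(design.y, mu0)
    else:
        warm = full_fit.params[keep]
        restricted = fit_logit(design.subset(keep), start=warm)
        dev_r = restricted.deviance
    stat = max(dev_r - full_fit.deviance, 0.0)
    df = len(drop)
    if df < 1:
        return LRTResult(name, 0.0, 0, 1.0, alpha, ())
    p = float(chi2.sf(stat, df))
    return LRTResult(
        name, float(stat), df, p, alpha, tuple(design.names[i] for i in drop)
    )


def lrt_parameter(
    dataset: pd.DataFrame | DesignMatrix,
    space: ScenarioSpace,
    spec: TermSpec | None = None,
    parameter: str = "",
    alpha: float = 0.01,
    full_fit: FitResult | None = None,
) -> LRTResult:
    """Joint LRT for one scenario parameter: the restricted model drops the
    parameter's main-effect block *and* every interaction column involving it
    (scenario-pair, sleeper and question). The statistic (difference in
    deviances) is referred to chi-squared with df = number of dropped
    columns."""
    spec = spec or TermSpec()
    design = dataset if isinstance(dataset, DesignMatrix) else build_design(dataset, space, spec)
    space.index_of(parameter)  # raises KeyError if unknown
    drop = design.columns_for_parameter(parameter)
    return _lrt_from_designs(design, drop, parameter, alpha, full_fit)


def lrt_interaction(
    dataset: pd.DataFrame | DesignMatrix,
    space: ScenarioSpace,
    spec: TermSpec | None = None,
    pair: tuple[str, str] = ("", ""),
    alpha: float = 0.01,
    full_fit: FitResult | None = None,
) -> LRTResult:
    """LRT for a single interaction block.

    ``pair`` is either two scenario parameters (a during-sleep x next-day
    pair), or ``(parameter, "sleeper")`` / ``(parameter, "question")`` for a
    modifier block.
    """
    spec = spec or TermSpec()
    design = dataset if isinstance(dataset, DesignMatrix) else build_design(dataset, space, spec)
    p1, p2 = pair
    if p2 in ("sleeper", "question"):
        drop = [
            i
            for i, c in enumerate(design.columns)
            if c.term == p2 and c.params == (p1,)
        ]
    else:
        drop = [
            i
            for i, c in enumerate(design.columns)
            if c.term == "pair" and c.params == (p1, p2)
        ]
    if not drop:
        raise ValueError(f"no columns found for interaction {pair}")
    return _lrt_from_designs(design, drop, f"{p1}:{p2}", alpha, full_fit)


# ---------------------------------------------------------------------------
# BIC importance ranking
# ---------------------------------------------------------------------------

@dataclass
class BICRanking:
    table: pd.DataFrame  # columns: entity, k, llf, bic; ascending bic

    @property
    def order(self) -> list[str]:
        return list(self.table["entity"])


def bic_rank(
    dataset: pd.DataFrame,
    space: ScenarioSpace,
    entities: Literal["parameters", "periods"] = "parameters",
    intercept: bool = True,
) -> BICRanking:
    """Rank individual parameters (or whole time periods) by the BIC of
    single-factor logistic models.

    Each entity's model contains only its main-effect block(s) plus the
    primacy intercept; BIC = -2 LL + k ln(n) with k the number of fitted
    coefficients. Lower BIC = more important.
    """
    if entities == "parameters":
        groups = [(name, (name,)) for name in space.names]
    elif entities == "periods":
        from .scenario_space import PERIODS

        groups = [(per, space.names_in_period(per)) for per in PERIODS]
    else:
        raise ValueError("entities must be 'parameters' or 'periods'")
    rows = []
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    for entity, names in groups:
        spec = TermSpec(
            interaction_pairs=(),
            sleeper_interactions=False,
            question_interactions=False,
            intercept=intercept,
            main_only_params=tuple(names),
        )
        design = build_design(dataset, space, spec)
        fit = fit_logit(design)
        k = design.X.shape[1]
        bic = -2.0 * fit.llf + k * math.log(n)
        rows.append({"entity": entity, "k": k, "llf": fit.llf, "bic": bic})
    table = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    return BICRanking(table=table)


# ---------------------------------------------------------------------------
# Best-preferred scenario synthesis
# ---------------------------------------------------------------------------

@dataclass
class BestScenario:
    scenario: Scenario
    narrative: str
    significant: dict[str, bool]


def best_scenario(
    fit: FitResult,
    lrt_results: Sequence[LRTResult],
    space: ScenarioSpace,
) -> BestScenario:
    """Synthesise the best-preferred scenario from a fitted model.

    For each parameter the level with the maximal estimated part-worth is
    selected (the reference level counts as 0; ties break toward the lower
    level index). The significance mask marks parameters whose joint LRT
    passed at its alpha; the rendered narrative highlights only those."""
    pw = fit.part_worths(space)
    levels = []
    for p in space.parameters:
        w = pw[p.name]
        levels.append(int(np.argmax(w)) + 1)  # argmax returns first max: low-index tie-break
    scen = Scenario(levels=tuple(levels))
    sig = {r.name: r.significant for r in lrt_results}
    mask = {p.name: sig.get(p.name, False) for p in space.parameters}
    narrative = render_narrative(scen, space, highlight=[k for k, v in mask.items() if v])
    return BestScenario(scenario=scen, narrative=narrative, significant=mask)
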