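"""Gelman–Rubin / Brooks–Gelman potential scale reduction diagnostics and the
burn-in selection rule for MCMCP chains.

Scenario states are coded numerically as their 1-based level indices, one
coordinate per parameter. The univariate diagnostic is the variance-based
corrected form

    Rhat = sqrt( ((n-1)/n + B/(n W)) * (df+3)/(df+1) ),

with ``W`` the mean within-chain variance, ``B = n * Var(chain means)`` the
between-chain variance, and ``df`` estimated by method of moments from the
sampling variance of the pooled variance estimate. The multivariate version
(MPSRF) replaces ``B/W`` with the largest eigenvalue of ``W^{-1} B`` and
omits the df correction. The interval-based variant of the diagnostic exists;
this package implements the variance-based form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PSRFResult",
    "psrf",
    "mpsrf",
    "chain_matrices",
    "select_burn_in",
]


@dataclass(frozen=True)
class PSRFResult:
    rhat: float
    B: float | np.ndarray
    W: float | np.ndarray
    n: int
    m: int
    multivariate: bool = False


def _check_shape(x: np.ndarray, min_n: int = 4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains (first axis)")
    if x.shape[1] < min_n:
        raise ValueError(f"need chain length >= {min_n}")
    return x


def psrf(chains: np.ndarray) -> PSRFResult:
    """Univariate corrected potential scale reduction factor.

    ``chains`` has shape (m, n): m parallel chains of length n. Constant
    identical chains give Rhat = 1; constant chains at different values give
    Rhat = inf.
    """
    x = _check_shape(chains)
    if x.ndim != 2:
        raise ValueError("psrf expects a 2-D (m, n) array")
    m, n = x.shape
    means = x.mean(axis=1)
    vars_ = x.var(axis=1, ddof=1)
    W = float(vars_.mean())
    B = float(n * means.var(ddof=1))
    if W == 0.0:
        return PSRFResult(1.0 if B == 0.0 else np.inf, B, W, n, m)
    # Pooled-variance estimate and its method-of-moments degrees of freedom.
    V = (n - 1) / n * W + B / n
    var_W = vars_.var(ddof=1) / m if m > 1 else 0.0
    var_B = 2.0 * B**2 / (m - 1)
    xbar = float(means.mean())
    cov_WB = n / m * (np.cov(vars_, means**2, ddof=1)[0, 1] - 2 * xbar * np.cov(vars_, means, ddof=1)[0, 1])
    var_V = (
        ((n - 1) / n) ** 2 * var_W
        + (1 / n) ** 2 * var_B
        + 2 * ((n - 1) / n) * (1 / n) * cov_WB
    )
    if var_V <= 0:
        correction = 1.0
    else:
        df = 2 * V**2 / var_V
        correction = (df + 3) / (df + 1)
    rhat = float(np.sqrt(((n - 1) / n + B / (n * W)) * correction))
    return PSRFResult(rhat, B, W, n, m)


def mpsrf(chains: np.ndarray, ridge: float = 1e-10) -> PSRFResult:
    """Multivariate potential scale reduction factor.

    ``chains`` has shape (m, n, d). Computes
    ``sqrt((n-1)/n + lambda_max(W^{-1} B)/n)`` with ``W`` the pooled
    within-chain covariance and ``B/n`` the covariance of chain means. A
    singular ``W`` is ridge-stabilised (with a warning). For d = 1 this
    reduces to the univariate Rhat without the df correction.
    """
    x = _check_shape(chains)
    if x.ndim == 2:
        x = x[:, :, None]
    m, n, d = x.shape
    if n <= d:
        warnings.warn("chain length <= dimension; W is rank-deficient", stacklevel=2)
    means = x.mean(axis=1)  # (m, d)
    W = np.zeros((d, d))
    for j in range(m):
        dev = x[j] - means[j]
        W += dev.T @ dev / (n - 1)
    W /= m
    grand = means.mean(axis=0)
    devm = means - grand
    B = n * (devm.T @ devm) / (m - 1)  # (d, d), "B" on the chain-length scale
    if np.all(W == 0):
        same = np.allclose(B, 0)
        return PSRFResult(1.0 if same else np.inf, B, W, n, m, multivariate=True)
    try:
        lam = _lambda_max(W, B)
    except np.linalg.LinAlgError:
        lam = None
    if lam is None or not np.isfinite(lam):
        warnings.warn("within-chain covariance singular; ridge-stabilising", stacklevel=2)
        W = W + ridge * max(np.trace(W) / d, 1.0) * np.eye(d)
        lam = _lambda_max(W, B)
    rhat = float(np.sqrt((n - 1) / n + lam / n))
    return PSRFResult(rhat, B, W, n, m, multivariate=True)


def _lambda_max(W: np.ndarray, B: np.ndarray) -> float:
    from scipy.linalg import eigh

    # Largest generalised eigenvalue of B v = lambda W v.
    vals = eigh(B, W, eigvals_only=True)
    return float(vals[-1])


# ---------------------------------------------------------------------------
# Chain extraction and burn-in selection
# ---------------------------------------------------------------------------

def chain_matrices(
    dataset: pd.DataFrame,
    question_type: str | None = None,
    level_columns_prefix: str = "a_",
) -> np.ndarray:
    """Stack per-chain state sequences from a choice dataset.

    The state *after* trial t is the chosen scenario of that trial; rows are
    assumed to be in generation order within each chain. Returns an
    (m, n, d) array truncated to the shortest chain, where d is the number of
    scenario parameters.
    """
    df = dataset
    if question_type is not None:
        df = df[df["question_type"] == question_type]
    a_cols = [c for c in df.columns if c.startswith("a_")]
    b_cols = ["b_" + c[2:] for c in a_cols]
    seqs = []
    for _, sub in df.groupby("chain_id", sort=True):
        a = sub[a_cols].to_numpy(dtype=float)
        b = sub[b_cols].to_numpy(dtype=float)
        chose_b = (sub["chosen"] == "b").to_numpy()
        states = np.where(chose_b[:, None], b, a)
        seqs.append(states)
    if len(seqs) < 2:
        raise ValueError("need >= 2 chains per stratum for the diagnostic")
    n = min(len(s) for s in seqs)
    return np.stack([s[:n] for s in seqs])


def select_burn_in(
    dataset: pd.DataFrame,
    threshold: float = 1.2,
    trials_per_participant_block: int = 12,
    floor: int = 1,
    per_question: bool = True,
) -> dict:
    """Choose burn-in in whole participant blocks per chain.

    Scans b = floor, floor+1, ... and returns the smallest b such that the
    MPSRF of the post-burn-in states is below ``threshold`` — computed
    separately per question type ("better" and "worse" chains target
    different distributions) and pooled across sleeper groups; the reported
    burn-in is the worst stratum's. A floor of one participant per chain is
    enforced by default (the first participant seeds the chains). If the
    threshold is never reached the full-length flag is set and a warning
    issued.

    Returns a dict with keys ``burn_in`` (participants per chain),
    ``reached`` (bool) and ``mpsrf`` (per-stratum trace of MPSRF vs b).
    """
    strata = ["better", "worse"] if per_question else [None]
    per_stratum: dict = {}
    burn = floor
    reached = True
    for q in strata:
        x = chain_matrices(dataset, question_type=q)
        m, n, d = x.shape
        max_blocks = n // trials_per_participant_block
        trace = []
        found = None
        for b in range(floor, max_blocks):
            sub = x[:, b * trials_per_participant_block :, :]
            if sub.shape[1] < max(4, 2):
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = mpsrf(sub).rhat
            trace.append((b, r))
            if r < threshold:
                found = b
                break
        key = q or "all"
        per_stratum[key] = trace
        if found is None:
            reached = False
            warnings.warn(
                f"MPSRF threshold {threshold} not reached for stratum {key!r}",
                stacklevel=2,
            )
            burn = max(burn, max_blocks)
        else:
            burn = max(burn, found)
    return {"burn_in": burn, "reached": reached, "mpsrf": per_stratum}
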