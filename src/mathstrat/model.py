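"""Two-strategy process-dissociation model of arithmetic verification.

Each trial of single-digit addition verification (operands 2-9, max RT 9.5 s)
is modeled as a probabilistic choice between two latent strategies — direct
memory retrieval and min-counting — each realized as its own drift-diffusion
process with a shared decision threshold.  Strategy selection is logistic in
the difference between an individual's retrieval propensity rho_i and the
item's group-level retrieval difficulty rho_k.  Counting carries an extra
non-decision component, the strategy-switching time.

The trial likelihood is the two-component mixture of defective Wiener
first-passage densities at the boundary implied by response correctness
(upper = correct).  Posterior strategy responsibilities follow by Bayes rule
trial by trial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wiener import WienerParams, wiener_pdf, _wiener_logpdf_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualParams",
    "ItemParams",
    "p_memory_retrieval",
    "memory_drift_rate",
    "counting_drift_rate",
    "trial_likelihood",
    "trial_loglik",
    "strategy_responsibility",
    "retrieval_use_summary",
    "preprocess_trials",
    "read_trials",
    "write_trials",
]

#: RTs below this (seconds) are anticipatory and treated as missing
RT_MISSING_BELOW = 0.300
#: the task's response deadline; longer RTs are invalid records
RT_MAX = 9.5

TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "item_id",
    "addend_a",
    "addend_b",
    "equation_valid",
    "response_correct",
    "rt_seconds",
]


@dataclass(frozen=True)
class ItemParams:
    """Group-level item: min-addend count steps n_k and retrieval difficulty rho_k."""

    item_id: str
    n_k: int
    rho_k: float

    def __post_init__(self) -> None:
        if self.n_k < 1:
            raise ValueError(f"n_k must be >= 1, got {self.n_k}")
        if not np.isfinite(self.rho_k):
            raise ValueError("rho_k must be finite")


@dataclass(frozen=True)
class IndividualParams:
    """Per participant-session latent vector of the strategy model.

    rho_i        retrieval propensity (logit scale)
    delta_M      memory-retrieval efficiency (> 0)
    delta_C      counting efficiency (> 0)
    alpha        decision threshold (> 0)
    tau          base non-decision time, seconds (> 0)
    tau_switch   strategy-switching time added to counting, seconds (>= 0)
    bias         diffusion start point as a fraction of alpha; 0.5 by default
    """

    rho_i: float
    delta_M: float
    delta_C: float
    alpha: float
    tau: float
    tau_switch: float
    bias: float = 0.5

    def __post_init__(self) -> None:
        if not (self.delta_M > 0 and self.delta_C > 0):
            raise ValueError("delta_M and delta_C must be positive")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if not (self.tau_switch >= 0):
            raise ValueError("tau_switch must be non-negative")
        if not (0.0 < self.bias < 1.0):
            raise ValueError("bias must lie in (0, 1)")


def p_memory_retrieval(rho_i, rho_k):
    """Probability of selecting the memory-retrieval strategy,
    1 / (1 + exp(-(rho_i - rho_k))).  Overflow-safe; counting probability is
    the complement."""
    x = np.asarray(rho_i, dtype=float) - np.asarray(rho_k, dtype=float)
    # logistic via tanh avoids overflow for large |x|
    out = 0.5 * (1.0 + np.tanh(x / 2.0))
    return float(out) if out.ndim == 0 else out


def memory_drift_rate(delta_M, rho_k):
    """Item-conditional retrieval drift delta_M / (1 + exp(rho_k))."""
    dM = np.asarray(delta_M, dtype=float)
    if np.any(dM <= 0):
        raise ValueError("delta_M must be positive")
    out = dM * 0.5 * (1.0 + np.tanh(-np.asarray(rho_k, dtype=float) / 2.0))
    return float(out) if out.ndim == 0 else out


def counting_drift_rate(delta_C, n_k):
    """Min-counting drift delta_C / n_k (n_k = smaller addend)."""
    dC = np.asarray(delta_C, dtype=float)
    nk = np.asarray(n_k)
    if np.any(dC <= 0):
        raise ValueError("delta_C must be positive")
    if np.any(nk < 1):
        raise ValueError("n_k must be >= 1")
    out = dC / nk.astype(float)
    return float(out) if out.ndim == 0 else out


def _components(rt: float, correct: bool, ip: IndividualParams, item: ItemParams):
    """Mixture weight and the two defective component densities at this trial."""
    p_m = p_memory_retrieval(ip.rho_i, item.rho_k)
    v_m = memory_drift_rate(ip.delta_M, item.rho_k)
    v_c = counting_drift_rate(ip.delta_C, item.n_k)
    boundary = "correct" if correct else "error"
    f_m = wiener_pdf(rt, boundary, WienerParams(ip.alpha, v_m, ip.tau, ip.bias))
    f_c = wiener_pdf(
        rt, boundary, WienerParams(ip.alpha, v_c, ip.tau + ip.tau_switch, ip.bias)
    )
    return p_m, float(f_m), float(f_c)


def trial_likelihood(rt, correct, ip: IndividualParams, item: ItemParams) -> float:
    """Mixture likelihood p_M * f_memory + (1 - p_M) * f_counting of one trial.

    ``rt`` may be NaN (missing after preprocessing), in which case NaN is
    returned and the trial is to be excluded from any likelihood product.
    """
    if rt is None or (isinstance(rt, float) and math.isnan(rt)):
        return float("nan")
    p_m, f_m, f_c = _components(float(rt), bool(correct), ip, item)
    return p_m * f_m + (1.0 - p_m) * f_c


def trial_loglik(rt, correct, ip: IndividualParams, item: ItemParams) -> float:
    """Log of :func:`trial_likelihood` (NaN propagates for missing RTs)."""
    lik = trial_likelihood(rt, correct, ip, item)
    if math.isnan(lik):
        return float("nan")
    return math.log(lik) if lik > 0 else -math.inf


def strategy_responsibility(rt, correct, ip: IndividualParams, item: ItemParams) -> float:
    """Posterior probability that the trial used memory retrieval.

    Returns NaN (with a warning) when both component densities are zero —
    the trial is impossible under either strategy.
    """
    if rt is None or (isinstance(rt, float) and math.isnan(rt)):
        return float("nan")
    p_m, f_m, f_c = _components(float(rt), bool(correct), ip, item)
    num = p_m * f_m
    den = num + (1.0 - p_m) * f_c
    if den == 0.0:
        logger.warning(
            "both strategy likelihoods are zero at rt=%.3f; responsibility undefined", rt
        )
        return float("nan")
    return num / den


def retrieval_use_summary(
    trials: pd.DataFrame,
    params: dict,
    items: dict,
    *,
    method: str = "mean",
) -> pd.Series:
    """Per participant-session summary of memory-retrieval use in [0, 1].

    Parameters
    ----------
    trials : preprocessed trial table (see :data:`TRIAL_COLUMNS`).
    params : mapping (participant_id, session) -> IndividualParams.
    items : mapping item_id -> ItemParams.
    method : "mean" (mean posterior responsibility, default) or "classify"
        (fraction of trials with responsibility > 0.5).

    Groups with no valid trial come back as NaN.
    """
    if method not in ("mean", "classify"):
        raise ValueError("method must be 'mean' or 'classify'")
    out = {}
    for (pid, sess), grp in trials.groupby(["participant_id", "session"], sort=True):
        ip = params[(pid, sess)]
        resp = [
            strategy_responsibility(row.rt_seconds, row.response_correct, ip, items[row.item_id])
            for row in grp.itertuples()
        ]
        resp = np.asarray(resp, dtype=float)
        resp = resp[~np.isnan(resp)]
        if resp.size == 0:
            out[(pid, sess)] = float("nan")
        elif method == "mean":
            out[(pid, sess)] = float(resp.mean())
        else:
            out[(pid, sess)] = float((resp > 0.5).mean())
    idx = pd.MultiIndex.from_tuples(out.keys(), names=["participant_id", "session"])
    return pd.Series(list(out.values()), index=idx, name="retrieval_use")


def preprocess_trials(raw: pd.DataFrame) -> pd.DataFrame:
    """Validate and clean a raw trial table.

    * RTs below 300 ms are set to NaN (missing for inference; the record stays).
    * RTs above the 9.5 s deadline are invalid records and are dropped.
    * Malformed rows (non-numeric addends, addends outside 2-9, nonpositive RT)
      are dropped and reported with their row positions.

    Exclusion counts are logged and attached as ``DataFrame.attrs['exclusions']``.
    """
    df = raw.copy()
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trial table missing columns: {missing_cols}")
    bad_rows = []
    for col in ("addend_a", "addend_b"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 2) | (vals > 9)
        bad_rows.extend(df.index[bad].tolist())
        df[col] = vals
    rt = pd.to_numeric(df["rt_seconds"], errors="coerce")
    neg = rt.notna() & (rt <= 0)
    bad_rows.extend(df.index[neg].tolist())
    too_slow = rt.notna() & (rt > RT_MAX)
    if bad_rows:
        logger.warning("dropping %d malformed rows at positions %s", len(set(bad_rows)), sorted(set(bad_rows)))
    n_slow = int(too_slow.sum())
    if n_slow:
        logger.info("dropping %d invalid records with rt > %.1f s", n_slow, RT_MAX)
    keep = ~df.index.isin(set(bad_rows)) & ~too_slow
    df = df.loc[keep].copy()
    rt = rt.loc[df.index]
    fast = rt.notna() & (rt < RT_MISSING_BELOW)
    n_fast = int(fast.sum())
    if n_fast:
        logger.info("marking %d anticipatory RTs (< %d ms) missing", n_fast, int(RT_MISSING_BELOW * 1000))
    rt[fast] = np.nan
    df["rt_seconds"] = rt
    df["addend_a"] = df["addend_a"].astype(int)
    df["addend_b"] = df["addend_b"].astype(int)
    df["response_correct"] = df["response_correct"].astype(bool)
    df["equation_valid"] = df["equation_valid"].astype(bool)
    df = df.reset_index(drop=True)
    df.attrs["exclusions"] = {
        "malformed": len(set(bad_rows)),
        "rt_over_max": n_slow,
        "rt_marked_missing": n_fast,
    }
    return df


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV (missing RT encoded as empty field) and preprocess it."""
    raw = pd.read_csv(path)
    return preprocess_trials(raw)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)
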