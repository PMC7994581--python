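"""Synthetic cohorts with the statistical structure the analysis assumes.

Emulates the study conditions end to end: a 35-child pre/post cohort solving
single-digit addition verification problems (operands 2-9, 9.5 s deadline),
individual strategy-model parameters drawn from hierarchical distributions
with training-effect shifts, and per-participant signed 30-node task networks
with a planted 2-module (pre) to 3-module (post) reorganization.  A designated
hippocampal node's post-training diversity coefficient is coupled to the
participant's memory-efficiency gain, providing ground truth for the joint
brain-behavior model.

Every generator is deterministic given (spec, seed).  Ground truth (strategy
labels, true parameters, true partitions, true diversity changes) is returned
separately from the "observed" tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .model import RT_MAX, p_memory_retrieval, memory_drift_rate, counting_drift_rate
from .network import ConnectivityMatrix, Partition

__all__ = [
    "CohortSpec",
    "NODE_LABELS",
    "generate_item_bank",
    "sample_population",
    "simulate_behavior",
    "simulate_networks",
    "simulate_roi_timeseries",
]

# 18 cortical regions from an arithmetic meta-analysis plus 12 MTL subregions
NODE_LABELS = [
    "L_SPL", "R_SPL", "L_IPS", "R_IPS", "L_AI", "R_AI", "L_IFG", "R_IFG",
    "L_DMPFC", "R_DMPFC", "L_FEF", "R_FEF", "L_ITG", "R_ITG", "L_LOC", "R_LOC",
    "L_MFG", "R_MFG",
    "L_cPHG", "R_cPHG", "L_lpPHG", "R_lpPHG", "L_EC", "R_EC",
    "L_mpPHG", "R_mpPHG", "L_rHipp", "R_rHipp", "L_cHipp", "R_cHipp",
]


def _default_hyper() -> dict:
    # (mean, sd) of pre-level and pre->post change distributions; training
    # raises retrieval propensity and retrieval efficiency, leaves counting
    # and caution roughly unchanged
    return {
        "rho_pre": (-0.2, 0.8),
        "d_rho": (0.5, 0.5),
        "delta_M_pre": (1.3, 0.3),
        "d_delta_M": (0.5, 0.2),
        "delta_C_pre": (2.2, 0.4),
        "d_delta_C": (0.1, 0.2),
        "alpha_pre": (1.6, 0.25),
        "d_alpha": (-0.1, 0.15),
        "tau": (0.35, 0.05),
        "tau_switch_pre": (0.35, 0.12),
        "d_tau_switch": (-0.05, 0.08),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions of the synthetic study."""

    n_participants: int = 35
    trials_per_session: int = 24
    addend_min: int = 2
    addend_max: int = 9
    item_rho_mean: float = 0.0
    item_rho_sd: float = 0.8
    hyper: dict = field(default_factory=_default_hyper)
    # network block model
    n_nodes: int = 30
    pre_blocks: tuple = ((0, 18), (18, 30))          # cortical vs MTL
    post_blocks: tuple = ((0, 10), (10, 20), (20, 30))
    within_mean: float = 0.35
    between_mean: float = 0.05
    edge_noise_sd: float = 0.15
    # coupling of the designated node's diversity change to memory-efficiency gain
    coupled_node: str = "R_rHipp"
    coupling_beta: float = -0.8
    coupling_resid_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (_, sd) in self.hyper.items():
            if sd <= 0:
                raise ValueError(f"variance parameter for {name} must be positive")
        covered = sorted(i for lo, hi in self.pre_blocks for i in range(lo, hi))
        covered_post = sorted(i for lo, hi in self.post_blocks for i in range(lo, hi))
        if covered != list(range(self.n_nodes)) or covered_post != list(range(self.n_nodes)):
            raise ValueError("block partitions must cover all nodes")


def generate_item_bank(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """All unique unordered addend pairs with sampled retrieval difficulties.

    Columns: item_id, addend_a (<= addend_b), addend_b, n_k, rho_k (truth).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for a in range(spec.addend_min, spec.addend_max + 1):
        for b in range(a, spec.addend_max + 1):
            rows.append({"item_id": f"{a}+{b}", "addend_a": a, "addend_b": b, "n_k": a})
    items = pd.DataFrame(rows)
    items["rho_k"] = rng.normal(spec.item_rho_mean, spec.item_rho_sd, len(items))
    return items


_PARAM_NAMES = list(_default_hyper().keys())


def sample_population(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw true per-participant parameters for pre and post sessions.

    Positivity of delta_M, delta_C, alpha (both sessions), tau, and of the
    post-session switching time is enforced by rejection (truncation); an
    infeasible configuration (acceptance ~ 0) raises.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for i in range(spec.n_participants):
        for _ in range(1000):
            d = {p: rng.normal(*spec.hyper[p]) for p in _PARAM_NAMES}
            ok = (
                d["delta_M_pre"] > 0 and d["delta_M_pre"] + d["d_delta_M"] > 0
                and d["delta_C_pre"] > 0 and d["delta_C_pre"] + d["d_delta_C"] > 0
                and d["alpha_pre"] > 0 and d["alpha_pre"] + d["d_alpha"] > 0
                and d["tau"] > 0.05
                and d["tau_switch_pre"] >= 0
                and d["tau_switch_pre"] + d["d_tau_switch"] >= 0
            )
            if ok:
                break
        else:
            raise ValueError("truncation region has negligible mass; check hyperparameters")
        d["participant_id"] = f"p{i:02d}"
        rows.append(d)
    return pd.DataFrame(rows).set_index("participant_id")


@njit(cache=True)
def _sim_fpt_batch(drift, alpha, dt, seed, t_max, shift):
    """Euler-Maruyama first passage for a batch of trials (unbiased start)."""
    np.random.seed(seed)
    n = drift.shape[0]
    rts = np.empty(n)
    upper = np.zeros(n, dtype=np.bool_)
    sdt = math.sqrt(dt)
    for i in range(n):
        a = alpha[i]
        lo = shift
        hi = a - shift
        x = 0.5 * a
        t = 0.0
        v = drift[i]
        while True:
            x += v * dt + sdt * np.random.normal()
            t += dt
            if x >= hi:
                rts[i] = t
                upper[i] = True
                break
            if x <= lo:
                rts[i] = t
                upper[i] = False
                break
            if t > t_max:
                rts[i] = np.nan
                break
    return rts, upper


def simulate_behavior(
    participants: pd.DataFrame,
    items: pd.DataFrame,
    spec: CohortSpec,
    seed: int | None = None,
    *,
    dt: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two-step generative process for every participant-session.

    Per trial: Bernoulli strategy draw with p_memory_retrieval, then a
    first-passage simulation of the selected strategy's diffusion (counting
    non-decision time = tau + tau_switch).  RTs beyond the 9.5 s deadline are
    censored at the deadline and marked.

    Returns (observed trial table, truth table with strategy labels).
    """
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    item_idx = rng.integers(0, len(items), size=(spec.n_participants, 2, spec.trials_per_session))

    pids = list(participants.index)
    rec_drift, rec_alpha, rec_tau_eff, meta = [], [], [], []
    for pi, pid in enumerate(pids):
        row = participants.loc[pid]
        for si, sess in enumerate(("pre", "post")):
            s = 1 if sess == "post" else 0
            rho_i = row["rho_pre"] + s * row["d_rho"]
            dM = row["delta_M_pre"] + s * row["d_delta_M"]
            dC = row["delta_C_pre"] + s * row["d_delta_C"]
            alpha = row["alpha_pre"] + s * row["d_alpha"]
            tau = row["tau"]
            tsw = row["tau_switch_pre"] + s * row["d_tau_switch"]
            for t_i in range(spec.trials_per_session):
                it = items.iloc[item_idx[pi, si, t_i]]
                p_m = p_memory_retrieval(rho_i, it["rho_k"])
                use_memory = rng.random() < p_m
                if use_memory:
                    v = memory_drift_rate(dM, it["rho_k"])
                    tau_eff = tau
                else:
                    v = counting_drift_rate(dC, it["n_k"])
                    tau_eff = tau + tsw
                rec_drift.append(v)
                rec_alpha.append(alpha)
                rec_tau_eff.append(tau_eff)
                meta.append((pid, sess, it["item_id"], int(it["addend_a"]), int(it["addend_b"]),
                             bool(rng.random() < 0.5), use_memory))

    shift = 0.5826 * math.sqrt(dt)
    dec_t, upper = _sim_fpt_batch(
        np.asarray(rec_drift), np.asarray(rec_alpha), dt,
        int(rng.integers(0, 2**31 - 1)), 30.0, shift,
    )
    rt = np.asarray(rec_tau_eff) + dec_t
    censored = ~np.isfinite(rt) | (rt > RT_MAX)
    rt_obs = np.where(censored, np.nan, rt)

    obs = pd.DataFrame(meta, columns=[
        "participant_id", "session", "item_id", "addend_a", "addend_b",
        "equation_valid", "true_memory"])
    truth = obs[["participant_id", "session", "item_id"]].copy()
    truth["true_memory"] = obs.pop("true_memory")
    truth["censored"] = censored
    truth["rt_uncensored"] = rt
    obs["response_correct"] = upper
    obs["rt_seconds"] = rt_obs
    obs = obs[["participant_id", "session", "item_id", "addend_a", "addend_b",
               "equation_valid", "response_correct", "rt_seconds"]]
    return obs, truth


def _block_partition(blocks, n_nodes) -> np.ndarray:
    aff = np.empty(n_nodes, dtype=int)
    for m, (lo, hi) in enumerate(blocks, start=1):
        aff[lo:hi] = m
    return aff


def _block_matrix(rng, aff, spec: CohortSpec) -> np.ndarray:
    n = spec.n_nodes
    same = aff[:, None] == aff[None, :]
    mean = np.where(same, spec.within_mean, spec.between_mean)
    noise = rng.normal(0.0, spec.edge_noise_sd, (n, n))
    w = mean + noise
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


def _node_diversity(W: np.ndarray, aff: np.ndarray, node: int) -> float:
    pos = np.clip(W[node], 0.0, None)
    mods = np.unique(aff)
    s = np.array([pos[aff == m].sum() for m in mods])
    tot = s.sum()
    if tot <= 0 or len(mods) < 2:
        return 0.0
    q = s[s > 0] / tot
    return float(-(q * np.log(q)).sum() / np.log(len(mods)))


def _solve_own_share(target_h: float) -> float:
    """Own-module share p (other two modules split equally) whose 3-module
    positive-strength entropy equals target_h; h is monotone decreasing on
    [1/3, 1)."""
    def h(p):
        if p >= 1.0 - 1e-12:
            return 0.0
        q = np.array([p, (1 - p) / 2, (1 - p) / 2])
        q = q[q > 0]
        return float(-(q * np.log(q)).sum() / np.log(3.0))
    lo, hi = 1.0 / 3.0, 1.0 - 1e-9
    target_h = min(max(target_h, 0.0), 1.0)
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if h(mid) > target_h:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_networks(
    spec: CohortSpec,
    true_changes: pd.DataFrame,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Per-participant pre/post signed connectivity with planted structure.

    Pre matrices follow the 2-block structure, post matrices the 3-block
    structure.  The designated node's post-training positive weights are set
    so that its diversity change equals beta * d_delta_M + residual noise
    (clipped, with a warning, to the feasible entropy range).

    Parameters
    ----------
    true_changes : DataFrame indexed by participant_id with a ``d_delta_M``
        column (from :func:`sample_population`).

    Returns
    -------
    matrices : dict mapping (participant_id, session) -> ConnectivityMatrix
    truth : DataFrame per participant with true pre/post diversity of the
        coupled node and its planted change; ``attrs['partitions']`` holds the
        true module affiliations.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    labels = NODE_LABELS[: spec.n_nodes]
    node = labels.index(spec.coupled_node)
    aff_pre = _block_partition(spec.pre_blocks, spec.n_nodes)
    aff_post = _block_partition(spec.post_blocks, spec.n_nodes)
    own_post = aff_post[node]
    post_mods = np.unique(aff_post)

    matrices: dict = {}
    rows = []
    import warnings

    for pid in true_changes.index:
        w_pre = _block_matrix(rng, aff_pre, spec)
        w_post = _block_matrix(rng, aff_post, spec)
        div_pre = _node_diversity(w_pre, aff_pre, node)
        d_dm = float(true_changes.loc[pid, "d_delta_M"])
        target = div_pre + spec.coupling_beta * d_dm + rng.normal(0.0, spec.coupling_resid_sd)
        clipped = min(max(target, 0.0), 1.0)
        if clipped != target:
            warnings.warn(f"planted diversity target {target:.3f} clipped to [0, 1] for {pid}")
        # rewrite the designated node's positive row: own-module share p,
        # remainder split equally across the other two modules
        p_share = _solve_own_share(clipped)
        total_pos = np.clip(w_post[node], 0.0, None).sum()
        new_row = np.zeros(spec.n_nodes)
        others = [m for m in post_mods if m != own_post]
        for m in post_mods:
            members = np.where((aff_post == m) & (np.arange(spec.n_nodes) != node))[0]
            share = p_share if m == own_post else (1.0 - p_share) / len(others)
            new_row[members] = share * total_pos / len(members)
        w_post[node, :] = new_row
        w_post[:, node] = new_row
        w_post[node, node] = 0.0
        div_post = _node_diversity(w_post, aff_post, node)
        matrices[(pid, "pre")] = ConnectivityMatrix(w_pre, labels, pid, "pre")
        matrices[(pid, "post")] = ConnectivityMatrix(w_post, labels, pid, "post")
        rows.append({"participant_id": pid, "div_pre": div_pre, "div_post": div_post,
                     "d_diversity": div_post - div_pre, "d_delta_M": d_dm})
    truth = pd.DataFrame(rows).set_index("participant_id")
    truth.attrs["partitions"] = {
        "pre": Partition(aff_pre),
        "post": Partition(aff_post),
    }
    return matrices, truth


def simulate_roi_timeseries(
    n_nodes: int,
    T: int,
    task_blocks: int,
    coupling: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    *,
    ar_coef: float = 0.5,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) node signals with task-gated cross-node coupling.

    The task indicator alternates +1 (Addition) / -1 (Control) blocks of
    length ``T // task_blocks``.  Each coupling entry (seed_node, target_node,
    g) adds ``g * x_seed`` to the target during task-on (+1) samples only; in
    a +1/-1-coded interaction regression this plants an interaction
    coefficient of g / 2.
    """
    rng = np.random.default_rng(seed)
    block = max(T // task_blocks, 1)
    task = np.array([1 if (t // block) % 2 == 0 else -1 for t in range(T)])
    x = np.zeros((T, n_nodes))
    eps = rng.normal(0.0, noise_sd, (T, n_nodes))
    for t in range(T):
        x[t] = (ar_coef * x[t - 1] if t > 0 else 0.0) + eps[t]
    if coupling:
        y = x.copy()
        on = task == 1
        for i, j, g in coupling:
            y[on, j] += g * x[on, i]
        x = y
    return x, task
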