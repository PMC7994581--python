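"""Signed task-connectivity networks: construction, modules, and reorganization.

The task network is a 30-node signed weighted symmetric matrix whose edges are
PPI (psychophysiological interaction) regression coefficients; no threshold is
applied.  Community structure is found by greedy Louvain optimization of the
signed quality Q* — positive-weight modularity at full weight minus the
negative-weight modularity term down-weighted by total strength — so that
anticorrelated nodes are penalized for sharing a module.  Training-induced
reorganization is measured globally by the partition distance 1 - NMI (with
the arithmetic normalization 2I/(H1+H2)) and regionally by the diversity
coefficient, the normalized entropy of a node's per-module strength.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import normalized_mutual_info_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "Partition",
    "NodeDiversity",
    "ppi_edge_weights",
    "signed_modularity",
    "louvain_modules",
    "brute_force_modules",
    "partition_distance",
    "diversity_coefficient",
    "group_average_network",
    "test_distance_nonzero",
    "node_change_tests",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Signed weighted symmetric task network with labeled nodes."""

    weights: np.ndarray
    node_labels: list[str]
    participant_id: str | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must match matrix order")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class Partition:
    """Node-to-module affiliation with contiguous module ids starting at 1."""

    affiliation: np.ndarray
    quality: float = float("nan")

    def __post_init__(self) -> None:
        aff = np.asarray(self.affiliation, dtype=int)
        object.__setattr__(self, "affiliation", _canonical(aff))

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.affiliation))

    def __len__(self) -> int:
        return len(self.affiliation)


@dataclass(frozen=True)
class NodeDiversity:
    """Per-node diversity coefficients for one sign channel."""

    values: np.ndarray
    partition: Partition
    channel: str = "positive"
    node_labels: list[str] | None = None

    def as_series(self) -> pd.Series:
        idx = self.node_labels if self.node_labels is not None else range(len(self.values))
        return pd.Series(self.values, index=idx, name=f"diversity_{self.channel}")


def _canonical(aff: np.ndarray) -> np.ndarray:
    """Relabel modules 1..m in order of first appearance."""
    out = np.empty_like(aff)
    mapping: dict[int, int] = {}
    for i, a in enumerate(aff):
        if a not in mapping:
            mapping[a] = len(mapping) + 1
        out[i] = mapping[a]
    return out


# ---------------------------------------------------------------- PPI edges

def ppi_edge_weights(
    roi_timeseries: np.ndarray,
    task_indicator: np.ndarray,
    node_labels: list[str] | None = None,
    participant_id: str | None = None,
    session: str | None = None,
) -> ConnectivityMatrix:
    """Construct the signed task network from node signals and a task contrast.

    For every ordered (seed, target) pair, target is regressed by OLS on
    [intercept, seed signal, task indicator, seed x task interaction]; the
    interaction coefficient is the edge weight.  The matrix is symmetrized by
    averaging the two directions and the diagonal zeroed.
    """
    X = np.asarray(roi_timeseries, dtype=float)
    task = np.asarray(task_indicator, dtype=float)
    if X.ndim != 2 or task.shape != (X.shape[0],):
        raise ValueError("roi_timeseries must be T x N with a length-T task indicator")
    if np.ptp(task) == 0:
        raise ValueError("rank-deficient design: task_indicator is constant")
    T, n = X.shape
    W = np.zeros((n, n))
    ones = np.ones(T)
    for i in range(n):
        seed = X[:, i]
        if np.ptp(seed) == 0:
            raise ValueError(f"rank-deficient design: seed signal {i} is constant")
        D = np.column_stack([ones, seed, task, seed * task])
        coef, _, rank, _ = np.linalg.lstsq(D, X, rcond=None)
        if rank < 4:
            raise ValueError(f"rank-deficient design for seed {i}")
        W[i, :] = coef[3]
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    labels = node_labels if node_labels is not None else [f"n{i}" for i in range(n)]
    return ConnectivityMatrix(W, labels, participant_id, session)


# ----------------------------------------------------------- signed Q* / Louvain

def _split_channels(W: np.ndarray):
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    return Wp, Wn


def signed_modularity(W: np.ndarray, affiliation: np.ndarray) -> float:
    """Asymmetric signed modularity Q*: the positive-channel modularity is
    normalized by positive strength, the negative-channel term by total
    strength, so negative within-module weight is penalized but cannot
    dominate."""
    W = np.asarray(W, dtype=float)
    aff = np.asarray(affiliation)
    Wp, Wn = _split_channels(W)
    sp, sn = Wp.sum(), Wn.sum()
    same = aff[:, None] == aff[None, :]
    q = 0.0
    if sp > 0:
        kp = Wp.sum(axis=1)
        q += (Wp[same].sum() - (np.outer(kp, kp)[same].sum()) / sp) / sp
    if sn > 0:
        kn = Wn.sum(axis=1)
        q -= (Wn[same].sum() - (np.outer(kn, kn)[same].sum()) / sn) / (sp + sn)
    return float(q)


def _louvain_once(W: np.ndarray, rng: np.random.Generator, resolution: float) -> np.ndarray:
    """One greedy Louvain pass hierarchy on the signed quality."""
    n0 = W.shape[0]
    Wp, Wn = _split_channels(W)
    sp, sn = Wp.sum(), Wn.sum()
    coef_p = 1.0 / sp if sp > 0 else 0.0
    coef_n = 1.0 / (sp + sn) if sn > 0 else 0.0
    # mapping from original nodes to current communities
    node_comm = np.arange(n0)

    while True:
        n = Wp.shape[0]
        comm = np.arange(n)
        kp = Wp.sum(axis=1)
        kn = Wn.sum(axis=1)
        # community aggregates
        Kp = kp.copy()
        Kn = kn.copy()
        improved_any = False
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(n):
                ci = comm[i]
                # strengths from i into each community
                wp_i = np.zeros(n)
                wn_i = np.zeros(n)
                np.add.at(wp_i, comm, Wp[i])
                np.add.at(wn_i, comm, Wn[i])
                Kp[ci] -= kp[i]
                Kn[ci] -= kn[i]
                wp_i[ci] -= Wp[i, i]
                wn_i[ci] -= Wn[i, i]
                # gain of joining community c (relative to being alone)
                gain = (
                    coef_p * (wp_i - resolution * kp[i] * Kp * coef_p)
                    - coef_n * (wn_i - resolution * kn[i] * Kn / max(sn, 1e-300))
                )
                best = int(np.argmax(gain))
                if gain[best] <= gain[ci] + 1e-12:
                    best = ci
                if best != ci:
                    improved = improved_any = True
                comm[i] = best
                Kp[best] += kp[i]
                Kn[best] += kn[i]
        if not improved_any:
            break
        # aggregate communities into super-nodes
        uniq, inv = np.unique(comm, return_inverse=True)
        m = len(uniq)
        P = np.zeros((n, m))
        P[np.arange(n), inv] = 1.0
        Wp = P.T @ Wp @ P
        Wn = P.T @ Wn @ P
        node_comm = inv[node_comm]
        if m == n:
            break
    return node_comm


def louvain_modules(
    W: ConnectivityMatrix | np.ndarray,
    resolution: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> Partition:
    """Best-of-restarts greedy Louvain optimization of signed Q*.

    Ties between restarts are broken by higher Q*, then fewer modules, then
    lexicographically smaller canonical affiliation, so the result is a
    deterministic function of (matrix, seed).
    """
    mat = W.weights if isinstance(W, ConnectivityMatrix) else np.asarray(W, dtype=float)
    if not np.any(mat):
        warnings.warn("all-zero matrix: returning the single-module partition")
        return Partition(np.ones(mat.shape[0], dtype=int), 0.0)
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_restarts):
        aff = _canonical(_louvain_once(mat, rng, resolution))
        q = signed_modularity(mat, aff)
        key = (-round(q, 12), len(np.unique(aff)), tuple(aff))
        if best is None or key < best[0]:
            best = (key, aff, q)
    return Partition(best[1], best[2])


def _set_partitions(n: int):
    """All set partitions of range(n) as affiliation vectors (restricted growth)."""
    aff = [0] * n

    def rec(i: int, m: int):
        if i == n:
            yield list(aff)
            return
        for c in range(m + 1):
            aff[i] = c
            yield from rec(i + 1, max(m, c + 1))

    yield from rec(0, 0)


def brute_force_modules(W: np.ndarray) -> Partition:
    """Exhaustive Q* maximization; oracle for small networks (n <= 12)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n > 12:
        raise ValueError("brute force is limited to n <= 12 nodes")
    best_aff, best_q = None, -np.inf
    for aff in _set_partitions(n):
        q = signed_modularity(W, np.asarray(aff))
        if q > best_q + 1e-12:
            best_q, best_aff = q, aff
    return Partition(np.asarray(best_aff), best_q)


# ------------------------------------------------------- distances & diversity

def partition_distance(p1: Partition, p2: Partition) -> float:
    """1 - NMI(p1, p2) with the symmetric normalization 2I/(H1+H2); 0 for
    identical partitions up to relabeling, 1 for independent ones."""
    a1, a2 = p1.affiliation, p2.affiliation
    if len(a1) != len(a2):
        raise ValueError("partitions must cover the same number of nodes")
    nmi = normalized_mutual_info_score(a1, a2, average_method="arithmetic")
    return float(np.clip(1.0 - nmi, 0.0, 1.0))


def diversity_coefficient(
    W: ConnectivityMatrix | np.ndarray,
    p: Partition,
    *,
    channel: str = "positive",
    node_labels: list[str] | None = None,
) -> NodeDiversity:
    """Normalized per-module strength entropy of each node.

    h_i = -(1/log m) sum_u s_i(u)/s_i log(s_i(u)/s_i) over the m modules,
    computed per sign channel (the node's own module included).  Isolated
    nodes (zero strength in the channel) get 0 by convention.
    """
    if channel not in ("positive", "negative"):
        raise ValueError("channel must be 'positive' or 'negative'")
    if isinstance(W, ConnectivityMatrix):
        mat, labels = W.weights, W.node_labels
    else:
        mat, labels = np.asarray(W, dtype=float), node_labels
    if len(p) != mat.shape[0]:
        raise ValueError("partition does not match matrix order")
    w = np.where(mat > 0, mat, 0.0) if channel == "positive" else np.where(mat < 0, -mat, 0.0)
    aff = p.affiliation
    mods = np.unique(aff)
    m = len(mods)
    S = np.stack([w[:, aff == u].sum(axis=1) for u in mods], axis=1)  # node x module
    tot = S.sum(axis=1)
    h = np.zeros(mat.shape[0])
    if m > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = S / tot[:, None]
            terms = np.where(q > 0, q * np.log(q), 0.0)
        h = -terms.sum(axis=1) / np.log(m)
        h[tot <= 0] = 0.0
    n_isolated = int((tot <= 0).sum())
    if n_isolated:
        logger.info("%d isolated node(s) in %s channel assigned diversity 0", n_isolated, channel)
    return NodeDiversity(h, p, channel, labels)


def group_average_network(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean network (used for the group pre/post partitions)."""
    if not matrices:
        raise ValueError("no matrices given")
    labels = matrices[0].node_labels
    for m in matrices:
        if m.node_labels != labels:
            raise ValueError("node label mismatch across matrices")
    W = np.mean([m.weights for m in matrices], axis=0)
    return ConnectivityMatrix(W, labels)


# ------------------------------------------------------------------- statistics

def test_distance_nonzero(distances) -> dict:
    """Two-tailed one-sample t-test of per-participant partition distances
    against 0.  Zero-variance input is reported exactly and flagged."""
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 distances")
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    if sd <= 1e-10 * max(1.0, abs(mean)):  # constant up to float noise
        sd = 0.0
    if sd == 0.0:
        return {"t": np.inf if mean != 0 else 0.0, "p": 0.0 if mean != 0 else 1.0,
                "mean": mean, "sd": sd, "n": int(d.size), "degenerate": True}
    res = stats.ttest_1samp(d, 0.0)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "mean": mean, "sd": sd, "n": int(d.size), "degenerate": False}


def node_change_tests(
    div_pre: pd.DataFrame,
    div_post: pd.DataFrame,
    *,
    pool: dict[str, list[str]] | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-node paired two-sided Wilcoxon signed-rank tests of diversity
    change with Benjamini-Hochberg adjustment across nodes.

    ``pool`` optionally averages groups of columns before testing, e.g.
    ``{"IPS": ["L_IPS", "R_IPS"]}`` pools the bilateral IPS nodes.
    """
    if list(div_pre.columns) != list(div_post.columns) or len(div_pre) != len(div_post):
        raise ValueError("pre/post must have matching participants and nodes")
    pre, post = div_pre.copy(), div_post.copy()
    if pool:
        for new, cols in pool.items():
            pre[new] = pre[cols].mean(axis=1)
            post[new] = post[cols].mean(axis=1)
            pre = pre.drop(columns=cols)
            post = post.drop(columns=cols)
    rows = []
    for node in pre.columns:
        diff = post[node].to_numpy() - pre[node].to_numpy()
        if np.allclose(diff, 0.0):
            logger.info("node %s has all-zero differences; p = 1 by convention", node)
            rows.append({"node": node, "statistic": np.nan, "p": 1.0, "mean_change": 0.0})
            continue
        res = stats.wilcoxon(diff, alternative="two-sided")
        rows.append({"node": node, "statistic": float(res.statistic),
                     "p": float(res.pvalue), "mean_change": float(diff.mean())})
    out = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(out["p"], alpha=fdr_q, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = rej
    return out


# ----------------------------------------------------------------------- I/O

def read_matrix(path, participant_id=None, session=None) -> ConnectivityMatrix:
    """Read a connectivity CSV with a header row of node labels."""
    df = pd.read_csv(path)
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns),
                              participant_id, session)


def write_matrix(m: ConnectivityMatrix, path) -> None:
    pd.DataFrame(m.weights, columns=m.node_labels).to_csv(path, index=False)
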