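"""Hierarchical Bayesian estimation of the strategy-mixture diffusion model.

All latent quantities — per-participant pre-level parameters and their
pre-to-post training changes, group-level item retrieval difficulties, and
the hierarchical hyperparameters — are sampled jointly by an adaptive
Metropolis-within-Gibbs scheme:

* participant and item parameters: adaptive random-walk Metropolis against
  the exact trial likelihood (scales tuned to ~0.44 acceptance in burn-in);
* hierarchical means: exact multivariate-normal Gibbs step under the
  multivariate-normal / inverse-Wishart hyperprior;
* hierarchical SDs (uniform prior): exact Gibbs via the truncated
  inverse-gamma conditional of the variance;
* hypermean covariance: conjugate inverse-Wishart Gibbs step;
* joint brain-behavior regression coefficients: conjugate normal Gibbs step.

Positivity of efficiencies and threshold (pre and post) is a joint
feasibility constraint of the Metropolis target.  The paper-scale defaults
are 3 chains x 10,000 samples (5,000 burn-in); ``FitConfig.ci()`` is the
reduced profile used by the test suite.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps
from scipy.special import logsumexp

from .wiener import _wiener_logpdf_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "PriorSpec",
    "PosteriorSamples",
    "JointModelResult",
    "fit_hierarchical",
    "convergence_diagnostics",
    "posterior_predictive",
    "compare_models",
    "fit_joint_brain_model",
    "savage_dickey_bf",
    "evidence_category",
]

# column layout of the per-participant parameter matrix
COLS = [
    "rho_pre", "d_rho", "delta_M_pre", "d_delta_M", "delta_C_pre",
    "d_delta_C", "alpha_pre", "d_alpha", "tau", "tau_switch_pre",
    "d_tau_switch",
]
_MODEL_CODE = {"simple": 0, "single_item": 1, "full": 2}
_HIER_COLS = {
    "full": [0, 1, 2, 3, 4, 5, 6, 7, 10],
    "single_item": [2, 3, 6, 7],
    "simple": [2, 3, 6, 7],
}
_COL_RENAME = {
    "single_item": {2: "delta_pre", 3: "d_delta"},
    "simple": {2: "drift_pre", 3: "d_drift"},
}
# change columns entering the joint latent regression, in reporting order
JOINT_PARAMS = ["d_rho", "d_delta_M", "d_delta_C", "d_alpha", "d_tau_switch"]
_JOINT_COLS = [1, 3, 5, 7, 10]


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings; defaults follow the original 3 x 10,000 / 5,000 scheme."""

    n_chains: int = 3
    n_samples: int = 10_000
    burn_in: int = 5_000
    thinning: int = 1
    seed: int = 0
    adapt_target: float = 0.44

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_samples:
            raise ValueError("burn_in must be smaller than n_samples")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def ci(cls, seed: int = 0, n_chains: int = 3) -> "FitConfig":
        """Reduced profile for continuous-integration-scale runs."""
        return cls(n_chains=n_chains, n_samples=1000, burn_in=500, seed=seed)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative hyperprior constants (all exposed)."""

    loc_prior_sd: float = 2.0      # SD of the normal prior on hypermeans
    sd_upper: float = 5.0          # uniform(0, sd_upper) on hierarchical SDs
    tau_bounds: tuple = (0.01, 2.0)
    tau_switch_bounds: tuple = (0.0, 3.0)
    beta_prior_sd: float = 1.0     # N(0, sd) prior on joint regression betas
    resid_sd_upper: float = 2.0    # uniform upper bound on residual scale
    # inverse-Wishart df offset over dimension, identity scale
    wishart_df_offset: int = 1


class PosteriorSamples:
    """Labeled MCMC draws: parameter name -> array (chain, draw[, index])."""

    def __init__(self, draws: dict, meta: dict):
        self.draws = draws
        self.meta = meta

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def names(self) -> list[str]:
        return list(self.draws)

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (chain*draw[, index])."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def median(self, name: str) -> np.ndarray:
        return np.median(self.stacked(name), axis=0)

    def to_arviz(self) -> az.InferenceData:
        return az.from_dict(posterior={k: v for k, v in self.draws.items()})

    def to_csv(self, path) -> None:
        """Tidy export: chain, draw, parameter, value."""
        frames = []
        for name, a in self.draws.items():
            a3 = a.reshape(a.shape[0], a.shape[1], -1)
            for j in range(a3.shape[2]):
                label = name if a3.shape[2] == 1 else f"{name}[{j}]"
                df = pd.DataFrame({
                    "chain": np.repeat(np.arange(a3.shape[0]), a3.shape[1]),
                    "draw": np.tile(np.arange(a3.shape[1]), a3.shape[0]),
                    "parameter": label,
                    "value": a3[:, :, j].ravel(),
                })
                frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def summary_json(self, path=None) -> dict:
        diag = convergence_diagnostics(self)
        out = {
            "meta": {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, bool, list))},
            "parameters": {},
        }
        for _, row in diag.iterrows():
            out["parameters"][row["parameter"]] = {
                "median": row["median"], "hdi_3%": row["lo"], "hdi_97%": row["hi"],
                "rhat": None if np.isnan(row["rhat"]) else row["rhat"],
                "ess": row["ess"],
            }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=1)
        return out


@dataclass(frozen=True)
class JointModelResult:
    """Posterior summaries and Savage-Dickey Bayes factors of the latent
    regression of diversity change on parameter changes."""

    betas: pd.DataFrame          # one row per latent change parameter
    resid_sd_median: float
    samples: PosteriorSamples


# ------------------------------------------------------------ likelihood core

@njit(cache=True)
def _ll_subset(idx, rt, cc, sess, pid, item, nk, R, P, model):
    total = 0.0
    for n in range(idx.shape[0]):
        t = idx[n]
        i = pid[t]
        s = sess[t]
        a = P[i, 6] + s * P[i, 7]
        tau = P[i, 8]
        if model == 2:
            z = (P[i, 0] + s * P[i, 1]) - R[item[t]]
            if z >= 0.0:
                pm = 1.0 / (1.0 + math.exp(-z))
            else:
                e = math.exp(z)
                pm = e / (1.0 + e)
            rk = R[item[t]]
            if rk > 30.0:
                vM = 0.0
            else:
                vM = (P[i, 2] + s * P[i, 3]) / (1.0 + math.exp(rk))
            vC = (P[i, 4] + s * P[i, 5]) / nk[t]
            lM = _wiener_logpdf_scalar(rt[t], cc[t], a, vM, tau, 0.5)
            tsw = P[i, 9] + s * P[i, 10]
            lC = _wiener_logpdf_scalar(rt[t], cc[t], a, vC, tau + tsw, 0.5)
            if pm >= 1.0:
                ll = lM
            elif pm <= 0.0:
                ll = lC
            else:
                x1 = math.log(pm) + lM
                x2 = math.log(1.0 - pm) + lC
                m = x1 if x1 > x2 else x2
                if m == -np.inf:
                    ll = -np.inf
                else:
                    ll = m + math.log(math.exp(x1 - m) + math.exp(x2 - m))
        elif model == 1:
            rk = R[item[t]]
            if rk > 30.0:
                v = 0.0
            else:
                v = (P[i, 2] + s * P[i, 3]) / (1.0 + math.exp(rk))
            ll = _wiener_logpdf_scalar(rt[t], cc[t], a, v, tau, 0.5)
        else:
            v = P[i, 2] + s * P[i, 3]
            ll = _wiener_logpdf_scalar(rt[t], cc[t], a, v, tau, 0.5)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total


@njit(cache=True)
def _ll_pointwise(rt, cc, sess, pid, item, nk, R, P, model, out):
    for t in range(rt.shape[0]):
        idx = np.empty(1, dtype=np.int64)
        idx[0] = t
        out[t] = _ll_subset(idx, rt, cc, sess, pid, item, nk, R, P, model)


@njit(cache=True)
def _ll_range(lo, hi, rt, cc, sess, pid, item, nk, R, P, model):
    idx = np.arange(lo, hi)
    return _ll_subset(idx, rt, cc, sess, pid, item, nk, R, P, model)


@njit(cache=True)
def _mw_sweep(
    seed, rt, cc, sess, pid, item, nk, p_start, item_idx, k_start,
    P, R, mu, sig, scales, item_scales, cur_ll,
    active_cols, fam_of_col, model, two_sessions, has_items,
    tau_lo, tau_hi, tsw_lo, tsw_hi,
    adapting, gamma, target,
    joint, y, jcols, beta, resid_sd,
):
    """One Metropolis-within-Gibbs sweep over participant and item parameters.

    Mutates P, R, scales, item_scales and cur_ll in place; Gibbs blocks for
    the hyperparameters are done by the caller.
    """
    np.random.seed(seed)
    n_p = p_start.shape[0] - 1
    for i in range(n_p):
        lo, hi = p_start[i], p_start[i + 1]
        for ci in range(active_cols.shape[0]):
            c = active_cols[ci]
            old = P[i, c]
            newv = old + np.random.normal() * scales[i, c]
            P[i, c] = newv
            if c == 8:
                valid = tau_lo < newv < tau_hi
            elif c == 9:
                valid = (tsw_lo <= newv <= tsw_hi) and (P[i, 9] + P[i, 10] >= 0.0)
            elif c == 10:
                valid = P[i, 9] + P[i, 10] >= 0.0
            elif c == 2 or c == 3:
                valid = True if model == 0 else (
                    P[i, 2] > 0.0 and ((not two_sessions) or P[i, 2] + P[i, 3] > 0.0))
            elif c == 4 or c == 5:
                valid = P[i, 4] > 0.0 and ((not two_sessions) or P[i, 4] + P[i, 5] > 0.0)
            elif c == 6 or c == 7:
                valid = P[i, 6] > 0.0 and ((not two_sessions) or P[i, 6] + P[i, 7] > 0.0)
            else:
                valid = True
            acc = 0.0
            if valid:
                f = fam_of_col[c]
                dlp = 0.0
                if f >= 0:
                    dlp = (-0.5 * ((newv - mu[f]) / sig[f]) ** 2
                           + 0.5 * ((old - mu[f]) / sig[f]) ** 2)
                if joint and (c == 1 or c == 3 or c == 5 or c == 7 or c == 10):
                    pred_new = 0.0
                    for jj in range(jcols.shape[0]):
                        pred_new += P[i, jcols[jj]] * beta[jj]
                    P[i, c] = old
                    pred_old = 0.0
                    for jj in range(jcols.shape[0]):
                        pred_old += P[i, jcols[jj]] * beta[jj]
                    P[i, c] = newv
                    dlp += (-0.5 * ((y[i] - pred_new) / resid_sd) ** 2
                            + 0.5 * ((y[i] - pred_old) / resid_sd) ** 2)
                new_ll = _ll_range(lo, hi, rt, cc, sess, pid, item, nk, R, P, model)
                if new_ll > -np.inf:
                    lr = new_ll - cur_ll[i] + dlp
                    if lr >= 0.0 or np.random.random() < np.exp(lr):
                        acc = 1.0
                        cur_ll[i] = new_ll
            if acc == 0.0:
                P[i, c] = old
            if adapting:
                s = scales[i, c] * np.exp(gamma * (acc - target))
                scales[i, c] = min(max(s, 1e-4), 3.0)
    if has_items:
        f_item = sig.shape[0] - 1
        for k in range(k_start.shape[0] - 1):
            idx = item_idx[k_start[k]:k_start[k + 1]]
            old = R[k]
            cur = _ll_subset(idx, rt, cc, sess, pid, item, nk, R, P, model)
            R[k] = old + np.random.normal() * item_scales[k]
            new = _ll_subset(idx, rt, cc, sess, pid, item, nk, R, P, model)
            dlp = (-0.5 * ((R[k] - mu[f_item]) / sig[f_item]) ** 2
                   + 0.5 * ((old - mu[f_item]) / sig[f_item]) ** 2)
            lr = new - cur + dlp
            acc = 1.0
            if not (lr >= 0.0 or np.random.random() < np.exp(lr)):
                R[k] = old
                acc = 0.0
            if adapting:
                item_scales[k] = min(max(item_scales[k] * np.exp(gamma * (acc - target)),
                                         1e-4), 3.0)
        # item moves changed every participant's likelihood
        for i in range(n_p):
            cur_ll[i] = _ll_range(p_start[i], p_start[i + 1],
                                  rt, cc, sess, pid, item, nk, R, P, model)


# ---------------------------------------------------------------- data prep

def _prepare(trials: pd.DataFrame):
    df = trials.dropna(subset=["rt_seconds"]).copy()
    pids = sorted(df["participant_id"].unique())
    sessions = sorted(df["session"].unique(), key=lambda s: 0 if s == "pre" else 1)
    if not set(sessions) <= {"pre", "post"}:
        raise ValueError("session must be 'pre' or 'post'")
    items = sorted(df["item_id"].unique())
    pid_ix = {p: i for i, p in enumerate(pids)}
    item_ix = {k: i for i, k in enumerate(items)}
    nk_by_item = df.groupby("item_id").apply(
        lambda g: int(min(g["addend_a"].iloc[0], g["addend_b"].iloc[0])),
        include_groups=False,
    )
    data = {
        "rt": df["rt_seconds"].to_numpy(float),
        "cc": df["response_correct"].to_numpy().astype(np.int64),
        "sess": (df["session"] == "post").to_numpy().astype(np.int64)
        if len(sessions) == 2 else np.zeros(len(df), dtype=np.int64),
        "pid": df["participant_id"].map(pid_ix).to_numpy(np.int64),
        "item": df["item_id"].map(item_ix).to_numpy(np.int64),
        "nk": df["item_id"].map(nk_by_item).to_numpy(float),
    }
    return data, pids, items, len(sessions) == 2


def _valid(P_row, col, model, prior: PriorSpec, two_sessions: bool) -> bool:
    v = P_row
    if col == 8:
        lo, hi = prior.tau_bounds
        return lo < v[8] < hi
    if col == 9:
        lo, hi = prior.tau_switch_bounds
        return lo <= v[9] <= hi and v[9] + v[10] >= 0
    if col == 10:
        return v[9] + v[10] >= 0
    if col in (2, 3):
        if model == 0:  # simple DDM drift is unconstrained
            return True
        return v[2] > 0 and (not two_sessions or v[2] + v[3] > 0)
    if col in (4, 5):
        return v[4] > 0 and (not two_sessions or v[4] + v[5] > 0)
    if col in (6, 7):
        return v[6] > 0 and (not two_sessions or v[6] + v[7] > 0)
    return True


def _trunc_invgamma(rng, shape_a, scale_b, upper_var):
    """Draw a variance from InvGamma(shape_a, scale_b) truncated to (0, upper_var)."""
    dist = sps.invgamma(shape_a, scale=scale_b)
    c = dist.cdf(upper_var)
    if c <= 0:
        return upper_var * 0.999
    u = rng.uniform(0.0, c)
    return float(dist.ppf(u))


# ----------------------------------------------------------------- the sampler

def fit_hierarchical(
    trials: pd.DataFrame,
    prior: PriorSpec | None = None,
    cfg: FitConfig | None = None,
    *,
    model: str = "full",
    joint_y: pd.Series | None = None,
    progress: bool = False,
) -> PosteriorSamples:
    """Sample the posterior of the hierarchical strategy model.

    Parameters
    ----------
    trials : preprocessed trial table (missing RTs are excluded).
    model : "full" (strategy dissociation), "single_item" (one strategy with
        item difficulty), or "simple" (plain DDM).
    joint_y : optional per-participant diversity-change outcome; when given,
        the latent regression of ``joint_y`` on all five change parameters is
        fitted jointly (full model only).

    Convergence is checked on return: any split-R-hat above 1.1 sets
    ``meta['converged'] = False`` with a warning (never silently accepted).
    """
    prior = prior or PriorSpec()
    cfg = cfg or FitConfig()
    if model not in _MODEL_CODE:
        raise ValueError(f"unknown model {model!r}")
    mcode = _MODEL_CODE[model]
    data, pids, items, two_sessions = _prepare(trials)
    n_p, n_items, n_trials = len(pids), len(items), len(data["rt"])
    has_items = mcode >= 1
    joint = joint_y is not None
    if joint:
        if model != "full" or not two_sessions:
            raise ValueError("joint regression requires the full model with both sessions")
        missing = [p for p in pids if p not in joint_y.index or not np.isfinite(joint_y.get(p, np.nan))]
        if missing:
            logger.info("excluding %d participants without modularity values: %s", len(missing), missing)
        keep = [p for p in pids if p not in missing]
        trials = trials[trials["participant_id"].isin(keep)]
        data, pids, items, two_sessions = _prepare(trials)
        n_p, n_items, n_trials = len(pids), len(items), len(data["rt"])
        y = joint_y.loc[pids].to_numpy(float)

    hier_cols = list(_HIER_COLS[model])
    if not two_sessions:  # change parameters only exist with both sessions
        hier_cols = [c for c in hier_cols if c not in (1, 3, 5, 7, 10)]
    active_cols = sorted(set(hier_cols) | {8} | ({9, 10} if mcode == 2 and two_sessions else ({9} if mcode == 2 else set())))
    dim = len(hier_cols) + (1 if has_items else 0)

    # sort trials by participant for contiguous likelihood slices
    order = np.argsort(data["pid"], kind="stable")
    for key in data:
        data[key] = np.ascontiguousarray(data[key][order])
    p_start = np.searchsorted(data["pid"], np.arange(n_p + 1)).astype(np.int64)
    by_item = np.argsort(data["item"], kind="stable").astype(np.int64)
    k_start = np.searchsorted(data["item"][by_item], np.arange(n_items + 1)).astype(np.int64)
    per_p_idx = [np.arange(p_start[i], p_start[i + 1]) for i in range(n_p)]
    min_rt = np.array([data["rt"][ix].min() if len(ix) else 1.0 for ix in per_p_idx])

    n_keep = (cfg.n_samples - cfg.burn_in) // cfg.thinning
    store: dict[str, np.ndarray] = {}
    col_names = [
        _COL_RENAME.get(model, {}).get(c, COLS[c]) for c in range(len(COLS))
    ]
    for c in active_cols:
        store[col_names[c]] = np.empty((cfg.n_chains, n_keep, n_p))
    if has_items:
        store["rho_item"] = np.empty((cfg.n_chains, n_keep, n_items))
    store["mu"] = np.empty((cfg.n_chains, n_keep, dim))
    store["sigma"] = np.empty((cfg.n_chains, n_keep, dim))
    if joint:
        store["beta"] = np.empty((cfg.n_chains, n_keep, len(_JOINT_COLS)))
        store["resid_sd"] = np.empty((cfg.n_chains, n_keep))

    df0 = dim + prior.wishart_df_offset
    psi0 = np.eye(dim)

    arrs = (data["rt"], data["cc"], data["sess"], data["pid"], data["item"], data["nk"])

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([cfg.seed, chain])
        # ---- initialization (data-informed, jittered per chain)
        P = np.zeros((n_p, len(COLS)))
        P[:, 0] = rng.normal(0.0, 0.3, n_p)
        P[:, 2] = (1.3 if mcode == 2 else 1.0) + rng.normal(0, 0.1, n_p)
        P[:, 4] = 2.0 + rng.normal(0, 0.1, n_p)
        P[:, 6] = 1.5 + rng.normal(0, 0.1, n_p)
        P[:, 8] = np.clip(0.6 * min_rt, prior.tau_bounds[0] + 1e-3, 0.8)
        P[:, 9] = 0.3 if mcode == 2 else 0.0
        if two_sessions:
            P[:, 1] = rng.normal(0.0, 0.1, n_p)
            P[:, 3] = np.abs(rng.normal(0.1, 0.05, n_p))
        R = rng.normal(0.0, 0.1, n_items) if has_items else np.zeros(1)
        mu = np.zeros(dim)
        sig = np.full(dim, 0.5)
        Sigma = np.eye(dim)
        beta = np.zeros(len(_JOINT_COLS))
        resid_sd = 0.2

        scales = np.full((n_p, len(COLS)), 0.15)
        scales[:, 8] = 0.03
        scales[:, 9] = 0.08
        scales[:, 10] = 0.08
        scales[:, 0] = 0.3
        scales[:, 1] = 0.3
        item_scales = np.full(n_items, 0.25)

        cur_ll = np.array([_ll_subset(ix, *arrs, R, P, mcode) for ix in per_p_idx])
        if not np.all(np.isfinite(cur_ll)):
            # push tau low enough for every trial to be reachable
            P[:, 8] = np.clip(0.5 * min_rt, prior.tau_bounds[0] + 1e-3, 0.5)
            P[:, 9] = np.minimum(P[:, 9], 0.05)
            cur_ll = np.array([_ll_subset(ix, *arrs, R, P, mcode) for ix in per_p_idx])
        if not np.all(np.isfinite(cur_ll)):
            raise RuntimeError("could not find a feasible starting state")

        fam_of_col = np.full(len(COLS), -1, dtype=np.int64)
        for f, c in enumerate(hier_cols):
            fam_of_col[c] = f
        active_arr = np.asarray(active_cols, dtype=np.int64)
        jcols_arr = np.asarray(_JOINT_COLS, dtype=np.int64)
        y_arr = y if joint else np.zeros(n_p)

        keep_ix = 0
        for sweep in range(cfg.n_samples):
            adapting = sweep < cfg.burn_in
            gamma = min(0.25, 5.0 / math.sqrt(sweep + 20.0))
            # ---- participant and item parameters (Metropolis kernel)
            _mw_sweep(
                int(rng.integers(0, 2**31 - 1)), *arrs, p_start, by_item, k_start,
                P, R, mu, sig, scales, item_scales, cur_ll,
                active_arr, fam_of_col, mcode, two_sessions, has_items,
                prior.tau_bounds[0], prior.tau_bounds[1],
                prior.tau_switch_bounds[0], prior.tau_switch_bounds[1],
                adapting, gamma, cfg.adapt_target,
                joint, y_arr, jcols_arr, beta, float(resid_sd),
            )
            # ---- hypermeans (MVN Gibbs)
            theta_sums = np.array([P[:, c].sum() for c in hier_cols] +
                                  ([R.sum()] if has_items else []))
            counts = np.array([n_p] * len(hier_cols) + ([n_items] if has_items else []))
            prec_prior = np.linalg.inv(Sigma + 1e-10 * np.eye(dim))
            D = np.diag(counts / sig**2)
            prec = prec_prior + D
            cov = np.linalg.inv(prec)
            mean = cov @ (theta_sums / sig**2)
            mu = rng.multivariate_normal(mean, (cov + cov.T) / 2.0)
            # ---- hierarchical SDs (truncated inverse-gamma Gibbs on variance)
            for f in range(dim):
                if f < len(hier_cols):
                    th = P[:, hier_cols[f]]
                else:
                    th = R
                ss = float(((th - mu[f]) ** 2).sum())
                a_sh = (len(th) - 1) / 2.0
                var = _trunc_invgamma(rng, max(a_sh, 0.5), max(ss, 1e-12) / 2.0,
                                      prior.sd_upper**2)
                sig[f] = math.sqrt(var)
            # ---- hypermean covariance (inverse-Wishart Gibbs)
            Sigma = sps.invwishart.rvs(df=df0 + 1, scale=psi0 + np.outer(mu, mu),
                                       random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            # ---- joint regression block (conjugate Gibbs)
            if joint:
                X = P[:, _JOINT_COLS]
                prec_b = X.T @ X / resid_sd**2 + np.eye(len(_JOINT_COLS)) / prior.beta_prior_sd**2
                cov_b = np.linalg.inv(prec_b)
                mean_b = cov_b @ (X.T @ y) / resid_sd**2
                beta = rng.multivariate_normal(mean_b, (cov_b + cov_b.T) / 2.0)
                rss = float(((y - X @ beta) ** 2).sum())
                a_sh = (n_p - 1) / 2.0
                resid_sd = math.sqrt(_trunc_invgamma(
                    rng, max(a_sh, 0.5), max(rss, 1e-12) / 2.0, prior.resid_sd_upper**2))
            # ---- store
            if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thinning == 0:
                for c in active_cols:
                    store[col_names[c]][chain, keep_ix] = P[:, c]
                if has_items:
                    store["rho_item"][chain, keep_ix] = R
                store["mu"][chain, keep_ix] = mu
                store["sigma"][chain, keep_ix] = sig
                if joint:
                    store["beta"][chain, keep_ix] = beta
                    store["resid_sd"][chain, keep_ix] = resid_sd
                keep_ix += 1
            if progress and sweep % 200 == 0:
                logger.info("chain %d sweep %d / %d", chain, sweep, cfg.n_samples)

    meta = {
        "model": model, "seed": cfg.seed, "n_chains": cfg.n_chains,
        "n_samples": cfg.n_samples, "burn_in": cfg.burn_in,
        "thinning": cfg.thinning, "participants": list(pids),
        "items": list(items), "two_sessions": bool(two_sessions),
        "joint": joint,
    }
    samples = PosteriorSamples(store, meta)
    diag = convergence_diagnostics(samples)
    converged = bool((diag["rhat"].dropna() < 1.1).all()) if cfg.n_chains >= 2 else None
    samples.meta["converged"] = converged
    samples.meta["max_rhat"] = float(diag["rhat"].max()) if cfg.n_chains >= 2 else None
    if converged is False:
        warnings.warn(
            f"split-R-hat above 1.1 on some parameters (max {samples.meta['max_rhat']:.3f}); "
            "treat estimates with caution"
        )
    return samples


# ---------------------------------------------------------------- diagnostics

def convergence_diagnostics(s: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per scalar parameter, with a pass flag at 1.1.

    With a single chain R-hat is unavailable (NaN) and only ESS is reported.
    Chains that are exact copies of one another carry no between-chain
    disagreement and are reported as R-hat = 1 exactly.
    """
    rows = []
    first = next(iter(s.draws.values()))
    single_chain = first.shape[0] < 2
    ds = az.convert_to_dataset({k: v for k, v in s.draws.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(ds) if not single_chain else None
        ess_ds = az.ess(ds)
    for name, a in s.draws.items():
        a3 = a.reshape(a.shape[0], a.shape[1], -1)
        rh = None if rhat_ds is None else np.asarray(rhat_ds[name]).reshape(-1)
        es = np.asarray(ess_ds[name]).reshape(-1)
        identical = np.all(a3 == a3[:1])  # every chain an exact copy of chain 0
        for j in range(a3.shape[2]):
            x = a3[:, :, j]
            label = name if a3.shape[2] == 1 else f"{name}[{j}]"
            if single_chain:
                rhat = np.nan
            elif identical or np.ptp(x) == 0:
                rhat = 1.0
            else:
                rhat = float(rh[j])
            rows.append({
                "parameter": label, "rhat": rhat, "ess": float(es[j]),
                "median": float(np.median(x)),
                "lo": float(np.quantile(x, 0.03)), "hi": float(np.quantile(x, 0.97)),
                "pass": bool(rhat < 1.1) if np.isfinite(rhat) else None,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------- posterior predictive

def posterior_predictive(
    s: PosteriorSamples,
    trials: pd.DataFrame,
    *,
    n_draws: int = 100,
    dt: float = 1e-3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate datasets from posterior draws; per participant-session
    predicted mean RT and error rate with 95% intervals and observed values.

    The ``coverage`` attrs entry is the fraction of participant-sessions whose
    observed value falls inside its predictive interval.
    """
    from .synth import _sim_fpt_batch  # local import to avoid a cycle

    if s.meta["model"] != "full":
        raise ValueError("posterior_predictive expects a full-model fit")
    data, pids, items, two_sessions = _prepare(trials)
    rng = np.random.default_rng(seed)
    a0 = s.draws["rho_pre"]
    total = a0.shape[0] * a0.shape[1]
    take = np.linspace(0, total - 1, min(n_draws, total)).astype(int)

    def pooled(name):
        return s.stacked(name)[take]

    cols = {c: pooled(c) for c in ("rho_pre", "delta_M_pre", "delta_C_pre",
                                   "alpha_pre", "tau", "tau_switch_pre")}
    for c in ("d_rho", "d_delta_M", "d_delta_C", "d_alpha", "d_tau_switch"):
        cols[c] = pooled(c) if c in s.draws else np.zeros_like(cols["rho_pre"])
    Ritem = pooled("rho_item")

    nd = len(take)
    obs_rows = []
    sims_rt = {}
    sims_err = {}
    for (pid, sess), grp in trials.dropna(subset=["rt_seconds"]).groupby(
            ["participant_id", "session"]):
        i = pids.index(pid)
        sflag = 1 if (sess == "post" and two_sessions) else 0
        kix = np.array([items.index(k) for k in grp["item_id"]])
        nk = np.minimum(grp["addend_a"], grp["addend_b"]).to_numpy(float)
        rts_mean = np.empty(nd)
        errs = np.empty(nd)
        for d in range(nd):
            rho_i = cols["rho_pre"][d, i] + sflag * cols["d_rho"][d, i]
            dM = cols["delta_M_pre"][d, i] + sflag * cols["d_delta_M"][d, i]
            dC = cols["delta_C_pre"][d, i] + sflag * cols["d_delta_C"][d, i]
            al = cols["alpha_pre"][d, i] + sflag * cols["d_alpha"][d, i]
            tau = cols["tau"][d, i]
            tsw = cols["tau_switch_pre"][d, i] + sflag * cols["d_tau_switch"][d, i]
            rk = Ritem[d, kix]
            pm = 1.0 / (1.0 + np.exp(-(rho_i - rk)))
            mem = rng.random(len(kix)) < pm
            v = np.where(mem, dM / (1.0 + np.exp(rk)), dC / nk)
            te = np.where(mem, tau, tau + tsw)
            dec, up = _sim_fpt_batch(v, np.full(len(kix), al), dt,
                                     int(rng.integers(0, 2**31 - 1)), 30.0,
                                     0.5826 * math.sqrt(dt))
            rts_mean[d] = np.nanmean(te + dec)
            errs[d] = 1.0 - up.mean()
        sims_rt[(pid, sess)] = rts_mean
        sims_err[(pid, sess)] = errs
        obs_rows.append({
            "participant_id": pid, "session": sess,
            "obs_mean_rt": float(grp["rt_seconds"].mean()),
            "obs_error_rate": float(1.0 - grp["response_correct"].mean()),
            "pred_mean_rt": float(np.median(rts_mean)),
            "rt_lo": float(np.quantile(rts_mean, 0.025)),
            "rt_hi": float(np.quantile(rts_mean, 0.975)),
            "pred_error_rate": float(np.median(errs)),
            "err_lo": float(np.quantile(errs, 0.025)),
            "err_hi": float(np.quantile(errs, 0.975)),
        })
    out = pd.DataFrame(obs_rows)
    out["rt_covered"] = (out["obs_mean_rt"] >= out["rt_lo"]) & (out["obs_mean_rt"] <= out["rt_hi"])
    out["err_covered"] = (out["obs_error_rate"] >= out["err_lo"]) & (out["obs_error_rate"] <= out["err_hi"])
    out.attrs["coverage"] = {
        "mean_rt": float(out["rt_covered"].mean()),
        "error_rate": float(out["err_covered"].mean()),
    }
    return out


# ------------------------------------------------------------- model comparison

def _waic(s: PosteriorSamples, trials: pd.DataFrame, max_draws: int = 200) -> dict:
    data, pids, items, _ = _prepare(trials)
    mcode = _MODEL_CODE[s.meta["model"]]
    model = s.meta["model"]
    names = [_COL_RENAME.get(model, {}).get(c, COLS[c]) for c in range(len(COLS))]
    total = next(iter(s.draws.values())).shape[0] * next(iter(s.draws.values())).shape[1]
    take = np.linspace(0, total - 1, min(max_draws, total)).astype(int)
    n_trials = len(data["rt"])
    ll = np.empty((len(take), n_trials))
    arrs = (data["rt"], data["cc"], data["sess"], data["pid"], data["item"], data["nk"])
    for d_i, d in enumerate(take):
        P = np.zeros((len(pids), len(COLS)))
        for c in range(len(COLS)):
            if names[c] in s.draws:
                P[:, c] = s.stacked(names[c])[d]
        R = s.stacked("rho_item")[d] if "rho_item" in s.draws else np.zeros(1)
        _ll_pointwise(*arrs, R, P, mcode, ll[d_i])
    lppd = np.sum(logsumexp(ll, axis=0) - math.log(ll.shape[0]))
    p_waic = float(np.var(ll, axis=0, ddof=1).sum())
    elpd_i = logsumexp(ll, axis=0) - math.log(ll.shape[0]) - np.var(ll, axis=0, ddof=1)
    se = float(math.sqrt(n_trials * np.var(elpd_i, ddof=1)))
    return {"elpd_waic": float(lppd - p_waic), "p_waic": p_waic, "se": se,
            "pointwise": elpd_i}


def compare_models(
    trials: pd.DataFrame,
    cfg: FitConfig | None = None,
    prior: PriorSpec | None = None,
    *,
    models: tuple = ("simple", "single_item", "full"),
    max_draws: int = 200,
) -> pd.DataFrame:
    """Fit the candidate models and rank them by WAIC expected predictive fit.

    Returns one row per model with elpd_waic (higher is better), its SE, the
    effective parameter count, convergence status, and rank.
    """
    if trials.dropna(subset=["rt_seconds"]).empty:
        raise ValueError("no valid trials to compare models on")
    cfg = cfg or FitConfig.ci()
    rows = []
    pointwise = {}
    for m in models:
        fit = fit_hierarchical(trials, prior, cfg, model=m)
        w = _waic(fit, trials, max_draws=max_draws)
        pointwise[m] = w.pop("pointwise")
        rows.append({"model": m, **w, "converged": fit.meta["converged"],
                     "max_rhat": fit.meta["max_rhat"]})
    out = pd.DataFrame(rows).sort_values("elpd_waic", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    best = out.loc[0, "model"]
    dse = []
    for _, row in out.iterrows():
        if row["model"] == best:
            dse.append(0.0)
        else:
            diff = pointwise[best] - pointwise[row["model"]]
            dse.append(float(math.sqrt(len(diff) * np.var(diff, ddof=1))))
    out["dse_vs_best"] = dse
    return out


# --------------------------------------------------------- joint brain model

def savage_dickey_bf(prior_density_at_zero: float, posterior_samples) -> dict:
    """Savage-Dickey Bayes factor BF_10 for the point null beta = 0.

    The posterior density at 0 is a Gaussian KDE (Scott bandwidth); a
    normal-approximation estimate is always computed and both are reported
    (with an instability flag) when they disagree by more than 20%.
    """
    x = np.asarray(posterior_samples, dtype=float)
    if x.size < 10:
        warnings.warn("too few posterior samples for stable density estimation")
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    dens_norm = sps.norm.pdf(0.0, mu, sd) if sd > 0 else math.inf
    if sd > 0 and x.size >= 10:
        dens_kde = float(sps.gaussian_kde(x)(0.0)[0])
    else:
        dens_kde = dens_norm
    bf = prior_density_at_zero / dens_kde if dens_kde > 0 else math.inf
    bf_norm = prior_density_at_zero / dens_norm if dens_norm > 0 else math.inf
    both_small = max(dens_kde, dens_norm) < 1e-12
    unstable = (not both_small) and (
        abs(dens_kde - dens_norm) > 0.2 * max(dens_kde, dens_norm, 1e-300))
    return {"bf10": float(bf), "bf10_normal_approx": float(bf_norm),
            "unstable": bool(unstable), "evidence": evidence_category(bf)}


def evidence_category(bf10: float) -> str:
    """Qualitative evidence label: BF > 3 moderate for H1, < 1/3 evidence of
    absence, otherwise insufficient."""
    if bf10 > 3.0:
        return "moderate_h1"
    if bf10 < 1.0 / 3.0:
        return "evidence_of_absence"
    return "insufficient"


def fit_joint_brain_model(
    trials: pd.DataFrame,
    delta_modularity: pd.Series,
    prior: PriorSpec | None = None,
    cfg: FitConfig | None = None,
) -> JointModelResult:
    """Latent regression of per-participant diversity change on the change in
    all strategy-model parameters, fitted jointly with the hierarchy.

    Returns posterior summaries and Savage-Dickey Bayes factors per
    coefficient (prior N(0, beta_prior_sd)).
    """
    prior = prior or PriorSpec()
    cfg = cfg or FitConfig()
    fit = fit_hierarchical(trials, prior, cfg, model="full", joint_y=delta_modularity)
    beta = fit.stacked("beta")
    prior0 = sps.norm.pdf(0.0, 0.0, prior.beta_prior_sd)
    rows = []
    for j, name in enumerate(JOINT_PARAMS):
        b = beta[:, j]
        sd_res = savage_dickey_bf(prior0, b)
        rows.append({
            "parameter": name,
            "beta_median": float(np.median(b)),
            "beta_lo": float(np.quantile(b, 0.025)),
            "beta_hi": float(np.quantile(b, 0.975)),
            "bf10": sd_res["bf10"],
            "evidence": sd_res["evidence"],
            "bf_unstable": sd_res["unstable"],
        })
    return JointModelResult(
        betas=pd.DataFrame(rows),
        resid_sd_median=float(np.median(fit.stacked("resid_sd"))),
        samples=fit,
    )
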