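"""Descriptive and inferential statistics for the pre/post training analyses.

Paired t-tests with both Cohen's d conventions (d_z = mean diff / SD of
diffs; d_av = mean diff / average of the pre and post SDs, the headline
value), Spearman rank correlations, a permutation comparison of dependent
correlations sharing an outcome, and the Region x Time repeated-measures
ANOVA.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "PairedResult",
    "paired_t",
    "spearman",
    "compare_dependent_correlations",
    "rm_anova",
]


@dataclass(frozen=True)
class PairedResult:
    t: float
    df: int
    p: float
    d_z: float
    d_av: float
    mean_diff: float
    degenerate: bool = False


def paired_t(pre, post) -> PairedResult:
    """Two-sided paired t-test of post vs pre with both effect sizes."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre and post must be equal-length 1-d arrays, n >= 2")
    diff = post - pre
    n = diff.size
    md = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    sd_av = (pre.std(ddof=1) + post.std(ddof=1)) / 2.0
    if sd_d == 0.0:
        warnings.warn("zero-variance differences; t undefined, reported degenerate")
        return PairedResult(0.0 if md == 0 else math.inf, n - 1,
                            1.0 if md == 0 else 0.0, 0.0, 0.0, md, degenerate=True)
    t = md / (sd_d / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    d_av = md / sd_av if sd_av > 0 else math.nan
    return PairedResult(float(t), n - 1, float(p), md / sd_d, float(d_av), md)


def spearman(x, y, *, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with a two-sided p.

    The default p uses the t approximation; ``exact=True`` enumerates all
    pairings for n <= 8 and falls back to a large fixed-seed Monte Carlo
    permutation set for n in (8, 10].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman correlation undefined")
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    if exact:
        n = x.size
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        if n <= 8:
            perms = itertools.permutations(range(n))
            count = total = 0
            for pm in perms:
                r = abs(np.corrcoef(rx, ry[list(pm)])[0, 1])
                count += r >= obs - 1e-12
                total += 1
            p = count / total
        elif n <= 10:
            rng = np.random.default_rng(0)
            sims = np.array([
                abs(np.corrcoef(rx, ry[rng.permutation(n)])[0, 1]) for _ in range(100_000)
            ])
            p = float((1 + (sims >= obs - 1e-12).sum()) / (1 + sims.size))
        else:
            raise ValueError("exact permutation p-value supported only for n <= 10")
    return float(rho), float(p)


def _steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j."""
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    rm2 = (r_jk**2 + r_jh**2) / 2.0
    f = min((1.0 - r_kh) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z_jk - z_jh) * math.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    return z, 2.0 * stats.norm.sf(abs(z))


def compare_dependent_correlations(
    x1, x2, y, *, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Test rho(x1, y) vs rho(x2, y) on the same sample.

    Default inference is a permutation test that swaps the x1/x2 labels
    within participant; Steiger's Z on the Spearman correlations is reported
    alongside as an analytic cross-check.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if not (x1.shape == x2.shape == y.shape):
        raise ValueError("x1, x2, y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    attainable = 2.0 ** (1 - n)
    if n_perm > 0 and attainable > 0.01:
        warnings.warn(
            f"small n: attainable two-sided permutation p is bounded below by {attainable:.3g}"
        )

    def rho_diff(a, b):
        return stats.spearmanr(a, y)[0] - stats.spearmanr(b, y)[0]

    obs = rho_diff(x1, x2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flip = rng.random(n) < 0.5
        a = np.where(flip, x2, x1)
        b = np.where(flip, x1, x2)
        count += abs(rho_diff(a, b)) >= abs(obs) - 1e-12
    p_perm = (1 + count) / (1 + n_perm)
    r1 = stats.spearmanr(x1, y)[0]
    r2 = stats.spearmanr(x2, y)[0]
    r12 = stats.spearmanr(x1, x2)[0]
    z, p_z = _steiger_z(r1, r2, r12, n)
    return {"difference": float(obs), "p": float(p_perm), "rho1": float(r1),
            "rho2": float(r2), "steiger_z": float(z), "steiger_p": float(p_z),
            "n_perm": n_perm}


def rm_anova(values: pd.DataFrame) -> dict:
    """Region x Time repeated-measures ANOVA interaction.

    ``values`` is long-format with columns participant, region, time, value;
    the design must be complete (every participant in every cell).
    """
    required = {"participant", "region", "time", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    counts = values.groupby(["participant", "region", "time"]).size()
    expected = values["region"].nunique() * values["time"].nunique()
    per_subj = counts.groupby("participant").size()
    if (per_subj != expected).any() or counts.isna().any():
        raise ValueError("incomplete crossed design: missing cells")
    if np.ptp(values["value"].to_numpy()) == 0:
        return {"F": 0.0, "df1": np.nan, "df2": np.nan, "p": 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=values, dv="value", within=["region", "time"],
                          subject="participant", detailed=True)
    row = aov[aov["Source"].str.contains(r"\*")].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return {"F": float(row["F"]), "df1": float(row["ddof1"]),
            "df2": float(row["ddof2"]), "p": float(row[p_col])}
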