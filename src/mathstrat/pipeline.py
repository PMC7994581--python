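"""End-to-end orchestration: simulate -> fit -> strategies -> network -> joint -> report.

``run_pipeline`` drives the whole analysis from a single ``RunConfig``, writes
every stage's tables into a run directory, and emits a summary report that
mirrors the study's statistics: paired tests on accuracy, reaction time,
retrieval use and retrieval efficiency; the one-sample test of the pre/post
partition distance; per-node diversity-change tests with FDR; brain-behavior
Spearman correlations; and the joint-model Bayes factors.

Each stage communicates with the next only through its written files plus the
in-memory bundle returned to the caller; the config (with every seed) is
serialized into the run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from . import stats as bstats
from .inference import FitConfig, PriorSpec, fit_hierarchical, fit_joint_brain_model
from .model import preprocess_trials, retrieval_use_summary, IndividualParams, ItemParams
from .synth import CohortSpec, generate_item_bank, sample_population, simulate_behavior, simulate_networks

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_supplementary_source_data"]


@dataclass
class RunConfig:
    """Everything a run needs; every stochastic stage has an explicit seed."""

    out_dir: str = "results/run"
    seed: int = 0
    profile: str = "ci"          # "ci" (reduced MCMC) or "full" (paper-scale)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    prior: PriorSpec = field(default_factory=PriorSpec)
    n_restarts: int = 100        # Louvain restarts
    resolution: float = 1.0
    fdr_q: float = 0.05
    use_method: str = "mean"     # retrieval-use summary convention
    pool_bilateral_ips: bool = True

    def fit_config(self) -> FitConfig:
        if self.profile == "full":
            return FitConfig(seed=self.seed)
        return FitConfig.ci(seed=self.seed)


def _params_from_fit(fit, pids):
    """Posterior-median IndividualParams per (participant, session)."""
    med = {name: fit.median(name) for name in (
        "rho_pre", "d_rho", "delta_M_pre", "d_delta_M", "delta_C_pre",
        "d_delta_C", "alpha_pre", "d_alpha", "tau", "tau_switch_pre",
        "d_tau_switch") if name in fit.draws}
    out = {}
    for i, pid in enumerate(pids):
        for sess, s in (("pre", 0), ("post", 1)):
            out[(pid, sess)] = IndividualParams(
                rho_i=med["rho_pre"][i] + s * med.get("d_rho", np.zeros(len(pids)))[i],
                delta_M=med["delta_M_pre"][i] + s * med.get("d_delta_M", np.zeros(len(pids)))[i],
                delta_C=med["delta_C_pre"][i] + s * med.get("d_delta_C", np.zeros(len(pids)))[i],
                alpha=med["alpha_pre"][i] + s * med.get("d_alpha", np.zeros(len(pids)))[i],
                tau=med["tau"][i],
                tau_switch=max(med["tau_switch_pre"][i]
                               + s * med.get("d_tau_switch", np.zeros(len(pids)))[i], 0.0),
            )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated cohort; returns the bundle of
    stage outputs and writes them under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump({**asdict(config), "cohort": asdict(config.cohort),
                   "prior": asdict(config.prior)}, fh, indent=1, default=str)

    # -- stage 1: simulate
    spec = config.cohort
    items = generate_item_bank(spec, seed=config.seed)
    pop = sample_population(spec, seed=config.seed + 1)
    trials_raw, truth = simulate_behavior(pop, items, spec, seed=config.seed + 2)
    matrices, net_truth = simulate_networks(spec, pop[["d_delta_M"]], seed=config.seed + 3)
    trials = preprocess_trials(trials_raw)
    trials.to_csv(out / "trials.csv", index=False)
    pop.to_csv(out / "truth_params.csv")
    net_truth.to_csv(out / "truth_network.csv")

    # -- stage 2: fit the strategy model
    fit = fit_hierarchical(trials, config.prior, config.fit_config())
    fit.to_csv(out / "posterior_samples.csv")
    fit.summary_json(out / "posterior_summary.json")
    pids = fit.meta["participants"]

    # -- stage 3: strategy use and efficiency summaries
    params = _params_from_fit(fit, pids)
    item_map = {
        r.item_id: ItemParams(r.item_id, int(min(r.addend_a, r.addend_b)), rho)
        for (_, r), rho in zip(
            items.iterrows(), fit.median("rho_item"))
    }
    use = retrieval_use_summary(trials, params, item_map, method=config.use_method)
    dM = pd.Series({(pid, sess): params[(pid, sess)].delta_M for pid in pids
                    for sess in ("pre", "post")})
    behav = trials.dropna(subset=["rt_seconds"]).groupby(
        ["participant_id", "session"]).agg(
        accuracy=("response_correct", "mean"), mean_rt=("rt_seconds", "mean"))
    summary = behav.copy()
    summary["retrieval_use"] = use
    summary["retrieval_efficiency"] = dM
    summary.to_csv(out / "participant_summaries.csv")

    # -- stage 4: network analysis
    partitions = {}
    for key, cm in matrices.items():
        partitions[key] = net.louvain_modules(cm, config.resolution,
                                              config.n_restarts, seed=config.seed + 10)
    dist = pd.Series({pid: net.partition_distance(partitions[(pid, "pre")],
                                                  partitions[(pid, "post")])
                      for pid in pids}, name="partition_distance")
    dist_test = net.test_distance_nonzero(dist.to_numpy())
    group = {}
    for sess in ("pre", "post"):
        g = net.group_average_network([matrices[(pid, sess)] for pid in pids])
        group[sess] = net.louvain_modules(g, config.resolution, config.n_restarts,
                                          seed=config.seed + 11)
    labels = next(iter(matrices.values())).node_labels
    div = {
        sess: pd.DataFrame(
            [net.diversity_coefficient(matrices[(pid, sess)], partitions[(pid, sess)]).values
             for pid in pids], index=pids, columns=labels)
        for sess in ("pre", "post")
    }
    pool = {"IPS": ["L_IPS", "R_IPS"]} if (
        config.pool_bilateral_ips and "L_IPS" in labels) else None
    node_tests = net.node_change_tests(div["pre"], div["post"], pool=pool,
                                       fdr_q=config.fdr_q)
    node_tests.to_csv(out / "node_diversity_tests.csv", index=False)
    dist.to_csv(out / "partition_distances.csv")

    # -- stage 5: joint brain-behavior model
    coupled = spec.coupled_node
    d_div = div["post"][coupled] - div["pre"][coupled]
    joint = fit_joint_brain_model(trials, d_div, config.prior, config.fit_config())
    joint.betas.to_csv(out / "joint_model_betas.csv", index=False)

    # -- stage 6: statistics report
    wide = summary.unstack("session")
    report_rows = []
    for measure in ("accuracy", "mean_rt", "retrieval_use", "retrieval_efficiency"):
        res = bstats.paired_t(wide[(measure, "pre")], wide[(measure, "post")])
        report_rows.append({"analysis": f"paired_t_{measure}", "stat": res.t,
                            "p": res.p, "effect": res.d_av, "n": res.df + 1})
    report_rows.append({"analysis": "partition_distance_vs_zero",
                        "stat": dist_test["t"], "p": dist_test["p"],
                        "effect": dist_test["mean"], "n": dist_test["n"]})
    d_acc = wide[("accuracy", "post")] - wide[("accuracy", "pre")]
    d_rt = wide[("mean_rt", "post")] - wide[("mean_rt", "pre")]
    d_use = wide[("retrieval_use", "post")] - wide[("retrieval_use", "pre")]
    d_eff = wide[("retrieval_efficiency", "post")] - wide[("retrieval_efficiency", "pre")]
    for name, (x, yv) in {
        "distance_vs_accuracy_gain": (dist, d_acc),
        "hipp_diversity_change_vs_accuracy_gain": (d_div, d_acc),
        "hipp_diversity_change_vs_efficiency_gain": (d_div, d_eff),
        "efficiency_gain_vs_accuracy_gain": (d_eff, d_acc),
        "use_gain_vs_rt_change": (d_use, d_rt),
    }.items():
        rho, p = bstats.spearman(x.loc[pids], yv.loc[pids])
        report_rows.append({"analysis": f"spearman_{name}", "stat": rho, "p": p,
                            "effect": rho, "n": len(pids)})
    for _, row in joint.betas.iterrows():
        report_rows.append({"analysis": f"joint_bf_{row['parameter']}",
                            "stat": row["beta_median"], "p": np.nan,
                            "effect": row["bf10"], "n": len(pids)})
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "report.csv", index=False)
    with open(out / "report.txt", "w") as fh:
        fh.write("Analysis report (seed %d, profile %s)\n\n" % (config.seed, config.profile))
        fh.write(report.to_string(index=False))
        fh.write("\n\nGroup modules pre: %d, post: %d\n"
                 % (group["pre"].n_modules, group["post"].n_modules))

    return {
        "trials": trials, "fit": fit, "summary": summary, "report": report,
        "partitions": partitions, "group_partitions": group,
        "distances": dist, "distance_test": dist_test,
        "diversity": div, "node_tests": node_tests, "joint": joint,
        "truth": {"params": pop, "network": net_truth, "labels": truth},
    }


# -------------------------------------------------- supplementary data loader

_COLUMN_HINTS = {
    "accuracy_pre": ["accuracy_pre", "acc_pre", "pre_accuracy"],
    "accuracy_post": ["accuracy_post", "acc_post", "post_accuracy"],
    "rt_pre": ["rt_pre", "reaction_time_pre", "pre_rt"],
    "rt_post": ["rt_post", "reaction_time_post", "post_rt"],
    "use_pre": ["use_pre", "retrieval_use_pre", "memory_use_pre"],
    "use_post": ["use_post", "retrieval_use_post", "memory_use_post"],
    "efficiency_pre": ["efficiency_pre", "drift_pre", "retrieval_efficiency_pre"],
    "efficiency_post": ["efficiency_post", "drift_post", "retrieval_efficiency_post"],
    "distance": ["distance", "partition_distance", "mutual_information_distance"],
    "hipp_diversity_change": ["hipp_diversity_change", "d_diversity_hipp",
                              "rhipp_diversity_change"],
}


def load_supplementary_source_data(path) -> dict[str, pd.DataFrame]:
    """Parse the per-child source-data workbook/CSV into tidy tables.

    The loader is schema-tolerant: it scans every sheet (xlsx) or the single
    table (csv), lowercases and snake_cases the headers, maps recognized
    column aliases, and reports what it found.  Raises a clear error if the
    file is absent or no recognizable columns exist.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"supplementary source-data file not found at {p}; download the "
            "per-child source data (Supplementary Data 1) and pass its path"
        )
    if p.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(p, sheet_name=None)
    else:
        sheets = {"data": pd.read_csv(p)}
    found: dict[str, pd.DataFrame] = {}
    diagnostics = {}
    for sheet, df in sheets.items():
        df = df.rename(columns=lambda c: str(c).strip().lower().replace(" ", "_"))
        mapped = {}
        for canon, aliases in _COLUMN_HINTS.items():
            for a in aliases:
                if a in df.columns:
                    mapped[a] = canon
                    break
        diagnostics[sheet] = {"columns": list(df.columns), "recognized": list(mapped.values())}
        if mapped:
            found[sheet] = df.rename(columns=mapped)
    if not found:
        raise ValueError(
            "no recognizable per-child columns in any sheet; found: "
            + json.dumps(diagnostics, indent=1)
        )
    logger.info("supplementary data parsed: %s", {k: v.shape for k, v in found.items()})
    return found
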