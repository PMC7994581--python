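#!/usr/bin/env python
"""Pre/post training gains: paired t-tests (with both Cohen's d conventions)
on accuracy, reaction time, memory-retrieval use and retrieval efficiency,
plus the cross-measure Spearman correlations among the change scores.
"""

import argparse
from pathlib import Path

import pandas as pd

from mathstrat.stats import paired_t, spearman


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fit", type=Path, default=Path("results/fit"))
    ap.add_argument("--out", type=Path, default=Path("results/behavior"))
    args = ap.parse_args()

    summary = pd.read_csv(args.fit / "participant_summaries.csv")
    wide = summary.pivot(index="participant_id", columns="session")
    rows = []
    for measure in ("accuracy", "mean_rt", "retrieval_use", "retrieval_efficiency"):
        res = paired_t(wide[(measure, "pre")], wide[(measure, "post")])
        rows.append({"measure": measure, "t": res.t, "df": res.df, "p": res.p,
                     "d_z": res.d_z, "d_av": res.d_av})
        print(f"{measure:22s} t({res.df}) = {res.t:6.2f}, p = {res.p:.2g}, "
              f"d_av = {res.d_av:.2f}")
    gains = pd.DataFrame(rows)

    d = {m: wide[(m, "post")] - wide[(m, "pre")]
         for m in ("accuracy", "mean_rt", "retrieval_use", "retrieval_efficiency")}
    corr_rows = []
    for a, b in [("retrieval_efficiency", "accuracy"),
                 ("retrieval_use", "mean_rt"),
                 ("retrieval_efficiency", "mean_rt"),
                 ("retrieval_use", "accuracy")]:
        rho, p = spearman(d[a], d[b])
        corr_rows.append({"x": f"d_{a}", "y": f"d_{b}", "rho": rho, "p": p})
        print(f"rho(d_{a}, d_{b}) = {rho:5.2f}, p = {p:.2g}")

    args.out.mkdir(parents=True, exist_ok=True)
    gains.to_csv(args.out / "paired_gains.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(args.out / "change_correlations.csv", index=False)


if __name__ == "__main__":
    main()
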