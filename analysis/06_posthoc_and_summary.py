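#!/usr/bin/env python
"""Univariate follow-ups and the cohort characteristics report.

Fits post-hoc OLS regressions (standardized ROI volume on two-group
indicator + age + sex) for the top-2 delta regions of each contrast, and
writes the sample-characteristics report (group-by-sex counts, TBV means,
one-way ANOVA on TBV, chi-square tests of group independence for income
and parental education).  Outputs under results/posthoc/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import netmdmr as nm

ROOT = Path(__file__).resolve().parents[1] / "results"
PAIRS = [("P-high", "P-low"), ("P-high", "changers"), ("P-low", "changers")]


def main() -> None:
    out = ROOT / "posthoc"
    out.mkdir(parents=True, exist_ok=True)
    cohort = nm.read_cohort(ROOT / "synthetic" / "cohort.csv")
    groups = cohort["group"].astype(str).to_numpy()

    rows = []
    for net in ("FPN", "DMN"):
        Y = pd.read_csv(ROOT / "normalized" / f"tscores_{net}.csv",
                        index_col="participant_id", float_precision="round_trip")
        deltas = pd.read_csv(ROOT / "effect_sizes" / f"delta_{net}.csv",
                             index_col="column")
        for a, b in PAIRS:
            tab = deltas[deltas["contrast"] == f"{a} vs {b}"]
            top = nm.rank_regions(tab, top_k=2).index.tolist()
            mask = np.isin(groups, [a, b])
            sub = cohort.loc[mask].reset_index(drop=True)
            Ysub = Y.loc[mask]
            Ysub.index = sub.index
            tbl = nm.posthoc_table(Ysub, sub, top, [(a, b)])
            tbl.insert(0, "network", net)
            rows.append(tbl)
    posthoc = pd.concat(rows, ignore_index=True)
    posthoc.to_csv(out / "posthoc_regressions.csv", index=False)
    print("post-hoc regressions (standardized beta, SE, p):")
    for _, r in posthoc.iterrows():
        print(f"  {r.network} {r.contrast:<22} {r.column:<38} "
              f"beta={r.beta:+.2f} SE={r.se:.2f} p={r.p:.4f}")

    rep = nm.cohort_summary(cohort)
    rep["counts"].to_csv(out / "counts.csv")
    payload = {"n": rep["n"], "anova": rep["anova"], "chi2": rep["chi2"],
               "ols_contrasts": rep["ols_contrasts"]}
    (out / "summary.json").write_text(json.dumps(payload, indent=2, default=str))
    tbv = rep["anova"]["tbv_cm3"]
    print(f"\nTBV one-way ANOVA: F({tbv['df1']}, {tbv['df2']}) = {tbv['F']:.2f}, "
          f"p = {tbv['p']:.2f}")
    for cov, res in rep["chi2"].items():
        if res["status"] == "ok":
            print(f"chi2 independence {cov}: chi2({res['df']}) = {res['chi2']:.1f}, "
                  f"p = {res['p']:.2f}")
    print(f"\nwrote post-hoc tables and summary to {out}")


if __name__ == "__main__":
    main()
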