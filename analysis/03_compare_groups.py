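#!/usr/bin/env python
"""Step 3 — nonparametric group comparisons.

From the measured summaries: per parameter and region, a Kruskal-Wallis
omnibus test across groups and Holm-adjusted pairwise Wilcoxon rank-sum
tests; within each group, Wilcoxon signed-rank tests of whether the
distal:proximal ratios depart from 1.

    results/statistics/kruskal_wallis.csv
    results/statistics/pairwise_holm.csv
    results/statistics/ratio_tests.csv
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from osteogrid import pipeline as pl
from osteogrid.regions import RATIO_PARAMETERS
from osteogrid.stats_allometry import signed_rank_ratio
from osteogrid.volume_io import read_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--measurements", default="results/measurements")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", default="results/statistics")
    args = ap.parse_args()

    summaries = read_table(os.path.join(args.measurements, "summaries.csv"))
    ratios = read_table(os.path.join(args.measurements, "ratios.csv"))
    os.makedirs(args.out, exist_ok=True)

    omni, pairw = pl.group_comparison_tables(summaries, alpha=args.alpha)
    write_table(omni, os.path.join(args.out, "kruskal_wallis.csv"))
    write_table(pairw, os.path.join(args.out, "pairwise_holm.csv"))

    rows = []
    cols = list(RATIO_PARAMETERS) + ["cortical_contribution_distal",
                                     "cortical_contribution_proximal"]
    for g, sub in ratios.groupby("group", sort=True):
        for param in cols:
            v = sub[param].dropna().to_numpy()
            if (v != 1.0).sum() < 2:
                continue
            V, p = signed_rank_ratio(v)
            rows.append({"group": g, "parameter": param, "n": len(v),
                         "V": V, "p": p, "significant": p <= args.alpha})
    tests = pd.DataFrame(rows)
    write_table(tests, os.path.join(args.out, "ratio_tests.csv"))

    sig = omni[omni["significant"]]
    print(f"omnibus tests: {len(omni)}, significant at alpha={args.alpha}: {len(sig)}")
    if len(sig):
        print(sig[["region", "parameter", "H", "p"]].to_string(index=False))
    print(f"ratio signed-rank tests: {len(tests)} -> {args.out}")


if __name__ == "__main__":
    main()
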