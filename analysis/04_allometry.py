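#!/usr/bin/env python
"""Step 4 — reduced major axis allometry and category replay.

Regresses each logged whole-bone parameter on the logged cube root of
bone volume (RMA, whole sample and per group), classifies each fit as
Positive / Negative / Isometry / Uncorrelated against its isometric
expectation (0 for shape-like, 1 for size-like parameters), and replays
the classification rule over the bundled published capitate regression
table as an external check.

    results/statistics/allometry.csv
    results/statistics/allometry_replay.csv
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from osteogrid import pipeline as pl
from osteogrid.datasets import load_capitate_rma_table
from osteogrid.stats_allometry import AllometryResult, classify_allometry
from osteogrid.volume_io import read_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--measurements", default="results/measurements")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", default="results/statistics")
    args = ap.parse_args()

    summaries = read_table(os.path.join(args.measurements, "summaries.csv"))
    os.makedirs(args.out, exist_ok=True)
    allom = pl.allometry_tables(summaries, alpha=args.alpha)
    write_table(allom, os.path.join(args.out, "allometry.csv"))
    print(allom[["scope", "parameter", "slope", "ci_low", "ci_high",
                 "r2", "p", "category"]].to_string(index=False))

    table = load_capitate_rma_table()
    rows = []
    for _, row in table.iterrows():
        fit = AllometryResult(
            parameter=row["parameter"], scope=row["scope"], slope=row["slope"],
            intercept=row["intercept"], ci_low=row["ci_low"],
            ci_high=row["ci_high"], r2=row["r2_num"], p=row["p_num"], n=0,
        )
        got = classify_allometry(fit, int(row["isometric_slope"]), alpha=args.alpha)
        rows.append({"scope": row["scope"], "parameter": row["parameter"],
                     "published": row["category"], "recomputed": got,
                     "agree": got == row["category"]})
    replay = pd.DataFrame(rows)
    write_table(replay, os.path.join(args.out, "allometry_replay.csv"))
    print(f"\npublished-category replay: {replay['agree'].sum()}/{len(replay)} agree")


if __name__ == "__main__":
    main()
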