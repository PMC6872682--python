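#!/usr/bin/env python
"""Statistical summary of the per-tooth discrepancy angles.

Reads results/per_tooth_angles.csv (written by 02_run_pipeline.py),
produces the descriptive table by jaw and tooth category, runs the
Kruskal-Wallis test across the mandibular tooth categories, reports the
a-priori sample-size calculation, and writes a machine-readable stats
report.

Run:  python analysis/03_statistics.py
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from rootaxis.stats import (
    descriptive_table,
    kruskal_wallis,
    sample_size_mean_difference,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.results / "per_tooth_angles.csv")
    df = df[df["flags"].isna() | (df["flags"] == "")]

    rows = descriptive_table(df)
    print("descriptive statistics of the discrepancy angle (degrees):")
    for r in rows:
        print("  " + r.display())
    table = pd.DataFrame([asdict(r) for r in rows])
    table.to_csv(args.results / "descriptives.csv", index=False)

    mand = df[df.jaw == 2]
    groups = [mand[mand.tooth_type == t].angle_deg.to_numpy() for t in (1, 2, 3)]
    kw = kruskal_wallis(groups)
    print(
        f"Kruskal-Wallis over mandibular categories: "
        f"H = {kw.H:.3f}, df = {kw.df}, p = {kw.p_value:.3f}"
    )

    n_req = sample_size_mean_difference(0.05, 0.80, 7.0, 3.0)
    print(f"a-priori sample size (alpha 0.05, power 80%, SD 7, delta 3): {n_req} teeth")

    report = {
        "descriptives": [asdict(r) for r in rows],
        "kruskal_wallis_mandible": asdict(kw),
        "sample_size": {"alpha": 0.05, "power": 0.80, "sd": 7.0, "delta": 3.0, "n": n_req},
    }
    (args.results / "stats_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"report -> {args.results/'stats_report.json'}")


if __name__ == "__main__":
    main()
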