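#!/usr/bin/env python
"""Collect scenario summaries into the three benchmark comparison tables.

Reads the *_summary.json files written by 02_run_scenarios and emits

* table_base_measure.csv   — baseline vs D/4 vs R/4 prior misspecification,
* table_concentration.csv  — the gamma_b / rho_c concentration sweep,
* table_observation.csv    — 3D vs naive-2D vs hidden-z observation models,

plus conditional_assignment_<scenario>.csv matrices (the per-true-state
distribution of aligned estimates).

    python analysis/03_summarize_tables.py --in results/scenarios --out results/tables
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

TABLES = {
    "table_base_measure.csv": ["baseline", "D_div4", "R_div4"],
    "table_concentration.csv": ["baseline", "gamma_b_0.001", "gamma_b_0.1",
                                "rho_c_5", "rho_c_100"],
    "table_observation.csv": ["baseline", "naive_2d", "hidden_z"],
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path,
                    default=Path("results/scenarios"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summaries = {}
    for p in sorted(args.indir.glob("*_summary.json")):
        s = json.loads(p.read_text())
        summaries[s["scenario"].replace("=", "_")] = s

    if not summaries:
        raise SystemExit(f"no *_summary.json under {args.indir}")

    for fname, wanted in TABLES.items():
        rows = [summaries[w] for w in wanted if w in summaries]
        if not rows:
            continue
        df = pd.DataFrame([{
            "scenario": r["scenario"],
            "mean_hamming": round(r["mean_hamming"], 3),
            "se": round(r["se"], 3),
            "sd": round(r["sd"], 3),
            "n": r["n"],
        } for r in rows])
        df.to_csv(args.out / fname, index=False)
        print(f"\n{fname.removesuffix('.csv')}:")
        print(df.to_string(index=False))

    for name, s in summaries.items():
        M = np.array([[np.nan if v is None else v for v in row]
                      for row in s["cond_matrix"]])
        labels = s["cond_labels"]
        pd.DataFrame(M, index=[f"true_{l}" for l in labels],
                     columns=[f"est_{l}" for l in labels]).to_csv(
            args.out / f"conditional_assignment_{name}.csv")
    print(f"\nwrote tables and conditional-assignment matrices to {args.out}")


if __name__ == "__main__":
    main()
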