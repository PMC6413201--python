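#!/usr/bin/env python
"""Deterministic displacement-mortality grid.

Projects the calibrated per-worker risks to all four employment-loss
scenarios (0.1%, 0.3%, 0.6%, 1% of processed-meat employment) and compares
every cell against the published grid. Writes
results/displacement_deaths.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import meatrisk as m

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

grid = m.load_reference_mortality()
wf = m.WorkforceSpec(sector_total=1_000_000, processed_share=0.542)
specs = {s.cause: s for s in
         m.calibrate_from_reference(grid, wf, loss_fraction=0.01)}

rows, max_err = [], 0.0
for _, ref in grid.iterrows():
    n = m.displaced_workers(wf, m.EmploymentScenario(ref["loss_fraction"]))
    res = m.project_excess_deaths(specs[ref["cause"]], n)
    rows.append({"cause": ref["cause"], "loss_fraction": ref["loss_fraction"],
                 "n_workers": n, "mean": res.mean, "ci_low": res.ci_low,
                 "ci_high": res.ci_high})
    max_err = max(max_err, abs(res.mean - ref["expected_deaths"]),
                  abs(res.ci_low - ref["ci_low"]),
                  abs(res.ci_high - ref["ci_high"]))

df = pd.DataFrame(rows)
args.out_dir.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out_dir / "displacement_deaths.csv", index=False)

wide = df.assign(cell=df.apply(
    lambda r: f"{r['mean']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f})",
    axis=1)).pivot(index="cause", columns="loss_fraction", values="cell")
print("Expected 4-year deaths among displaced workers (95% CI):")
print(wide.to_string())
print(f"\nMax |projected - published| over all 60 numbers: {max_err:.4f} "
      "(printed rounding only)")
print(f"Wrote {args.out_dir / 'displacement_deaths.csv'}")
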