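#!/usr/bin/env python
"""Monte Carlo displacement mortality: 10,000 draws per scenario cell.

Runs the second-order simulation (normal parameter draws; worker-level
binomial cohorts by default) for all five causes at the -1% scenario and
compares means and intervals against the deterministic projection. Writes
results/displacement_deaths_mc.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import meatrisk as m

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=20190214)
parser.add_argument("--n-sims", type=int, default=10_000)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

grid = m.load_reference_mortality()
wf = m.WorkforceSpec(sector_total=1_000_000, processed_share=0.542)
specs = m.calibrate_from_reference(grid, wf, loss_fraction=0.01)
n = m.displaced_workers(wf, m.EmploymentScenario(0.01))

rng = np.random.default_rng(args.seed)
rows = []
for spec in specs:
    det = m.project_excess_deaths(spec, n)
    for level, label in ((True, "worker_level"), (False, "parameter_level")):
        mc = m.MCConfig(n_sims=args.n_sims,
                        seed=int(rng.integers(2**31 - 1)))
        res = m.simulate_excess_deaths(spec, n, mc=mc, worker_level=level)
        rows.append({"cause": spec.cause, "sampling": label,
                     "mean": res.mean, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "det_mean": det.mean,
                     "det_ci_low": det.ci_low, "det_ci_high": det.ci_high,
                     "n_sims": mc.n_sims, "seed": args.seed})

df = pd.DataFrame(rows)
args.out_dir.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out_dir / "displacement_deaths_mc.csv", index=False)

print(f"-1% scenario, n = {n:.0f} displaced workers, "
      f"{args.n_sims} draws, seed {args.seed}:")
for _, r in df.iterrows():
    print(f"  {r['cause']:<20s} {r['sampling']:<16s} "
          f"mean {r['mean']:8.2f} (det {r['det_mean']:8.2f})  "
          f"CI ({r['ci_low']:8.2f}, {r['ci_high']:8.2f})")
print("Parameter-level intervals track the deterministic projection; "
      "worker-level intervals are wider by the cohorts' binomial noise.")
print(f"Wrote {args.out_dir / 'displacement_deaths_mc.csv'}")
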