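#!/usr/bin/env python
"""Measure every phantom mask and compare against analytic ground truth.

Reads results/simulation/masks (run 01_simulate_phantoms.py first) and
writes, under results/morphometry/:
  vessel_metrics.csv     per-vessel VL, chord, DM, SD_theta, N, M, VTI
  subject_summaries.csv  per-subject count and mean/median/SD summaries
"""

import sys
from pathlib import Path

import pandas as pd

from lsamorph import RunConfig, run_measure

mask_dir = Path("results/simulation/masks")
if not mask_dir.exists():
    sys.exit("no masks found - run analysis/01_simulate_phantoms.py first")

config = RunConfig(mask_dir=str(mask_dir), out_dir="results/morphometry",
                   min_branch_mm=2.0, seed=20260922)
out = run_measure(config)

vessels = pd.read_csv(out / "vessel_metrics.csv")
truth = pd.read_csv("results/simulation/curve_ground_truth.csv")
merged = vessels.merge(truth, left_on="vessel_file", right_on="file")
vl_err = (merged.vl_mm / merged.arc_length_mm - 1).abs() * 100
dm_err = (merged.dm / merged.dm_true - 1).abs() * 100

print(f"measured {len(vessels)} vessels "
      f"({vessels.subject_id.nunique()} subjects)")
print(f"VL error vs analytic truth: median {vl_err.median():.2f}%, "
      f"max {vl_err.max():.2f}%")
print(f"DM error vs analytic truth: median {dm_err.median():.2f}%, "
      f"max {dm_err.max():.2f}%")
print(f"VTI range across phantoms: {vessels.vti.min():.2f} .. "
      f"{vessels.vti.max():.2f} (straight curves are exactly 0)")
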