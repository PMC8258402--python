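#!/usr/bin/env python
"""Run the covariate-adjusted comparison grid on the simulated cohort.

Reads results/simulation/cohort.csv and writes
results/statistics/stat_results.csv: ANCOVA (age/sex/ICV-adjusted) for
each risk factor x outcome, partial Spearman for each artery diameter x
outcome, Bonferroni-corrected within each family.
"""

import sys
from pathlib import Path

import pandas as pd

from lsamorph import RunConfig, run_analyze

cohort_csv = Path("results/simulation/cohort.csv")
if not cohort_csv.exists():
    sys.exit("no cohort found - run analysis/01_simulate_phantoms.py first")

config = RunConfig(cohort_csv=str(cohort_csv), out_dir="results/statistics",
                   seed=20260922)
out = run_analyze(config)

results = pd.read_csv(out / "stat_results.csv")
print(f"{len(results)} comparisons "
      f"({(results.family == 'risk_factors').sum()} risk-factor ANCOVAs, "
      f"{(results.family == 'diameters').sum()} diameter correlations)")
hits = results[results.p_raw < 0.05].sort_values("p_raw")
print("\nnominally significant (p_raw < 0.05):")
for row in hits.itertuples():
    print(f"  {row.comparison:38s} effect {row.effect:+.3f}  "
          f"p {row.p_raw:.4f}  p_adj {row.p_adjusted:.3f}")
fw = results[results.p_adjusted < 0.05]
print(f"\nfamily-wise significant after Bonferroni: {len(fw)}")
for row in fw.itertuples():
    print(f"  {row.comparison:38s} effect {row.effect:+.3f}  "
          f"p_adj {row.p_adjusted:.3f}")
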