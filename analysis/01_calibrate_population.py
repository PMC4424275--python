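#!/usr/bin/env python
"""Calibrate the synthetic forest population to the study targets.

Starting from neutral generator settings, moment-match the plot panel to
the study population: occasion means 120.3 / 132.5 t/ha, between-occasion
correlation 0.804, and tree counts 8650 / 8191 on 750 subplots of 400 m2.
Writes the fitted parameters and a panel summary table under results/.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

import sprforest as sf
from sprforest import io as sfio
from sprforest.population import CalibrationTargets, PopulationParams, calibrate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    targets = CalibrationTargets()
    start = PopulationParams(growth_mean=2.0, plot_growth_sd=2.0)
    params = calibrate(start, targets, tol_mean=0.01, tol_r=0.01,
                       seed=args.seed, n_seeds=30, max_iter=60)
    sfio.write_params(params, args.out / "population_params.yaml")

    rows = []
    for s in range(20):
        pop = sf.generate_population(replace(params, seed=args.seed + 5000 + s))
        summ = sf.summarize_panel(sf.build_panel(pop))
        rows.append({"seed": s, "n_trees_t1": pop.n_trees_t1,
                     "n_trees_t2": pop.n_trees_t2,
                     "mean_t1": summ.t1.mean, "mean_t2": summ.t2.mean,
                     "sd_t1": summ.t1.sd, "sd_t2": summ.t2.sd,
                     "correlation": summ.correlation})
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "panel_summary.csv", index=False)

    print("calibrated parameters written to", args.out / "population_params.yaml")
    print(f"  dbh_scale        = {params.dbh_scale:.3f} cm")
    print(f"  mortality_prob   = {params.mortality_prob:.4f}")
    print(f"  growth_mean      = {params.growth_mean:.3f} cm / period")
    print(f"  plot_growth_sd   = {params.plot_growth_sd:.3f}")
    print("panel over 20 fresh populations "
          f"(targets {targets.mean_t1} / {targets.mean_t2} t/ha, r {targets.correlation}):")
    print(f"  mean t1 = {df.mean_t1.mean():.1f} t/ha, mean t2 = {df.mean_t2.mean():.1f} t/ha, "
          f"r = {df.correlation.mean():.3f}")
    print(f"  tree counts = {df.n_trees_t1.mean():.0f} -> {df.n_trees_t2.mean():.0f} "
          "(targets 8650 -> 8191)")
    print(f"  plot SDs = {df.sd_t1.mean():.1f} / {df.sd_t2.mean():.1f} t/ha "
          "(the occasion-2 SD exceeds the study's 65.5; see docs/methods.md)")


if __name__ == "__main__":
    main()
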