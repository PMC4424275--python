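#!/usr/bin/env python
"""True biomass change under each disturbance scenario.

For each of the six scenarios, compute the expected population-level
change (undisturbed growth minus the expected disturbance loss under the
SRSWOR affected-plot draw), averaged over 12 population realizations.
Only heavy degradation of large trees (dbh > 45 cm on 20% of plots)
should outweigh growth.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from sprforest import io as sfio
from sprforest.montecarlo import PanelSource, expected_true_change


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--populations", type=int, default=12)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params = sfio.default_params()
    scenarios = sfio.default_scenarios()
    rows = []
    for k in range(args.populations):
        source = PanelSource.from_params(replace(params, seed=args.seed + 4000 + k))
        for spec in scenarios:
            rows.append({"population": k, "scenario": spec.name,
                         "true_change_tha": expected_true_change(source, spec)})
    df = pd.DataFrame(rows)
    agg = df.groupby("scenario", sort=False)["true_change_tha"].agg(["mean", "std"])
    agg.to_csv(args.out / "true_changes.csv")

    print(f"expected true change over {args.populations} populations (t/ha):")
    for name, row in agg.iterrows():
        print(f"  {name:16s} {row['mean']:+6.2f} +- {row['std']:.2f}")
    negatives = agg[agg["mean"] < 0].index.tolist()
    print("net biomass loss only under:", negatives or "none")


if __name__ == "__main__":
    main()
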