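#!/usr/bin/env python
"""AFM cell-cell detachment: work, force histograms, cadherin fraction.

Simulates force-distance curve batches for a strongly adhering condition
(mean well depth 200 pN) and a cadherin-compromised one (mean depth
80 pN), both at 300 pN contact force / 5 s contact time, with baseline
noise.  Computes per-curve detachment work (area enclosed between
approach and retract), maximum detachment force, the 25 pN-binned force
histogram and the percentage of cadherin-dependent events (force
strictly above 150 pN).

Finding: detachment work and the cadherin-dependent fraction separate
the two conditions cleanly; recovered works track the analytic
1/2*depth*width ground truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ccpol.afm import analyze_curves, force_histogram, parse_curve
from ccpol.io_core import RunConfig, write_results
from ccpol.synthetic import ForceCurveSpec, gen_force_curve


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows, all_results = [], []
    for cond, mean_depth in (("strong_adhesion", 200.0), ("weak_adhesion", 80.0)):
        curves, truths = [], []
        for i in range(40):
            depth = max(10.0, rng.normal(mean_depth, mean_depth * 0.35))
            width = max(0.5, rng.normal(2.0, 0.4))
            table, w_true, f_true = gen_force_curve(ForceCurveSpec(
                adhesion_depth=depth, adhesion_width=width,
                baseline_noise_sd=3.0, seed=int(rng.integers(2**31))))
            curves.append(parse_curve(table))
            truths.append({"work_true_fJ": w_true, "force_true_pN": f_true})
        res = analyze_curves(curves)
        res = pd.concat([res, pd.DataFrame(truths)], axis=1)
        res["condition"] = cond
        all_results.append(res)
        counts, edges = force_histogram(res.max_force_pN, bin_width=25.0)
        cadherin_pct = 100.0 * (res.max_force_pN > 150.0).mean()
        rows.append({"condition": cond,
                     "mean_work_fJ": float(res.work_fJ.mean()),
                     "mean_max_force_pN": float(res.max_force_pN.mean()),
                     "cadherin_dependent_percent": cadherin_pct,
                     "max_work_rel_error": float(
                         ((res.work_fJ - res.work_true_fJ).abs()
                          / res.work_true_fJ).max())})
    summary = pd.DataFrame(rows)
    results = pd.concat(all_results, ignore_index=True)

    write_results({"curves": results.drop(columns=[]), "summary_by_condition": summary},
                  {"conditions": rows},
                  args.out, config=RunConfig(seed=args.seed), prefix="afm")

    print(summary.to_string(index=False))
    print("work recovery worst relative error:",
          f"{summary.max_work_rel_error.max():.3%}")


if __name__ == "__main__":
    main()
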