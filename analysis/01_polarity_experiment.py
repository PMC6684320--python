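#!/usr/bin/env python
"""Simulated scratch-wound polarity experiment: coordinated vs uncoordinated.

Generates monolayers for a control-like condition (von Mises concentration
kappa = 2.5 up to 300 um behind the wound edge) and a junction-disrupted
condition (kappa floor only in the first 50 um, emulating the geometric
polarity bias of the free edge), runs the full pipeline (centroids ->
global nucleus-Golgi assignment -> polarity angles -> 50 um binned PI),
derives the uncoordination threshold (mean + 1 SD of the per-image per-bin
PIs of the uncoordinated condition, first bin excluded), and writes the
merged PI-vs-distance profiles.

Finding: the coordinated profile stays above the threshold up to 300 um
and drops below beyond it; the uncoordinated profile is below threshold
everywhere past the first row, whose PI stays high purely from edge
geometry.
"""

import argparse
from pathlib import Path

import pandas as pd

from ccpol.io_core import RunConfig, write_results
from ccpol.workflows import run_two_condition_experiment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = run_two_condition_experiment(seed=args.seed)
    thr = out["threshold"]
    table = out["profile_table"]
    per_image = pd.concat([
        out["coordinated"].per_image_table.assign(condition="coordinated"),
        out["uncoordinated"].per_image_table.assign(condition="uncoordinated"),
    ], ignore_index=True)

    write_results(
        {"profile": table, "per_image_bins": per_image},
        {"threshold_pi": thr,
         "n_images": {"coordinated": 9, "uncoordinated": 4}},
        args.out, config=RunConfig(seed=args.seed), prefix="polarity")

    print(f"uncoordination threshold: PI = {thr:.3f} "
          "(mean + 1 SD of uncoordinated per-bin PIs, first bin excluded)")
    for cond in ("coordinated", "uncoordinated"):
        t = table[table.condition == cond]
        coords = ", ".join(f"{int(r.bin_start_um)}um:{r.pi:.2f}"
                           for r in t.itertuples())
        print(f"{cond} merged profile: {coords}")
    un_past = table[(table.condition == "uncoordinated") & (table.bin_start_um > 0)]
    print("uncoordinated below threshold past first bin:",
          bool((un_past.pi < thr).all()))


if __name__ == "__main__":
    main()
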