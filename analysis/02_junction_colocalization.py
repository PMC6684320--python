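#!/usr/bin/env python
"""Junction co-localization time course (calcium-switch emulation).

Generates two-channel spot images whose true pixel-overlap fraction ramps
from 0 to 50% - as junction components re-associate after calcium
restoration - segments both channels, and quantifies the object-based
overlap percentage per timepoint with the query-channel denominator.

Finding: the recovered time course tracks the generated ground truth to
within a few percent, and the curve is monotone as junctions reassemble.
"""

import argparse
from pathlib import Path

import pandas as pd

from ccpol.coloc import coloc_timecourse
from ccpol.io_core import RunConfig, write_results
from ccpol.synthetic import gen_coloc_pair


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    timepoints = [0, 1, 5, 10, 20, 30]              # min after calcium switch
    targets = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    pairs, truths = [], []
    for i, target in enumerate(targets):
        a, b, truth = gen_coloc_pair(25, 25, target, image_shape=(256, 256),
                                     seed=args.seed + i)
        pairs.append((a.astype(float) * 100.0, b.astype(float) * 100.0))
        truths.append(100.0 * truth)

    table = coloc_timecourse(pairs, timepoints, denominator="query")
    table["true_overlap_percent"] = truths
    table["abs_error_percent"] = (table.overlap_percent
                                  - table.true_overlap_percent).abs()

    write_results({"timecourse": table},
                  {"max_abs_error_percent": float(table.abs_error_percent.max()),
                   "monotone": bool(table.overlap_percent.is_monotonic_increasing)},
                  args.out, config=RunConfig(seed=args.seed), prefix="coloc")

    print(table[["time_min", "overlap_percent", "true_overlap_percent"]]
          .to_string(index=False))
    print(f"max |error|: {table.abs_error_percent.max():.2f}% ; "
          f"monotone recovery: {table.overlap_percent.is_monotonic_increasing}")


if __name__ == "__main__":
    main()
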