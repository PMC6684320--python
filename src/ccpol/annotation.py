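"""Tallies of manually annotated categorical measurements.

Junction morphology (linear / serrated / reticular perimeter shares) and
stress-fiber-junction connections are scored by hand; this module only
tabulates the annotation files - no detector is attempted, since the
underlying classification is visual.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["JUNCTION_CLASSES", "perimeter_fractions", "fiber_connection_count"]

JUNCTION_CLASSES = ("linear", "serrated", "reticular")


def perimeter_fractions(annotations: pd.DataFrame):
    """Per-cell and group-mean percent of perimeter per junction class.

    ``annotations`` columns: cell_id, junction_class, length_um, and
    optionally start_um/end_um (checked for overlapping segments).  Shares
    are length-weighted and sum to 100% of the annotated perimeter per
    cell.  Returns (per_cell, group) DataFrames.
    """
    df = annotations
    if df.empty:
        raise ValueError("at least one annotated cell required")
    bad = set(df["junction_class"]) - set(JUNCTION_CLASSES)
    if bad:
        raise ValueError(f"unknown junction classes: {sorted(bad)}")
    if {"start_um", "end_um"} <= set(df.columns):
        for cid, grp in df.groupby("cell_id"):
            seg = grp.sort_values("start_um")
            if np.any(seg["end_um"].to_numpy()[:-1] - seg["start_um"].to_numpy()[1:] > 1e-9):
                raise ValueError(f"overlapping perimeter segments for cell {cid}")
    per_cell = (df.pivot_table(index="cell_id", columns="junction_class",
                               values="length_um", aggfunc="sum", fill_value=0.0)
                  .reindex(columns=JUNCTION_CLASSES, fill_value=0.0))
    totals = per_cell.sum(axis=1)
    per_cell = per_cell.div(totals, axis=0) * 100.0
    group = pd.DataFrame({
        "mean_percent": per_cell.mean(axis=0),
        "sd_percent": per_cell.std(axis=0, ddof=1).fillna(0.0),
    })
    per_cell.columns = [f"{c}_percent" for c in per_cell.columns]
    return per_cell.reset_index(), group.reset_index(names="junction_class")


def fiber_connection_count(annotations: pd.DataFrame):
    """Stress-fiber-to-junction connection counts per image.

    ``annotations`` columns: image_id, fiber_id.  Duplicate fiber marks
    within an image are collapsed to unique fibers.  Returns (per_image,
    summary_dict).
    """
    if annotations.empty:
        per_image = pd.DataFrame({"image_id": [], "n_connections": []})
        return per_image, {"mean": 0.0, "sd": 0.0, "n_images": 0}
    per_image = (annotations.drop_duplicates(["image_id", "fiber_id"])
                 .groupby("image_id").size().rename("n_connections")
                 .reset_index())
    counts = per_image["n_connections"].to_numpy(float)
    summary = {"mean": float(counts.mean()),
               "sd": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
               "n_images": int(counts.size)}
    return per_image, summary
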