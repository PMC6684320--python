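"""Single-cell force spectroscopy: detachment work and forces.

A cell-cell adhesion measurement yields an approach and a retract
force-separation curve.  The energy needed to separate the two cells
(detachment work) is the area enclosed between the baseline-corrected
approach and retract traces; the maximum detachment force is the deepest
baseline-corrected negative excursion of the retract trace.  Events with
detachment force above 150 pN are classified as cadherin-dependent, per
the calibration against cadherin-depleted cells.

Units: separation um, force pN, work fJ (1 pN*um = 1e-3 fJ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "DetachmentResult",
    "parse_curve",
    "detachment_work",
    "max_detachment_force",
    "cadherin_fraction",
    "force_histogram",
    "PN_UM_TO_FJ",
    "CADHERIN_FORCE_THRESHOLD_PN",
]

PN_UM_TO_FJ = 1e-3                 # 1 pN * 1 um = 1e-18 J = 1e-3 fJ
CADHERIN_FORCE_THRESHOLD_PN = 150.0
BASELINE_TAIL_FRACTION = 0.10      # far-separation fraction used as baseline


@dataclass
class ForceCurve:
    """Paired approach/retract force-separation traces plus metadata."""

    approach_s: np.ndarray   # um, sorted ascending
    approach_f: np.ndarray   # pN
    retract_s: np.ndarray
    retract_f: np.ndarray
    curve_id: str | int = 0
    contact_force_pN: float | None = None
    contact_time_s: float | None = None

    def __post_init__(self):
        for name in ("approach", "retract"):
            s = np.asarray(getattr(self, f"{name}_s"), float)
            f = np.asarray(getattr(self, f"{name}_f"), float)
            if s.size != f.size or s.size < 2:
                raise ValueError(f"{name} segment needs matched arrays of length >= 2")
            if not np.all(np.isfinite(f)):
                raise ValueError(f"{name} forces must be finite")


@dataclass
class DetachmentResult:
    """Per-curve detachment work, max force and cadherin-dependence call."""

    curve_id: str | int
    work_fJ: float
    max_force_pN: float
    cadherin_dependent: bool
    no_adhesion: bool = False


def parse_curve(table: pd.DataFrame, curve_id=None) -> ForceCurve:
    """Build a ForceCurve from a long-format table.

    Expected columns: segment ('approach'/'retract'), separation_um,
    force_pN, optionally curve_id.  Rows are sorted by separation; exact
    duplicate separations are averaged with a warning.
    """
    df = table
    if curve_id is not None and "curve_id" in df.columns:
        df = df[df["curve_id"] == curve_id]
    segments = {}
    for name in ("approach", "retract"):
        seg = df[df["segment"] == name]
        if seg.empty:
            raise ValueError(f"missing {name} segment")
        seg = seg.sort_values("separation_um", kind="stable")
        s = seg["separation_um"].to_numpy(float)
        f = seg["force_pN"].to_numpy(float)
        if np.any(np.diff(s) == 0):
            warnings.warn(f"{name}: duplicate separations averaged")
            grouped = seg.groupby("separation_um", sort=True)["force_pN"].mean()
            s = grouped.index.to_numpy(float)
            f = grouped.to_numpy(float)
        segments[name] = (s, f)
    cid = curve_id if curve_id is not None else (
        df["curve_id"].iloc[0] if "curve_id" in df.columns else 0)
    return ForceCurve(approach_s=segments["approach"][0],
                      approach_f=segments["approach"][1],
                      retract_s=segments["retract"][0],
                      retract_f=segments["retract"][1],
                      curve_id=cid)


def _baseline(s: np.ndarray, f: np.ndarray) -> float:
    """Mean force over the far-separation tail (top 10% of the range)."""
    cut = s.max() - BASELINE_TAIL_FRACTION * (s.max() - s.min())
    tail = f[s >= cut]
    return float(tail.mean()) if tail.size else float(f[-1])


def detachment_work(curve: ForceCurve, mode: str = "hysteresis") -> tuple[float, bool]:
    """Detachment work in fJ and a no-adhesion flag.

    ``mode='hysteresis'`` (default) integrates the area enclosed between
    the baseline-corrected approach and retract traces over their common
    separation range (trapezoid rule); ``mode='retract_only'`` integrates
    only the negative part of the baseline-corrected retract trace.  Both
    segments are baseline-corrected independently against their
    far-separation tail.  A retract trace that never drops below baseline
    yields work 0 with the flag set.
    """
    a_s, a_f = curve.approach_s, curve.approach_f - _baseline(curve.approach_s, curve.approach_f)
    r_s, r_f = curve.retract_s, curve.retract_f - _baseline(curve.retract_s, curve.retract_f)
    lo = max(a_s.min(), r_s.min())
    hi = min(a_s.max(), r_s.max())
    if hi <= lo:
        raise ValueError("approach and retract do not share a separation range")
    sel = (r_s >= lo) & (r_s <= hi)
    s = r_s[sel]
    r = r_f[sel]
    a = np.interp(s, a_s, a_f)
    if mode == "hysteresis":
        integrand = a - r
    elif mode == "retract_only":
        integrand = np.clip(-r, 0.0, None)
    else:
        raise ValueError("mode must be 'hysteresis' or 'retract_only'")
    work_pn_um = float(np.trapezoid(integrand, s))
    no_adhesion = not np.any(r < 0)
    if no_adhesion:
        return 0.0, True
    return max(work_pn_um, 0.0) * PN_UM_TO_FJ, False


def max_detachment_force(curve: ForceCurve) -> float:
    """Magnitude (pN) of the deepest baseline-corrected retract force."""
    r = curve.retract_f - _baseline(curve.retract_s, curve.retract_f)
    return float(max(0.0, -r.min()))


def cadherin_fraction(forces_pN, threshold: float = CADHERIN_FORCE_THRESHOLD_PN) -> float:
    """Percent of detachment events with force strictly above the threshold."""
    f = np.asarray(list(forces_pN), float)
    if f.size == 0:
        raise ValueError("cadherin_fraction requires at least one event")
    return 100.0 * float(np.count_nonzero(f > threshold)) / f.size


def force_histogram(forces_pN, bin_width: float = 25.0):
    """Detachment-force histogram; returns (counts, bin_edges_pN)."""
    f = np.asarray(list(forces_pN), float)
    if f.size == 0:
        raise ValueError("no forces to histogram")
    top = np.ceil(f.max() / bin_width) * bin_width
    edges = np.arange(0.0, max(top, bin_width) + bin_width / 2, bin_width)
    counts, _ = np.histogram(f, bins=edges)
    return counts, edges


def analyze_curves(tables, mode: str = "hysteresis",
                   threshold: float = CADHERIN_FORCE_THRESHOLD_PN) -> pd.DataFrame:
    """Work/force/cadherin call for a batch of curve tables."""
    rows = []
    for t in tables:
        curve = t if isinstance(t, ForceCurve) else parse_curve(t)
        work, no_adh = detachment_work(curve, mode=mode)
        fmax = max_detachment_force(curve)
        rows.append({"curve_id": curve.curve_id, "work_fJ": work,
                     "max_force_pN": fmax,
                     "cadherin_dependent": bool(fmax > threshold),
                     "no_adhesion": no_adh})
    return pd.DataFrame(rows)
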