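"""Collective motion metrics: velocity correlation length, tracks, PIV.

The spatial autocorrelation of the x-component of the velocity field
(the direction of wound closure),

    C(r) = <u'(x) u'(x + r)> / <u'^2>,   u' = u - <u>,

is binned by inter-node distance and fitted with C(r) = exp(-r / lambda);
lambda is the correlation length, the spatial scale of coordinated motion.
Track-level metrics (speed, straightness = displacement / trajectory
length, wound closure) and a minimal block-matching PIV complete the
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "VelocityField",
    "CorrelationCurve",
    "spatial_correlation",
    "correlation_length",
    "track_metrics",
    "tracks_metrics",
    "wound_closure",
    "block_piv",
]


@dataclass
class VelocityField:
    """Regular-grid velocity field; u is the x-component (um/h)."""

    x_um: np.ndarray   # (nx,) node x coordinates
    y_um: np.ndarray   # (ny,)
    u: np.ndarray      # (ny, nx) um/h
    v: np.ndarray      # (ny, nx)
    valid: np.ndarray | None = None   # bool per node; None = all valid

    def __post_init__(self):
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if self.u.shape != (len(self.y_um), len(self.x_um)):
            raise ValueError("velocity arrays must be (ny, nx)")

    @property
    def spacing_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0])


@dataclass
class CorrelationCurve:
    """Radially binned spatial autocorrelation with optional fitted length."""

    lag_um: np.ndarray
    c: np.ndarray
    fitted_lambda_um: float | None = None

    def __post_init__(self):
        if np.any(np.diff(self.lag_um) <= 0):
            raise ValueError("lags must be increasing")


def spatial_correlation(field: VelocityField, max_lag: float | None = None,
                        component: str = "u") -> CorrelationCurve:
    """Radially binned spatial autocorrelation of one velocity component.

    Mean-subtracted, FFT-based (zero-padded, overlap-count normalized) 2D
    autocorrelation, binned by physical inter-node distance with bin width
    equal to the grid spacing.  C(0) = 1 by construction.  By default only
    the x-component is used; ``component='iso'`` averages the two
    components' correlations.
    """
    if component == "iso":
        cu = spatial_correlation(field, max_lag, "u")
        cv = spatial_correlation(field, max_lag, "v")
        return CorrelationCurve(cu.lag_um, 0.5 * (cu.c + cv.c))
    comp = {"u": field.u, "v": field.v}[component]
    if comp.size < 2:
        raise ValueError("need at least 2 grid nodes")
    w = comp - comp.mean()
    if np.allclose(w, 0.0):
        raise ValueError("zero-variance field: correlation undefined")
    ny, nx = w.shape
    py, px = 2 * ny, 2 * nx
    fw = np.fft.rfft2(w, s=(py, px))
    acorr = np.fft.irfft2(fw * np.conj(fw), s=(py, px))
    ones = np.fft.rfft2(np.ones_like(w), s=(py, px))
    counts = np.fft.irfft2(ones * np.conj(ones), s=(py, px))
    # fold shifts into signed lags
    sy = np.fft.fftfreq(py, d=1.0 / py).astype(int)
    sx = np.fft.fftfreq(px, d=1.0 / px).astype(int)
    h = field.spacing_um
    ry = np.abs(sy)[:, None] * h
    rx = np.abs(sx)[None, :] * h
    r = np.hypot(ry, rx)
    good = counts > 0.5
    cvals = np.zeros_like(acorr)
    cvals[good] = acorr[good] / counts[good]
    cvals /= cvals[0, 0]

    if max_lag is None:
        max_lag = min(ny, nx) / 2 * h
    nb = int(np.floor(max_lag / h)) + 1
    edges = (np.arange(nb + 1) - 0.5) * h
    flat_r = r[good].ravel()
    flat_c = cvals[good].ravel()
    idx = np.digitize(flat_r, edges) - 1
    sel = (idx >= 0) & (idx < nb)
    sums = np.bincount(idx[sel], weights=flat_c[sel], minlength=nb)
    ns = np.bincount(idx[sel], minlength=nb)
    lag = np.arange(nb) * h
    keep = ns > 0
    return CorrelationCurve(lag_um=lag[keep], c=sums[keep] / ns[keep])


def correlation_length(curve: CorrelationCurve, fit_range: tuple[float, float] | None = None,
                       c_floor: float = 0.05, two_param: bool = False) -> float:
    """Correlation length lambda from an exponential fit C(r) = exp(-r/lambda).

    Fit range defaults to the leading lags where C(r) > ``c_floor`` (at
    least 4 bins).  With ``two_param=True`` the model is A*exp(-r/lambda).
    A curve that never decays (all C > 0.95 in range) raises an error.
    """
    r = np.asarray(curve.lag_um, float)
    c = np.asarray(curve.c, float)
    if fit_range is not None:
        sel = (r >= fit_range[0]) & (r <= fit_range[1])
    else:
        below = np.nonzero(c <= c_floor)[0]
        stop = below[0] if below.size else r.size
        sel = np.zeros(r.size, bool)
        sel[:max(stop, 4)] = True
    r_fit, c_fit = r[sel], c[sel]
    if r_fit.size < 4:
        raise ValueError("need at least 4 lag bins in the fit range")
    if np.all(c_fit > 0.95):
        raise ValueError("correlation curve does not decay over the fit range")
    lam0 = float(r_fit[np.argmin(np.abs(c_fit - np.exp(-1.0)))]) or float(r_fit[-1])
    if two_param:
        popt, _ = curve_fit(lambda r, a, lam: a * np.exp(-r / lam),
                            r_fit, c_fit, p0=(1.0, lam0))
        lam = popt[1]
    else:
        popt, _ = curve_fit(lambda r, lam: np.exp(-r / lam),
                            r_fit, c_fit, p0=(lam0,))
        lam = popt[0]
    curve.fitted_lambda_um = float(lam)
    return float(lam)


# ---------------------------------------------------------------------------
# tracks

def track_metrics(track: pd.DataFrame) -> dict:
    """Speed, straightness, displacement and path length of one track.

    ``track`` has time-ordered columns t_h, x_um, y_um (>= 2 rows, strictly
    increasing timestamps).  straightness = displacement / path length in
    [0, 1]; velocity = path length / elapsed time (um/h).
    """
    t = track["t_h"].to_numpy(float)
    x = track["x_um"].to_numpy(float)
    y = track["y_um"].to_numpy(float)
    if t.size < 2:
        raise ValueError("a track needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    disp = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    elapsed = float(t[-1] - t[0])
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    straightness = disp / path if path > 0 else 0.0
    return {"velocity_um_h": path / elapsed, "straightness": straightness,
            "displacement_um": disp, "path_length_um": path}


def tracks_metrics(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-cell track metrics for a (cell_id, t_h, x_um, y_um) table."""
    rows = []
    for cid, grp in tracks.sort_values("t_h").groupby("cell_id"):
        m = track_metrics(grp)
        m["cell_id"] = cid
        rows.append(m)
    cols = ["cell_id", "velocity_um_h", "straightness", "displacement_um",
            "path_length_um"]
    return pd.DataFrame(rows)[cols]


def wound_closure(free_area_t0: float, free_area_t: float) -> float:
    """Percent of the initial free (wound) area closed at time t, in [0, 100]."""
    if free_area_t0 <= 0:
        raise ValueError("initial free area must be positive")
    pct = 100.0 * (1.0 - free_area_t / free_area_t0)
    if pct < 0 or pct > 100:
        warnings.warn(f"wound closure {pct:.1f}% outside [0, 100]: clipped")
    return float(np.clip(pct, 0.0, 100.0))


# ---------------------------------------------------------------------------
# minimal block-matching PIV

def block_piv(frame_a, frame_b, window: int = 64, overlap: float = 0.5,
              pixel_size_um: float = 1.0, frame_interval_h: float = 1.0,
              min_peak: float = 0.3) -> VelocityField:
    """Displacement field between two frames by windowed cross-correlation.

    Interrogation windows of ``window`` px with fractional ``overlap``;
    per-window displacement from the normalized cross-correlation peak with
    parabolic subpixel interpolation.  Featureless windows (near-zero
    variance or NCC peak below ``min_peak``) are flagged invalid (NaN).
    Velocities are px/frame converted to um/h.
    """
    from scipy.signal import fftconvolve

    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if window > min(a.shape):
        raise ValueError("window larger than the frame")
    step = max(1, int(round(window * (1.0 - overlap))))
    ys = np.arange(0, a.shape[0] - window + 1, step)
    xs = np.arange(0, a.shape[1] - window + 1, step)
    u = np.full((len(ys), len(xs)), np.nan)
    v = np.full((len(ys), len(xs)), np.nan)
    valid = np.zeros((len(ys), len(xs)), bool)
    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            wa = a[y0:y0 + window, x0:x0 + window]
            wb = b[y0:y0 + window, x0:x0 + window]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            na, nb_ = np.sqrt((wa ** 2).sum()), np.sqrt((wb ** 2).sum())
            if na < 1e-12 or nb_ < 1e-12:
                continue
            cc = fftconvolve(wb, wa[::-1, ::-1], mode="same") / (na * nb_)
            py, px = np.unravel_index(np.argmax(cc), cc.shape)
            if cc[py, px] < min_peak:
                continue
            cy = window // 2
            dy, dx = float(py - cy), float(px - cy)
            # parabolic subpixel refinement
            if 0 < py < cc.shape[0] - 1:
                c0, c1, c2 = cc[py - 1, px], cc[py, px], cc[py + 1, px]
                den = c0 - 2 * c1 + c2
                if den < 0:
                    dy += 0.5 * (c0 - c2) / den
            if 0 < px < cc.shape[1] - 1:
                c0, c1, c2 = cc[py, px - 1], cc[py, px], cc[py, px + 1]
                den = c0 - 2 * c1 + c2
                if den < 0:
                    dx += 0.5 * (c0 - c2) / den
            u[iy, ix] = dx * pixel_size_um / frame_interval_h
            v[iy, ix] = dy * pixel_size_um / frame_interval_h
            valid[iy, ix] = True
    x_nodes = (xs + window / 2) * pixel_size_um
    y_nodes = (ys + window / 2) * pixel_size_um
    return VelocityField(x_um=x_nodes, y_um=y_nodes, u=u, v=v, valid=valid)
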