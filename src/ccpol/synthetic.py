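"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one assay:

* wounded-monolayer geometry with von Mises-distributed polarity angles
  whose concentration kappa depends on distance to the free edge,
* co-localized / disjoint binary spot channels,
* donor-channel photobleach image pairs,
* peaky biosensor activation traces over a flat background,
* AFM retract curves with an adhesion well of known enclosed area,
* gridded velocity fields with a prescribed exponential spatial
  autocorrelation.

All generators are deterministic for a fixed seed and return the ground
truth alongside the data, so every downstream estimator can be tested
without external data.  They reproduce statistical structure only - no
signaling, junction mechanics or force propagation is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .polarity import CellPolarityRecord, EdgeReference, wrap_angle_deg

__all__ = [
    "MonolayerSpec",
    "ForceCurveSpec",
    "VelocityFieldSpec",
    "gen_monolayer",
    "gen_coloc_pair",
    "gen_photobleach_pair",
    "gen_activation_trace",
    "gen_force_curve",
    "gen_velocity_field",
    "merge_events",
    "kappa_step",
]


def kappa_step(breaks: Sequence[tuple[float, float]], beyond: float = 0.0):
    """Piecewise-constant kappa(distance) profile.

    ``breaks`` is a list of (upper_distance_um, kappa) pairs; a distance d
    gets the kappa of the first pair with d < upper_distance_um, and
    ``beyond`` past the last break.
    """
    ups = np.array([b[0] for b in breaks], float)
    ks = np.array([b[1] for b in breaks], float)
    if np.any(ks < 0) or beyond < 0:
        raise ValueError("kappa must be >= 0 everywhere")
    if not np.all(np.diff(ups) > 0):
        raise ValueError("break distances must be increasing")

    def profile(d):
        d = np.asarray(d, float)
        idx = np.searchsorted(ups, d, side="right")
        out = np.where(idx < len(ks), ks[np.minimum(idx, len(ks) - 1)], beyond)
        return out

    return profile


@dataclass
class MonolayerSpec:
    """Geometry and polarity statistics of a simulated wounded monolayer.

    The free edge is the line x = 0 with the wound at x < 0 (``edge_geometry
    = 'line'``) or a circular arc front.  Cells occupy a field of
    ``field_size`` = (depth, height) um behind the edge.  Each cell's
    polarity angle is drawn from a von Mises distribution centered on
    ``mean_direction`` (0 deg = toward the free edge) with concentration
    ``kappa_profile(distance_to_edge)``; kappa = 0 yields uniform angles.
    The Golgi lies exactly ``golgi_offset`` um from the nucleus along the
    sampled axis.
    """

    n_cells: int
    field_size: tuple[float, float] = (400.0, 500.0)  # (depth from edge, height) um
    edge_geometry: str = "line"
    kappa_profile: Callable | float = 0.0
    mean_direction: float = 0.0   # degrees, 0 = toward free edge
    golgi_offset: float = 8.0     # um, typical nucleus-Golgi centroid distance
    nucleus_jitter: float = 3.0   # um, positional jitter around lattice sites
    arc_radius: float = 1000.0    # um, used when edge_geometry == 'arc'
    seed: int = 0

    def kappa(self, d):
        if callable(self.kappa_profile):
            k = np.asarray(self.kappa_profile(d), float)
        else:
            k = np.full_like(np.asarray(d, float), float(self.kappa_profile))
        if np.any(k < 0):
            raise ValueError("kappa must be >= 0 everywhere")
        return k

    def validate(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.golgi_offset <= 0:
            raise ValueError("golgi_offset must be positive")
        if self.edge_geometry not in ("line", "arc"):
            raise ValueError("edge_geometry must be 'line' or 'arc'")
        self.kappa(0.0)


def _sample_von_mises(rng: np.random.Generator, mu_rad: np.ndarray,
                      kappa: np.ndarray) -> np.ndarray:
    """Von Mises draws; kappa = 0 handled exactly as a uniform draw."""
    out = np.empty_like(mu_rad)
    zero = kappa == 0
    if np.any(zero):
        out[zero] = rng.uniform(-np.pi, np.pi, size=int(zero.sum()))
    if np.any(~zero):
        out[~zero] = rng.vonmises(mu_rad[~zero], kappa[~zero])
    return out


def gen_monolayer(spec: MonolayerSpec):
    """Simulate a wounded monolayer; returns (records, edge, truth table).

    Nuclei sit on a jittered square lattice filling the field behind the
    edge.  The truth table records, per cell, the true sampled polarity
    angle, the kappa used and the distance to the edge.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    depth, height = spec.field_size

    # jittered lattice with approximately n_cells sites
    spacing = float(np.sqrt(depth * height / spec.n_cells))
    xs = np.arange(spacing / 2, depth, spacing)
    ys = np.arange(spacing / 2, height, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    if len(pos) > spec.n_cells:
        pos = pos[rng.choice(len(pos), size=spec.n_cells, replace=False)]
    elif len(pos) < spec.n_cells:
        extra = rng.uniform([0, 0], [depth, height], size=(spec.n_cells - len(pos), 2))
        pos = np.vstack([pos, extra])
    pos = pos + rng.normal(0.0, spec.nucleus_jitter, size=pos.shape)
    pos[:, 0] = np.clip(pos[:, 0], 0.0, depth)
    pos[:, 1] = np.clip(pos[:, 1], 0.0, height)

    if spec.edge_geometry == "line":
        edge = EdgeReference.vertical_line(0.0, free_side="negative_x",
                                           length=10 * height)
        dist = pos[:, 0].copy()
    else:  # arc: circle centered at (-R, height/2), front at distance R
        center = np.array([-spec.arc_radius, height / 2.0])
        theta = np.linspace(-0.4, 0.4, 65)
        arc = center + spec.arc_radius * np.column_stack([np.cos(theta), np.sin(theta)])
        edge = EdgeReference(arc, inward_side="right")
        dist = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1]) - spec.arc_radius
        dist = np.abs(dist)

    kappa = spec.kappa(dist)
    mu = np.full(len(pos), np.radians(spec.mean_direction))
    alpha = _sample_von_mises(rng, mu, kappa)  # radians, relative to edge normal

    records = []
    for i, (p, a) in enumerate(zip(pos, alpha)):
        n_hat = edge.inward_normal(p)
        # rotate the inward normal by -a in the signed-angle convention of
        # polarity_angle: v = (n rotated so that angle(v, n) = a)
        ca, sa = np.cos(a), np.sin(a)
        v = np.array([ca * n_hat[0] + sa * n_hat[1], -sa * n_hat[0] + ca * n_hat[1]])
        golgi = p + spec.golgi_offset * v
        records.append(CellPolarityRecord(
            cell_id=i, nucleus_xy=(float(p[0]), float(p[1])),
            golgi_xy=(float(golgi[0]), float(golgi[1])),
            distance_to_edge=float(dist[i]),
        ))
    truth = pd.DataFrame({
        "cell_id": np.arange(len(pos)),
        "nx_um": pos[:, 0], "ny_um": pos[:, 1],
        "alpha_true_deg": wrap_angle_deg(np.degrees(alpha)),
        "kappa": kappa,
        "distance_um": dist,
    })
    return records, edge, truth


# ---------------------------------------------------------------------------
# co-localization

def gen_coloc_pair(n_spots_a: int, n_spots_b: int, overlap_target: float,
                   image_shape=(256, 256), spot_radius: int = 3, seed: int = 0):
    """Two binary spot channels with a controlled pixel-overlap fraction.

    The overlap fraction is defined on channel A (the query):
    |A & B| / |A|.  B re-uses whole spots of A (plus a partial spot to hit
    the pixel target) and places its remaining spots disjoint from A.

    Returns (mask_a, mask_b, achieved_overlap_fraction).
    """
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]

    def disc(cy, cx):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= spot_radius ** 2

    mask_a = np.zeros(image_shape, dtype=bool)
    spots_a = []
    while len(spots_a) < n_spots_a:
        cy, cx = rng.integers(spot_radius, h - spot_radius), rng.integers(spot_radius, w - spot_radius)
        d = disc(cy, cx)
        if not (mask_a & d).any():           # keep A spots disjoint
            mask_a |= d
            spots_a.append((cy, cx))

    n_a = int(mask_a.sum())
    target_px = int(round(overlap_target * n_a))
    mask_b = np.zeros(image_shape, dtype=bool)
    copied = 0
    remaining_b = n_spots_b
    for cy, cx in spots_a:
        d = disc(cy, cx)
        sz = int(d.sum())
        if copied + sz <= target_px and remaining_b > 0:
            mask_b |= d
            copied += sz
            remaining_b -= 1
        else:
            break
    short = target_px - copied
    if short > 0 and remaining_b > 0:
        # partial copy of the next A spot: its first `short` pixels in scan order
        for cy, cx in spots_a:
            d = disc(cy, cx)
            if not (mask_b & d).any():
                idx = np.flatnonzero(d.ravel())[:short]
                part = np.zeros(h * w, dtype=bool)
                part[idx] = True
                mask_b |= part.reshape(image_shape)
                remaining_b -= 1
                break
    while remaining_b > 0:
        cy, cx = rng.integers(spot_radius, h - spot_radius), rng.integers(spot_radius, w - spot_radius)
        d = disc(cy, cx)
        if not ((mask_a | mask_b) & d).any():  # disjoint from A and existing B
            mask_b |= d
            remaining_b -= 1

    achieved = float((mask_a & mask_b).sum() / n_a)
    return mask_a, mask_b, achieved


# ---------------------------------------------------------------------------
# FRET

def gen_photobleach_pair(ef_true: float, i_post: float = 100.0,
                         noise_sd: float = 0.0, shape=(64, 64),
                         roi=None, background: float = 10.0, seed: int = 0):
    """Donor-channel pre/post acceptor-photobleach image pair.

    ROI mean intensities satisfy (Ipost - Ipre)/Ipost = ef_true before
    noise, i.e. Ipre = i_post * (1 - ef_true).  Returns (pre, post, roi).
    """
    if not 0.0 <= ef_true < 1.0:
        raise ValueError("ef_true must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if roi is None:
        roi = np.zeros(shape, dtype=bool)
        h, w = shape
        roi[h // 4: 3 * h // 4, w // 4: 3 * w // 4] = True
    pre = np.full(shape, background, dtype=float)
    post = np.full(shape, background, dtype=float)
    pre[roi] = i_post * (1.0 - ef_true)
    post[roi] = i_post
    if noise_sd > 0:
        pre += rng.normal(0.0, noise_sd, shape)
        post += rng.normal(0.0, noise_sd, shape)
    return pre, post, roi


def merge_events(frames: Sequence[int], window: int = 3) -> list[int]:
    """Merge maxima within ``window`` frames of each other into single events.

    Transitive chaining: maxima m1, m2 with |m1 - m2| <= window join one
    event, and chains extend (so {5, 7, 9} is one event at window 3).  The
    representative frame of an event is the first frame of its chain.
    Idempotent on its own output.
    """
    fr = sorted(int(f) for f in frames)
    if not fr:
        return []
    events = [fr[0]]
    last = fr[0]
    for f in fr[1:]:
        if f - last > window:
            events.append(f)
        last = f
    return events


@dataclass
class ActivationTrace:
    """Intensity-vs-time trace of one region with its background trace."""

    time: np.ndarray          # frame indices (uniform spacing)
    intensity: np.ndarray     # a.u. per frame
    background: np.ndarray    # matched trace from a no-activation region
    region_kind: str = "junction"   # 'junction' | 'free-edge'
    region_id: str | int = 0
    frame_interval_s: float = 1.0

    def __post_init__(self):
        if len(self.intensity) != len(self.background):
            raise ValueError("intensity and background traces must have equal length")


def gen_activation_trace(peak_frames: Sequence[int], peak_height: float = 5.0,
                         background_level: float = 100.0, n_frames: int = 150,
                         noise_sd: float = 1.0, decay_frames: float = 4.0,
                         region_kind: str = "junction", region_id=0,
                         seed: int = 0):
    """Biosensor trace with step-up/exponential-decay activation peaks.

    Each peak is an instantaneous rise of ``peak_height`` at its frame
    followed by exponential decay with time constant ``decay_frames``.  The
    ground-truth event count applies the 3-frame transitive merge rule to
    ``peak_frames``.  Returns (ActivationTrace, true_event_count).
    """
    peak_frames = sorted(int(f) for f in peak_frames)
    if any(f < 0 or f >= n_frames for f in peak_frames):
        raise ValueError("peak frames must lie within [0, n_frames)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    x = np.full(n_frames, background_level, dtype=float)
    for f in peak_frames:
        tail = t[f:] - f
        x[f:] += peak_height * np.exp(-tail / decay_frames)
    bg = np.full(n_frames, background_level, dtype=float)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n_frames)
        bg += rng.normal(0.0, noise_sd, n_frames)
    trace = ActivationTrace(time=t, intensity=x, background=bg,
                            region_kind=region_kind, region_id=region_id)
    truth = len(merge_events(peak_frames, window=3))
    return trace, truth


# ---------------------------------------------------------------------------
# AFM

@dataclass
class ForceCurveSpec:
    """Shape parameters of a synthetic cell-cell detachment force curve.

    Defaults mirror the acquisition conditions of the assay being emulated:
    300 pN applied contact force and 5 s cell-cell contact time.
    """

    contact_force: float = 300.0   # pN
    contact_time: float = 5.0      # s
    adhesion_depth: float = 100.0  # pN, depth of the retract adhesion well
    adhesion_width: float = 2.0    # um, base width of the well
    well_start: float = 1.0        # um, separation where the well begins
    baseline_noise_sd: float = 0.0  # pN
    max_separation: float = 10.0   # um
    n_samples: int = 2001
    seed: int = 0

    def validate(self):
        if self.adhesion_depth < 0 or self.adhesion_width <= 0:
            raise ValueError("adhesion depth must be >= 0 and width > 0")
        if self.well_start + self.adhesion_width >= self.max_separation:
            raise ValueError("adhesion well must fit inside the separation range")


def gen_force_curve(spec: ForceCurveSpec):
    """Approach/retract force-separation curve pair with analytic ground truth.

    The approach is flat at baseline except for a linear contact ramp up to
    ``contact_force`` at zero separation.  The retract repeats the ramp and
    adds a triangular adhesion well of depth ``adhesion_depth`` (negative
    force) and base ``adhesion_width``.  Ground truth: enclosed area
    (detachment work) = 1/2 * depth * width in pN*um, converted to fJ
    (1 pN*um = 1e-3 fJ); maximum detachment force = depth in pN.

    Returns (curve_table, true_work_fJ, true_max_force_pN) where the table
    has columns curve_id, segment, separation_um, force_pN.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = np.linspace(0.0, spec.max_separation, spec.n_samples)
    contact_ramp = np.where(s < 0.5, spec.contact_force * (1.0 - s / 0.5), 0.0)

    approach = contact_ramp.copy()
    half = spec.adhesion_width / 2.0
    apex = spec.well_start + half
    well = np.where(
        (s >= spec.well_start) & (s <= spec.well_start + spec.adhesion_width),
        -spec.adhesion_depth * (1.0 - np.abs(s - apex) / half), 0.0)
    retract = contact_ramp + well

    if spec.baseline_noise_sd > 0:
        approach = approach + rng.normal(0.0, spec.baseline_noise_sd, s.size)
        retract = retract + rng.normal(0.0, spec.baseline_noise_sd, s.size)

    true_work_fj = 0.5 * spec.adhesion_depth * spec.adhesion_width * 1e-3
    true_max_force = float(spec.adhesion_depth)
    table = pd.DataFrame({
        "curve_id": 0,
        "segment": np.repeat(["approach", "retract"], s.size),
        "separation_um": np.concatenate([s, s]),
        "force_pN": np.concatenate([approach, retract]),
    })
    return table, float(true_work_fj), true_max_force


# ---------------------------------------------------------------------------
# velocity fields

@dataclass
class VelocityFieldSpec:
    """Gridded velocity field with exponential spatial autocorrelation.

    The x-component (and, independently, the y-component) is a Gaussian
    random field whose target autocorrelation is exp(-r / correlation_length).
    """

    grid_shape: tuple[int, int] = (128, 128)
    grid_spacing: float = 10.0        # um
    correlation_length: float = 100.0  # um
    rms_speed: float = 10.0           # um/h
    seed: int = 0

    def validate(self):
        if self.correlation_length <= self.grid_spacing:
            raise ValueError("correlation_length must exceed grid_spacing")
        if min(self.grid_shape) < 2:
            raise ValueError("grid must have at least 2 nodes per axis")


def _correlated_field(rng, shape, spacing, lam):
    """Spectral synthesis of a periodic Gaussian field with C(r)=exp(-r/lam)."""
    ny, nx = shape
    ky = np.minimum(np.arange(ny), ny - np.arange(ny)) * spacing
    kx = np.minimum(np.arange(nx), nx - np.arange(nx)) * spacing
    r = np.hypot(ky[:, None], kx[None, :])
    cov = np.exp(-r / lam)
    spec = np.fft.fft2(cov).real
    spec = np.clip(spec, 0.0, None)
    white = rng.standard_normal(shape)
    f = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(spec)).real
    f /= f.std()
    return f


def gen_velocity_field(spec: VelocityFieldSpec):
    """Synthesize a velocity field; returns (x_um, y_um, u, v).

    u and v are independent correlated fields scaled so the per-component
    RMS equals ``rms_speed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    u = _correlated_field(rng, spec.grid_shape, spec.grid_spacing,
                          spec.correlation_length) * spec.rms_speed
    v = _correlated_field(rng, spec.grid_shape, spec.grid_spacing,
                          spec.correlation_length) * spec.rms_speed
    ny, nx = spec.grid_shape
    x = np.arange(nx) * spec.grid_spacing
    y = np.arange(ny) * spec.grid_spacing
    return x, y, u, v
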