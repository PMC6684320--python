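"""Golgi-nucleus axial polarity of endothelial monolayers.

A cell's front-rear polarity axis is the vector from the nucleus centroid to
the Golgi centroid.  Relative to a free-edge reference (scratch wound or
sprouting front) each cell gets a polarity angle ``alpha``; the polarity
index (PI) of a population is the length of the mean resultant vector of
those angles,

    PI = sqrt[ (1/N sum cos a)^2 + (1/N sum sin a)^2 ],

which is 1 for perfectly aligned cells and tends to 0 for uniformly random
orientations.  The module also provides the spatial PI profile (50 um bins
from the edge), leader/follower row classification, and the derivation of
the uncoordination threshold (mean + 1 SD of per-bin PIs of a junction-
disrupted control, first row excluded).

Angle convention: degrees in I/O, interval (-180, 180], 0 deg = pointing
toward the free space (into the wound / ahead of the front).  Coordinates
are image-frame micrometers (origin top-left, y down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "CellPolarityRecord",
    "EdgeReference",
    "PolarityIndexResult",
    "PolarityProfile",
    "segment_centroids",
    "assign_golgi",
    "polarity_angle",
    "polarity_index",
    "bin_pi_by_distance",
    "classify_rows",
    "derive_threshold",
    "angular_histogram",
    "rayleigh_test",
    "wrap_angle_deg",
]


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)
    return wrapped


@dataclass
class CellPolarityRecord:
    """One cell: centroids, polarity angle and position relative to the edge.

    ``alpha`` is None when the Golgi assignment left the cell unmatched or
    the polarity vector has zero length (flagged, not silently dropped).
    """

    cell_id: int | str
    nucleus_xy: tuple[float, float]
    golgi_xy: tuple[float, float] | None = None
    alpha: float | None = None            # degrees in (-180, 180]
    distance_to_edge: float | None = None  # um, >= 0
    row_index: int | None = None          # 1 = leader row

    @property
    def polarity_vector(self) -> np.ndarray | None:
        if self.golgi_xy is None:
            return None
        return np.asarray(self.golgi_xy, float) - np.asarray(self.nucleus_xy, float)


class EdgeReference:
    """Oriented polyline marking the free edge (wound margin / sprouting front).

    Parameters
    ----------
    polyline
        (N, 2) array of um coordinates, N >= 2, consecutive vertices distinct.
    inward_side
        'left' or 'right': on which side of the oriented polyline the free
        space lies.  With image-frame coordinates (y down) and a polyline
        running with direction d, 'left' means the side of d rotated by
        +90 degrees in array coordinates, i.e. (-dy, dx).
    """

    def __init__(self, polyline: np.ndarray, inward_side: str = "left"):
        pl = np.asarray(polyline, dtype=float)
        if pl.ndim != 2 or pl.shape[1] != 2 or pl.shape[0] < 2:
            raise ValueError("polyline must be an (N>=2, 2) array")
        seg = np.diff(pl, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError("polyline has repeated consecutive vertices")
        if inward_side not in ("left", "right"):
            raise ValueError("inward_side must be 'left' or 'right'")
        self.polyline = pl
        self.inward_side = inward_side

    @classmethod
    def vertical_line(cls, x: float = 0.0, free_side: str = "negative_x",
                      length: float = 1e4) -> "EdgeReference":
        """Straight vertical edge at ``x``; free space at x < x (default)."""
        pl = np.array([[x, -length], [x, length]])
        # direction (0, 1); left normal = (-1, 0) -> negative-x side
        side = "left" if free_side == "negative_x" else "right"
        return cls(pl, inward_side=side)

    def _nearest_segment(self, point: np.ndarray) -> tuple[int, float, np.ndarray]:
        """Return (segment index, distance, foot point) of the nearest segment."""
        p = np.asarray(point, float)
        a = self.polyline[:-1]
        b = self.polyline[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        foot = a + t[:, None] * ab
        d = np.hypot(*(p - foot).T)
        k = int(np.argmin(d))
        return k, float(d[k]), foot[k]

    def distance(self, point) -> float:
        """Euclidean distance from ``point`` to the nearest polyline segment."""
        return self._nearest_segment(np.asarray(point, float))[1]

    def inward_normal(self, point) -> np.ndarray:
        """Unit normal of the nearest segment pointing into the free space."""
        k, _, _ = self._nearest_segment(np.asarray(point, float))
        d = self.polyline[k + 1] - self.polyline[k]
        d = d / np.hypot(*d)
        n = np.array([-d[1], d[0]])  # left of direction
        if self.inward_side == "right":
            n = -n
        return n


@dataclass
class PolarityIndexResult:
    """Polarity index (mean resultant length), mean angle and sample size."""

    pi: float
    mean_angle: float  # degrees in (-180, 180]
    n: int


@dataclass
class PolarityProfile:
    """Per-distance-bin polarity index; bins [k*w, (k+1)*w) from the edge."""

    bin_edges: np.ndarray                 # length n_bins + 1, um
    results: list[PolarityIndexResult | None]  # None for empty bins

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def bin_pis(self, skip_empty: bool = True) -> list[float]:
        return [r.pi for r in self.results if r is not None or not skip_empty]


# ---------------------------------------------------------------------------
# image -> centroids

def segment_centroids(image, pixel_size_um: float, min_area: int = 20,
                      threshold_method: str = "otsu"):
    """Segment one organelle channel and return centroids in micrometers.

    The channel (nucleus or Golgi staining) is thresholded, connected
    components are labeled, components smaller than ``min_area`` pixels are
    dropped, and centroids are returned as (x, y) um in label-scan order.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size (um/px) must be known and positive")

    if threshold_method == "otsu":
        if img.max() == img.min():
            warnings.warn("constant image: empty segmentation")
            return []
        mask = img > threshold_otsu(img)
    elif threshold_method == "nonzero":
        mask = img > 0
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    labels = label(mask)
    centroids = []
    for prop in regionprops(labels):
        if prop.area >= min_area:
            r, c = prop.centroid
            centroids.append((c * pixel_size_um, r * pixel_size_um))
    if not centroids:
        warnings.warn("empty segmentation result")
    return centroids


def assign_golgi(nuclei: Sequence, golgi: Sequence, max_distance: float = 30.0):
    """Globally optimal one-to-one nucleus-Golgi pairing.

    Minimizes the total Euclidean distance over all one-to-one assignments
    (Hungarian algorithm; rectangular instances allowed).  Pairs farther
    apart than ``max_distance`` um are dissolved into the unmatched sets.

    Returns
    -------
    pairs : list of (nucleus_index, golgi_index)
    unmatched_nuclei, unmatched_golgi : sorted index lists
    """
    if len(nuclei) == 0 or len(golgi) == 0:
        raise ValueError("both centroid lists must be non-empty")
    nuc = np.asarray(nuclei, float)
    gol = np.asarray(golgi, float)
    dist = cdist(nuc, gol)
    rows, cols = linear_sum_assignment(dist)
    order = np.lexsort((cols, rows))  # deterministic tie-break
    pairs = []
    un_n = set(range(len(nuc)))
    un_g = set(range(len(gol)))
    for i, j in zip(rows[order], cols[order]):
        if dist[i, j] <= max_distance:
            pairs.append((int(i), int(j)))
            un_n.discard(int(i))
            un_g.discard(int(j))
    return pairs, sorted(un_n), sorted(un_g)


def polarity_angle(nucleus_xy, golgi_xy, edge: EdgeReference) -> float:
    """Signed angle (degrees) between the polarity vector and the edge normal.

    0 deg = the nucleus-to-Golgi vector points straight into the free space;
    +/-90 deg = parallel to the edge; 180 deg = away from the free space.

    Raises ``ValueError`` on a zero-length polarity vector (callers should
    flag such records instead of assigning an angle).
    """
    v = np.asarray(golgi_xy, float) - np.asarray(nucleus_xy, float)
    if np.hypot(*v) == 0.0:
        raise ValueError("zero-length polarity vector")
    n = edge.inward_normal(nucleus_xy)
    ang = np.degrees(np.arctan2(v[0] * n[1] - v[1] * n[0], v[0] * n[0] + v[1] * n[1]))
    return float(wrap_angle_deg(ang))


# ---------------------------------------------------------------------------
# circular statistics

def polarity_index(angles_deg: Iterable[float]) -> PolarityIndexResult:
    """Polarity index: length of the mean resultant vector of the angles.

    PI = sqrt[(mean cos a)^2 + (mean sin a)^2], in [0, 1]; the mean angle is
    the direction of the resultant.
    """
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        raise ValueError("polarity_index requires at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    if np.all(a == a[0]):
        # degenerate fully-aligned case: exactly 1 by definition
        return PolarityIndexResult(pi=1.0,
                                   mean_angle=float(wrap_angle_deg(np.degrees(a[0]))),
                                   n=a.size)
    c = np.cos(a).mean()
    s = np.sin(a).mean()
    pi = float(np.hypot(c, s))
    mean_angle = float(wrap_angle_deg(np.degrees(np.arctan2(s, c))))
    return PolarityIndexResult(pi=min(pi, 1.0), mean_angle=mean_angle, n=a.size)


def bin_pi_by_distance(records: Sequence[CellPolarityRecord],
                       edge: EdgeReference | None = None,
                       bin_width: float = 50.0,
                       max_distance: float | None = None) -> PolarityProfile:
    """Polarity index per 50 um slice of distance from the free edge.

    Cells fall in half-open bins [k*w, (k+1)*w) starting at the edge; a bin
    without cells carries no PI (None).  Records missing ``distance_to_edge``
    are filled from ``edge`` when given; records with no angle are skipped.
    As in a histogram, the right edge of the final bin is inclusive; cells
    beyond ``max_distance`` are excluded.
    """
    dist, angs = [], []
    for r in records:
        if r.alpha is None:
            continue
        d = r.distance_to_edge
        if d is None:
            if edge is None:
                raise ValueError("record lacks distance_to_edge and no edge given")
            d = edge.distance(r.nucleus_xy)
        dist.append(d)
        angs.append(r.alpha)
    dist = np.asarray(dist, float)
    angs = np.asarray(angs, float)
    if max_distance is None:
        max_distance = dist.max() if dist.size else bin_width
    n_bins = max(1, int(np.ceil(max_distance / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    idx = np.floor(dist / bin_width).astype(int)
    on_outer_edge = dist == edges[-1]
    idx[on_outer_edge] = n_bins - 1
    results: list[PolarityIndexResult | None] = []
    for k in range(n_bins):
        sel = angs[idx == k]
        results.append(polarity_index(sel) if sel.size else None)
    return PolarityProfile(bin_edges=edges, results=results)


def derive_threshold(profiles: Sequence[PolarityProfile],
                     exclude_first_bin: bool = True,
                     n_sd: float = 1.0,
                     per_image: bool = False) -> float:
    """Uncoordination threshold from junction-disrupted control profiles.

    Pools the per-bin PIs of all profiles (by default excluding the first
    bin, the leader row, which is biased toward the wound by the monolayer
    asymmetry) and returns mean + ``n_sd`` * sample SD.  With
    ``per_image=True`` the mean/SD are taken over per-image means instead of
    the pooled bins.
    """
    groups = []
    for prof in profiles:
        start = 1 if exclude_first_bin else 0
        vals = [r.pi for r in prof.results[start:] if r is not None]
        if vals:
            groups.append(vals)
    pooled = [v for g in groups for v in g]
    values = [float(np.mean(g)) for g in groups] if per_image else pooled
    if len(values) < 2:
        raise ValueError("need at least 2 contributing bins to derive a threshold")
    return float(np.mean(values) + n_sd * np.std(values, ddof=1))


def angular_histogram(angles_deg: Iterable[float], n_bins: int = 24):
    """Counts of angles over equal circular bins covering 360 degrees.

    Bin edges run from -180 to 180; angles are wrapped to (-180, 180] first,
    so -179 deg and 179 deg land in circularly adjacent bins.  Returns
    (counts, bin_centers_deg).
    """
    a = wrap_angle_deg(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        raise ValueError("angular_histogram requires at least one angle")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # 180 deg belongs to the last bin (np.histogram includes the right edge
    # of the final bin already)
    counts, _ = np.histogram(a, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def rayleigh_test(angles_deg: Iterable[float]) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Z = n * PI^2; the p-value uses the standard approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n*PI,
    accurate for small and large n alike.

    Returns (Z, p).  Requires n >= 5.
    """
    a = list(angles_deg)
    n = len(a)
    if n < 5:
        raise ValueError("rayleigh_test requires n >= 5")
    pi = polarity_index(a).pi
    r_big = n * pi
    z = n * pi ** 2
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - r_big ** 2)) - (1.0 + 2.0 * n)))
    return float(z), min(p, 1.0)


# ---------------------------------------------------------------------------
# leader/follower row classification

def classify_rows(records: Sequence[CellPolarityRecord], edge: EdgeReference,
                  max_rows: int | None = None,
                  envelope_pad: float | None = None) -> list[int]:
    """Assign each cell a row index by peeling from the free edge.

    Row 1 (leaders) = cells whose Voronoi neighborhood region touches the
    free edge; row k = cells Voronoi-adjacent to row k-1 after peeling.
    Returns the row index per record (also written onto the records).
    Disconnected components that never become adjacent to a peeled row are
    assigned rows by their own peeling, with a warning.
    """
    import shapely
    from shapely.geometry import LineString, MultiPoint, Point

    pts = np.asarray([r.nucleus_xy for r in records], float)
    n = len(pts)
    if n == 0:
        raise ValueError("no cells to classify")
    if n == 1:
        records[0].row_index = 1
        return [1]

    if envelope_pad is None:
        # pad so first-row regions can reach past the edge
        span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
        envelope_pad = max(0.5 * span, float(np.max([edge.distance(p) for p in pts[:5]])))
    mp = MultiPoint([Point(p) for p in pts])
    env = shapely.box(pts[:, 0].min() - envelope_pad, pts[:, 1].min() - envelope_pad,
                      pts[:, 0].max() + envelope_pad, pts[:, 1].max() + envelope_pad)
    env = env.union(LineString(edge.polyline).buffer(envelope_pad))
    cells_geo = shapely.voronoi_polygons(mp, extend_to=env)
    # map polygons back to generating points
    polys = [None] * n
    for geom in cells_geo.geoms:
        # nearest generating point of a representative interior point
        rp = geom.representative_point()
        k = int(np.argmin(np.hypot(pts[:, 0] - rp.x, pts[:, 1] - rp.y)))
        polys[k] = geom.intersection(env)
    missing = [k for k, p in enumerate(polys) if p is None]
    if missing:  # duplicated points collapse Voronoi cells; share the region
        for k in missing:
            j = int(np.argmin([np.inf if j == k or polys[j] is None else
                               np.hypot(*(pts[k] - pts[j])) for j in range(n)]))
            polys[k] = polys[j]

    edge_line = LineString(edge.polyline)
    touches_edge = np.array([p.intersects(edge_line) for p in polys])

    # adjacency: Voronoi cells sharing a boundary of positive length
    adj: list[set[int]] = [set() for _ in range(n)]
    tree = shapely.STRtree(polys)
    for i in range(n):
        for j in tree.query(polys[i]):
            j = int(j)
            if j <= i:
                continue
            inter = polys[i].intersection(polys[j])
            if inter.length > 1e-9:
                adj[i].add(j)
                adj[j].add(i)

    rows = np.zeros(n, dtype=int)
    current = set(np.nonzero(touches_edge)[0])
    if not current:  # no region reaches the edge: nearest cells are leaders
        d = np.array([edge.distance(p) for p in pts])
        current = set(np.nonzero(d == d.min())[0])
    k = 1
    while current:
        for i in current:
            rows[i] = k
        nxt = set()
        for i in current:
            nxt |= {j for j in adj[i] if rows[j] == 0}
        current = nxt
        k += 1
        if max_rows is not None and k > max_rows:
            break
    if np.any(rows == 0):
        warnings.warn("disconnected cells: assigning rows per component by edge distance")
        left = np.nonzero(rows == 0)[0]
        d = np.array([edge.distance(pts[i]) for i in left])
        seed = {int(left[np.argmin(d)])}
        while np.any(rows == 0) and seed:
            base = k
            current = seed
            kk = 1
            while current:
                for i in current:
                    rows[i] = kk  # rows within the stray component restart at 1
                nxt = set()
                for i in current:
                    nxt |= {j for j in adj[i] if rows[j] == 0}
                current = nxt
                kk += 1
            left = np.nonzero(rows == 0)[0]
            if left.size:
                d = np.array([edge.distance(pts[i]) for i in left])
                seed = {int(left[np.argmin(d)])}
            else:
                seed = set()
    for r, row in zip(records, rows):
        r.row_index = int(row)
    return [int(r) for r in rows]


def select_followers(records: Sequence[CellPolarityRecord],
                     rows: range = range(2, 6)) -> list[CellPolarityRecord]:
    """Follower subset by row index (default rows 2-5; rows 2-4 optional)."""
    return [r for r in records if r.row_index in rows]
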