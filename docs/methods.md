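# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `ccpol`. It is the package's own account of its science;
every number quoted here is computed by the test suite or the analysis
scripts.

## Coordinates, angles, units

Coordinates are image-frame micrometers: origin top-left, y increasing
downward. Angles are degrees in I/O on the interval (−180, 180] and radians
internally. The polarity angle α of a cell is the signed angle between its
nucleus→Golgi vector and the inward normal of the nearest free-edge
segment, so α = 0° means "pointing into the free space" (into the wound, or
ahead of the sprouting front). Physical columns always carry units in their
names (`distance_um`, `force_pN`, `work_fJ`); 1 pN·µm = 10⁻³ fJ.

## Polarity index

For angles α₁…α_N the polarity index is the mean resultant length
PI = |mean of unit vectors| = √[(Σcos α/N)² + (Σsin α/N)²] ∈ [0, 1]; the
mean angle is the direction of the resultant. PI is invariant to rotation
of all angles, to sample ordering and to duplication of the whole sample.
The degenerate all-identical case is special-cased to return exactly 1, so
the "PI = 1 iff all angles equal" invariant holds in floating point. For a
von Mises population with concentration κ the expected PI is the mean
resultant length of that distribution; tests verify the sampled PI against
a direct numerical-integration oracle (no Bessel-function shortcut) to
0.01 at n = 5×10⁴ for κ ∈ {0.5, 1, 2, 4}. For uniform angles the sampling
magnitude of PI is ≈ √π/(2√n) (~0.003 at n = 10⁵).

The Rayleigh uniformity test uses Z = n·PI² with the standard closed-form
p-value approximation p = exp(√(1+4n+4(n²−R²)) − (1+2n)), R = n·PI;
it is cross-checked against an independent implementation (pingouin) in
the tests.

## Edge geometry, binning, rows

The free edge is an oriented polyline with a declared free side; distance
to edge is Euclidean point-to-segment distance, and the same code path
serves straight scratch wounds and curved sprouting fronts. The PI profile
uses contiguous half-open bins [k·50, (k+1)·50) µm starting at the edge;
the outer boundary of the last bin is inclusive (histogram convention) so
a cell clipped exactly to the field depth does not spawn a spurious
single-cell bin. Empty bins carry no PI.

Leader/follower classification peels rows from the edge: row 1 contains
cells whose Voronoi neighborhood region (clipped to a padded envelope)
intersects the edge polyline; row k+1 contains cells Voronoi-adjacent to
row k. Adjacency is shared-boundary of Voronoi cells, which handles
degenerate (collinear) configurations that defeat a Delaunay construction.
Followers default to rows 2–5, with rows 2–4 available as an option, since
both definitions are in circulation for this assay; disconnected cell
clouds are peeled per component with a warning.

## Nucleus–Golgi assignment

Pairing minimizes the total Euclidean distance over all one-to-one
assignments (Hungarian algorithm, rectangular instances allowed), not
greedy nearest-neighbor — greedy is provably suboptimal on crossing
configurations, and tests verify optimality against exhaustive search for
n ≤ 7. Pairs farther than `max_distance` (default 30 µm, roughly three
cell radii) are dissolved post-hoc into the unmatched sets; the default
guards against pathological long-range matches when one channel
under-segments.

## Uncoordination threshold

The wound–monolayer interface biases polarity even in junction-disrupted
cells, so "uncoordinated" is calibrated empirically: pool the per-bin PIs
of the disrupted condition across images, exclude the first bin (leader
row, strongly edge-biased), and set the threshold at mean + 1 sample SD.
Pooling bins across images (rather than averaging per image first) is the
default; per-image mode is a flag. The rule is translation-covariant, and
on the published control summary (pooled bins with mean 0.10, SD 0.04) it
reproduces the 0.14 threshold.

When profiles are compared against the threshold, the per-condition
profile merges cells across images per bin, which is how the global
profiles of this assay are reported; per-image bins (smaller n, higher
uniform-PI floor) are what the threshold is derived from.

## Co-localization

Object-based only: each channel is thresholded (Otsu by default; adaptive
and manual available), objects below 9 px removed, and co-localization is
100·|A∩B|/|D| with denominator D = query mask (default), reference mask,
or union. The query default reflects directional reporting ("X/Y" = share
of X at Y); the union mode is the symmetric option. PLA quantification is
the same operation with the PLA-dot mask as query and the junction mask as
reference. Time courses apply one segmentation setting across the series;
missing timepoints are flagged, never interpolated.

## FRET

Acceptor photobleaching: EF = (Ī_post − Ī_pre)/Ī_post over ROI means of
the donor channel, after a Gaussian prefilter of σ = 0.75 px on both
images. EF is scale-invariant; negative EF (donor loss) is returned but
flagged. Note the prefilter mixes ROI-boundary pixels with background, so
on synthetic hard-edged ROIs the recovered EF differs from the nominal
value by ~0.002; tests therefore check identities on uniform images
exactly and generator recovery to 0.01.

Biosensor peaks: the trace is differentiated (first difference); candidate
events are local maxima of the differential with positive rise. A
candidate becomes an event when the 3-frame moving-average intensity
exceeds the background trace's moving-average mean + 4 SD, with two
refinements chosen by an explicit false-positive budget:

* **hysteresis** — after a detection, no new threshold crossing counts
  until the smoothed trace has fallen back below mean + 1 SD, so noise
  hovering on an activation's decay tail cannot re-trigger;
* **significant-rise override** — a candidate whose differential exceeds
  the background differential's mean + 3 SD is accepted regardless of
  state, so activations stacked on a decaying predecessor are still
  counted.

With a plain 2σ intensity gate a 150-frame trace accrues ≈0.5 false events
(per-frame α ≈ 2.3% times the density of differential maxima), which
swamps per-region counts of order 1–3; the chosen cutoffs bring expected
false events per trace below 0.01. Monte Carlo at SNR 5 (3000 traces,
3 events each): 97.2% exact counts, ~2.7% off by one, ~0.1% off by two.
All cutoffs are keyword-configurable. Retained maxima within 3 frames of
each other merge into one event by transitive chaining ({5,7,9} is one
event) — the only order-independent closure of the pairwise rule — and the
generator's ground truth applies the identical rule. Counting is invariant
to adding a constant to trace and background, and merging is idempotent.
An optional mono-exponential detrend (off by default) handles
photobleaching drift in time-lapse traces.

## AFM detachment

Curves are long-format CSV (curve_id, segment, separation_um, force_pN);
segments are sorted by separation and each is baseline-corrected by the
mean force over its far-separation 10%. Detachment work integrates the
area enclosed between the corrected approach and retract traces over
their common separation range (trapezoid rule), default "hysteresis"
mode; a retract-only mode (negative excursion area) is a flag, since the
enclosed-area diagram admits both readings. A retract trace never dropping
below baseline yields work 0 with a flag. Work is invariant to a constant
offset of both segments, additive over multiple wells, and stable to <1%
under halved sampling on smooth wells. Maximum detachment force is the
magnitude of the deepest corrected retract force. The cadherin-dependent
fraction counts events with force **strictly** above 150 pN (literal
"above"), a threshold calibrated against cadherin-depleted controls;
force histograms default to 25 pN bins. Synthetic curves default to
300 pN contact force and 5 s contact time, the acquisition settings of
the emulated assay, with a triangular adhesion well whose analytic area
(½·depth·width) is the recorded truth.

## Velocity correlation

C(r) = ⟨u′(x)u′(x+r)⟩/⟨u′²⟩ on the mean-subtracted x-component (the
wound-closure direction; an isotropic mode averaging both components is
off by default), computed by zero-padded FFT autocorrelation with
overlap-count normalization and binned radially at the grid spacing, so
C(0) = 1 exactly. The correlation length λ comes from a least-squares fit
of C(r) = exp(−r/λ) over the leading lags with C > 0.05 (≥4 bins);
amplitude is fixed at 1 by normalization, with a two-parameter A·exp(−r/λ)
variant behind a flag. The fit is exact (10⁻⁶) on noiseless exponential
samples and recovers a synthesized λ = 100 µm on a single 256×256 field to
within ~10% — the residual spread is the realization noise of a field
containing ~26 correlation lengths per axis, not fit error.

The synthetic field uses circulant-embedding spectral synthesis: the
target covariance exp(−r/λ) on the periodic grid is transformed, clipped
at zero, and used to color white noise, giving the prescribed correlation
in expectation.

Block PIV is a minimal faithful stand-in for full deformation PIV:
64×64 px interrogation windows at 50% overlap, normalized cross-
correlation peak with parabolic subpixel interpolation, nodes flagged
invalid on near-zero variance or peak below 0.3. Parabolic interpolation
carries an O(0.1 px) texture-dependent bias, so "exact" recovery of
integer shifts means exact after rounding, with subpixel residual < 0.5 px.

## Tracks and wound closure

straightness = displacement/path length ∈ [0, 1]; velocity = path
length/elapsed time; wound closure = 100·(1 − A_t/A_0), clipped to
[0, 100] with a warning if exceeded. Zero elapsed time and non-increasing
timestamps are errors.

## Synthetic monolayer

Nuclei sit on a jittered square lattice (jitter 3 µm) behind a straight or
arc edge; each cell's angle is von Mises with concentration κ(distance)
and the Golgi is placed exactly `golgi_offset` (default 8 µm, a typical
nucleus–Golgi centroid distance) along the sampled axis, so the sampled
angle is recoverable exactly from the centroids. κ = 0 is handled as an
exact uniform draw. The default two-condition experiment uses 9
coordinated images (κ = 2.5 within 300 µm of the edge — per-bin PI ≈ 0.74,
matching strongly coordinated monolayers — and 0 beyond) and 4
uncoordinated images (κ = 1.5 within the first 50 µm only, emulating the
first-row geometric bias; its magnitude is a free parameter, as the bias
has no published quantification), 400 cells per 400×500 µm field — image
counts and cell densities at the scale of the emulated experiments.

What the generator does **not** emulate: segmentation errors, uneven
staining, cell shape, curved wound edges with overhangs, temporal
dynamics of polarity, or spatially correlated angle noise between
neighboring cells. Passing tests therefore demonstrate correctness of the
estimators on data with the declared statistical structure, not robustness
to imaging artifacts; the image-processing entry points
(`segment_centroids`, `segment_mask`) accept externally segmented inputs
as the escape hatch for real data.

## Interfaces

The library functions and the numbered `analysis/` drivers are the
package's interface; outputs are CSV tables plus a JSON summary embedding
the exact configuration and package version, so any run is reproducible
from its snapshot and seed. TIFF is read via tifffile with pixel size
taken from metadata or an explicit override (an error names the config
key when neither is present).

## Known limitations

* Row peeling assumes a roughly confluent monolayer; sparse clouds get
  per-component rows with a warning.
* The biosensor detector's thresholds are calibrated for flat-background
  traces; strongly drifting backgrounds need the detrend flag.
* `correlation_length` on small fields (few correlation lengths per axis)
  inherits realization noise of order 10%; averaging curves over replicate
  fields before fitting is the recommended remedy and is supported by
  fitting a user-averaged curve.
* The AFM baseline (far-separation 10%) assumes the curve reaches a
  force-free plateau; curves truncated mid-well will bias the work.
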