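# ccpol

Quantitative analyses of **endothelial collective cell behavior**: a tested,
reusable implementation of the measurements used to characterize coordinated
migration in wounded endothelial monolayers and sprouting vessels —

* **axial polarity**: per-cell nucleus→Golgi polarity vectors, the polarity
  index (PI) of a population, its distance-from-edge profile, leader/follower
  row classification, and the derivation of an uncoordination threshold;
* **object-based co-localization** of two junction channels (also used for
  PLA dots and calcium-switch time courses);
* **FRET**: acceptor-photobleaching efficiency and ratiometric biosensor
  activation-peak counting;
* **AFM single-cell force spectroscopy**: cell–cell detachment work, maximum
  detachment force, force histograms and the cadherin-dependent fraction;
* **collective motion**: velocity-field spatial correlation and correlation
  length, track metrics (speed, straightness), wound closure, and a minimal
  block-matching PIV.

Every stage is exercisable without external data through a bundled
synthetic-data generator (`ccpol.synthetic`) that produces inputs with known
ground truth.

## The core statistic

Each cell's front–rear polarity axis is the vector from its nucleus centroid
to its Golgi centroid; relative to the free edge (scratch wound or sprouting
front) this gives a polarity angle α, with 0° pointing into the free space.
For N cells the **polarity index** is the length of the mean resultant
vector,

```
PI = sqrt[ (1/N Σ cos α)² + (1/N Σ sin α)² ]  ∈ [0, 1],
```

1 for perfect alignment, →0 for uniformly random orientations. PI is
computed in consecutive 50 µm bins of distance from the edge. Because the
edge itself biases the first cell row toward the wound, perfect
randomization does not reach PI = 0 in practice; the **uncoordination
threshold** is therefore derived from a junction-disrupted control
(α-catenin-depleted-like) as mean + 1 SD of its per-bin PIs, first row
excluded. Applied to the published control summary (per-bin PIs with mean
0.10, sample SD 0.04) this rule yields the threshold **PI = 0.14**.

## Worked example

```python
import numpy as np
from ccpol import (EdgeReference, assign_golgi, bin_pi_by_distance,
                   derive_threshold, polarity_angle, polarity_index)
from ccpol.synthetic import MonolayerSpec, gen_monolayer, kappa_step

# a wounded monolayer: strong polarity coordination up to 300 um
spec = MonolayerSpec(n_cells=400, kappa_profile=kappa_step(((300.0, 2.5),)),
                     seed=0)
records, edge, truth = gen_monolayer(spec)

# full pipeline: re-pair nucleus/Golgi centroids, recompute angles, bin PI
pairs, _, _ = assign_golgi([r.nucleus_xy for r in records],
                           [r.golgi_xy for r in records])
for ni, gi in pairs:
    records[ni].alpha = polarity_angle(records[ni].nucleus_xy,
                                       records[gi].golgi_xy, edge)
profile = bin_pi_by_distance(records, edge, bin_width=50.0, max_distance=400)
for k, res in enumerate(profile.results):
    print(f"bin {int(profile.bin_edges[k])}-{int(profile.bin_edges[k+1])} um: "
          f"PI = {res.pi:.2f} (n = {res.n})")
```

prints (seed 0):

```
bin 0-50 um: PI = 0.71 (n = 47)
bin 50-100 um: PI = 0.82 (n = 55)
bin 100-150 um: PI = 0.84 (n = 53)
bin 150-200 um: PI = 0.74 (n = 44)
bin 200-250 um: PI = 0.79 (n = 45)
bin 250-300 um: PI = 0.74 (n = 53)
bin 300-350 um: PI = 0.17 (n = 55)
bin 350-400 um: PI = 0.13 (n = 48)
```

— coordination (PI ≈ 0.77 ± sampling noise, the von Mises mean resultant
length at κ = 2.5 being 0.74)
up to 300 µm from the edge, random orientation beyond.

## Analysis scripts

The `analysis/` drivers run the full simulated experiments and write their
tables under `results/`:

| script | analysis |
|---|---|
| `01_polarity_experiment.py` | coordinated vs uncoordinated monolayers, threshold derivation, PI profiles |
| `02_junction_colocalization.py` | calcium-switch-style co-localization time course |
| `03_fret_analysis.py` | photobleach EF recovery; activation peaks per junction / leading edge |
| `04_afm_detachment.py` | detachment work/force batches, cadherin-dependent fraction |
| `05_motion_analysis.py` | correlation lengths, track straightness, wound closure, PIV check |

Each accepts `--seed` and `--out`.

## Layout

```
src/ccpol/      library: polarity, coloc, fret, afm, motion, synthetic,
                io_core, annotation, workflows
analysis/       numbered narrative drivers writing results/
tests/          pytest suite (unit + property + acceptance checks)
docs/methods.md model, parameter and design documentation
```
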