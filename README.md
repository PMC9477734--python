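# pavecell

Quantitative image analysis for cellulose-synthase-complex (CSC) and
cortical-microtubule (MT) imaging in plant epidermal pavement cells.

Pavement cells grow into interlocking puzzle pieces; cortical MTs and the
CSCs they guide concentrate in the indenting "necks" of those cells as
shape develops. Measuring this from confocal time-lapse data requires a
chain of quantitative steps, each of which this package implements as a
tested, reusable library:

- **Surface-manifold projection** — per-pixel brightest-z of a membrane or
  MT reference channel, smoothed into a continuous height map z(x, y),
  used to sample any co-recorded channel at (or within a short
  maximum-intensity window below) the curved cell surface, suppressing
  deep signals such as bright mobile Golgi stacks.
- **Sub-pixel spot detection** — à-trous B-spline wavelet filtering,
  8-neighbourhood maxima, pixel-integrated 2D-Gaussian fitting with
  Mortensen localization uncertainty, and quality filtering (non-zero
  offset, uncertainty 5–60 nm, σ 50–500 nm, intensity < 500,000), plus
  Gaussian re-rendering and areal density normalization.
- **Tracking and motility classes** — mutual-nearest-neighbour linking and
  two speed metrics: a persistent speed `v_fit` (regression along the
  track's principal axis) and a path speed `v_step` (mean step length).
  Foci are classified with the cut-offs STALL < 25, CSC 25–200,
  SMACC > 200 nm·min⁻¹.
- **Contour geometry** — signed local curvature κ = ±1/R by least-squares
  (Kåsa) circle fitting over a fixed arc length, negative in indentations;
  margin-band intensity sampling; the curvature-correlation coefficient
  (Pearson r of κ vs intensity; r < 0 means signal in necks);
  FibrilTool-style nematic orientation/anisotropy; and the co-alignment
  angle of a cell's MT array with the nearest edge of an ablation site.
- **Co-localization** — Pearson and Manders coefficients on spot-rendered
  channels with a Costes block-randomization significance test.
- **Shape statistics** — area, perimeter, lobeyness (perimeter ÷
  convex-hull perimeter, ≥ 1), the lobeyness-vs-area rate-of-shape-
  formation regression, and Welch's unpaired two-tailed t-test with
  means ± 95 % CI.
- **Synthetic scenes** — every stage is validated against seeded
  generators with exact ground truth: curved surfaces with sub-surface
  blob confounders, moving puncta with controlled speeds and motion
  types, puzzle contours with analytic curvature, curvature-coupled
  margin textures, and channel pairs with controlled mixing.

## Worked example

```python
import numpy as np
import pavecell as pc
from pavecell.scene import observed_spots_from_truth

spec = pc.SceneSpec(shape=(600, 600), n_frames=16, seed=3)   # 110 nm/px, 1-min frames
_, truth = pc.make_spot_movie(
    spec, [(40, 0.0, "immobile"), (40, 100.0, "linear"), (40, 300.0, "erratic")]
)
spots = observed_spots_from_truth(truth, jitter_nm=20.0,
                                  pixel_size_nm=spec.pixel_size_nm, seed=4)
tracks = pc.link_tracks(spots)
tracks, fractions = pc.classify_and_fractions(tracks)
```

Running this (it is `examples/03_motility_classes.py`) prints:

```
122 tracks; class fractions (truth: 1/3 each):
  CSC     33.6%
  STALL   32.8%
  SMACC   33.6%
mean CSC persistent speed: 99.6 nm/min (planted: 100)
```

The three motility classes of a known mixture are recovered to within a
fraction of a percentage point, and the steady movers' speed to 0.4 %.
The other scripts in `examples/` walk through surface projection, spot
detection, curvature correlation, co-localization and shape statistics
the same way, each printing the measured quantity next to its ground
truth.

A thin CLI mirrors the library (`pavecell simulate | project | detect |
track | contour | coloc | shape | run`); `pavecell run --seed 3 --out out/`
executes the whole chain on a synthetic scene and writes CSV/JSON tables
stamped with the configuration hash.

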