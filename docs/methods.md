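# Methods

This note documents the models, defaults and design choices behind
pavecell, and what its synthetic-scene validation does and does not
establish about real data.

## Coordinate and unit conventions

Arrays are indexed `[z, y, x]` or `[t, y, x]`; z increases from the cell
surface into the tissue. Positions are `(x, y)` in pixels, 0-based,
sampled at pixel centres. Contours are stored with positive shoelace
area in array coordinates (interior on the left of the traversal).
Every physical quantity is derived from three calibration numbers
carried by `SceneSpec`/`ImageStack`: lateral pixel size (default
110 nm/px, plausible for a ×100/NA 1.49 objective with an sCMOS
camera — it is configuration, not an assumption about any instrument),
z-step (default 300 nm) and frame interval (default 60 s; movies default
to 16 frames). Nothing downstream hard-codes a nanometre scale.

## Surface-manifold projection

The cortex is the outermost bright structure in a reference channel
(plasma-membrane or cortical-MT marker). The raw surface estimate is the
per-(x, y) argmax over z. Robustness comes from two scales of outlier
suppression: a 5×5 median filter removes single-pixel noise flips, and
any pixel still deviating by more than 2 z-steps from a 15×15 median is
replaced by that coarse estimate — this is what rejects bright
sub-surface blobs several pixels wide, which can only pull the argmax
*inward*. The cleaned map is smoothed with a Gaussian (σ = 2 px). An
optional envelope step takes the per-pixel minimum with a smoothed
grey-erosion envelope, biasing the manifold toward the outermost
(smallest-z) signal; it is off by default because the two-scale median
already handles the generator's confounders. All window sizes are
keyword arguments.

Sampling at the surface interpolates linearly between the two adjacent
slices. The surface MIP takes the maximum over
`z ∈ [floor(h), floor(h) + depth]`, inclusive at both ends (the window
starts *at* the surface), with `depth = 3` px ≈ 1 µm at a 300-nm z-step;
windows reaching the stack bottom are clipped and logged. The same
manifold is reused across channels — that coupling is the point of the
method. Drift correction is translation-only sub-pixel phase correlation
against the first frame; rolling-ball background subtraction wraps the
standard rolling-ball estimator (radii of 5–15 px suit punctate data at
~110 nm/px).

## Spot detection and localization

Candidates are strict 8-neighbourhood maxima of the second à-trous
B3-spline wavelet plane (kernel [1, 4, 6, 4, 1]/16, dilated per level),
thresholded at 1.5 × the SD of the first plane; candidates closer than
the fit radius are merged keeping the brighter. Each candidate window
((2·3 + 1)² px) is fitted with a pixel-integrated symmetric 2D Gaussian
plus constant offset (initial σ 1.6 px) by least squares. The
localization uncertainty is Mortensen's least-squares expression with
the background correction,

    var = (σ_a²/N) · (16/9 + 8π σ_a² b² / (N a²)),  σ_a² = σ² + a²/12,

with N fitted photons, a the pixel size and b² the residual variance in
the fit window. The quality filter keeps foci with non-zero offset,
uncertainty 5–60 nm, σ 50–500 nm and integrated intensity below 500,000;
the intensity bound is in camera-count units and its mapping to
synthetic photon counts is configuration. Filtered foci are re-rendered
as unit-mass Gaussians whose SD equals their uncertainty (so the
rendered mass equals the spot count), and density is the in-polygon
detection count divided by cell area (µm²) and frame count.

## Tracking and motility classes

Linking is greedy mutual-nearest-neighbour between consecutive frames
(search radius 500 nm/frame, one-frame gap closing at twice the radius,
minimum track length 4 frames — all configurable; the defaults were
chosen so that well-separated synthetic mixtures link essentially
perfectly). Two speed metrics are computed per track, both in nm/min:

- `v_fit`, the absolute slope of position projected on the track's
  principal axis regressed against time — a persistent speed that is
  robust to localization jitter (an immobile focus with 20 nm noise
  stays below 25 nm/min);
- `v_step`, the mean frame-to-frame step length per unit time — a path
  speed that exposes erratic walkers, whose `v_fit` collapses toward 0.

Classification applies the cut-offs exactly as stated: SMACC if the path
(or persistent) speed exceeds 200 nm/min, else STALL if the persistent
speed is below 25 nm/min, else CSC (the CSC band [25, 200] is closed).
The dual-metric rule replaces the randomized-kymograph speed estimator
of the original tooling, whose algorithm is not specified; it reproduces
the stated discriminators (velocity and continuity of movement).
Kymographs (distance × time sampling along a polyline, averaged across
the line width) are provided for visual verification.

## Contour geometry

Curvature is measured by fitting the arc of fixed length centred on each
vertex to a circle with the algebraic Kåsa least-squares fit (no
iterative refinement; adequate at these arc lengths, and exactly the
method of the classic `circfit`). κ = 1/R in µm⁻¹; exactly collinear
arcs are detected by rank deficiency and give κ = 0.

The concavity convention is that the fitted centre lies outside the cell
in indenting regions. Two sign rules implement it:
`sign_rule="centre_in_polygon"` applies the point-in-polygon test
verbatim; the default `"normal_side"` tests which side of the contour
the centre falls on (inward normal ⇒ convex). The two agree whenever
the fitted circle is small enough to sit inside the cell — every neck
and lobe — but on near-straight stretches the fitted radius exceeds the
cell size and an interior-side centre can land beyond the far boundary,
which the literal test would misread as concave; the normal-side rule
keeps the closed-contour turning integral ∮κ ds at 2π.

The fit window defaults to 1.8 µm (CSC–MT data) with a 1.2 µm preset
(PM–MT data). These suit real cell margins; the synthetic puzzle
contour r(θ) = R(1 + a·cos kθ) with R = 10 µm, k = 6, a = 0.3 has necks
with a ~0.5 µm radius of curvature, so its validation uses a 0.5 µm
window — the window must stay small relative to the tightest radius
being measured. Against the analytic curvature
κ = (r² + 2r′² − r·r″)/(r² + r′²)^{3/2}, the fit is accurate to a few
percent pointwise except in two places where no estimator can do
better: at the curvature extrema (any finite window smooths a peak) and
near the zero crossings (where a pointwise *relative* error is
ill-defined because the true value passes through 0).

Margin intensity is measured only in the band extending a fixed margin
(default 1.8 µm, clipped at the cell midline) inward of the contour;
each band pixel is attributed to its nearest contour vertex, and each
vertex averages the pixels whose arc position lies within half the
locality window of it (arc-distance neighbourhood; one locality scale
serves both curvature and intensity). Vertices masked as excluded —
e.g. walls shared with stomata, supplied by the user — return NaN and
drop out of the correlation. The curvature-correlation coefficient is
the Pearson r of per-vertex κ against margin intensity over ≥ 10 usable
vertices; zero variance in either variable flags the result undefined.

The nematic tensor averages the unit-intensity-gradient outer product
over a region (trace 1); fibrils run perpendicular to gradients, so
orientation is the minor eigenvector (degrees mod 180) and anisotropy
the eigenvalue difference (0 isotropic, 1 parallel). Co-alignment with
an ablation edge is the acute axial angle between a cell's orientation
and the polygon segment nearest its centroid.

Watershed contour extraction floods the lightly smoothed membrane image
(σ = 1 px; heavier smoothing displaces ridge lines of thin walls) from
its regional minima; manual polygons are always accepted as an
alternative.

## Co-localization

Raw intensity correlation across cells with strongly varying
fluorescence is unreliable, so the intended mode compares spot-rendered
channels (a raw mode exists). Manders coefficients use the classic zero
thresholds by default (identical positive channels give M1 = M2 = 1);
per-channel Otsu thresholds are available via `thresholds="otsu"` for
strongly backgrounded data. The Costes test shuffles non-overlapping
blocks of channel A and recomputes Pearson r; the add-one p-value
(1 + #{r_shuffled ≥ r_observed})/(n + 1) cannot reach 0, and 999
randomizations make p = 0.001 the smallest attainable value. Blocks
must be at least as large as the image's correlation length (the PSF
for real data); on the generator's smooth fields (~5 px FWHM) a 10-px
block keeps the null conservative, which the tests verify by simulation.

## Shape statistics

Lobeyness is perimeter divided by convex-hull perimeter — exactly 1 for
convex outlines, invariant to similarity transforms; it is the one
place the shape-complexity definition lives. Area uses the shoelace
formula times the squared pixel size. The rate of shape formation is
the OLS slope of lobeyness on area (cells pooled across individuals;
slope comparisons use a Welch-style t on the slope standard errors).
Group comparisons use Welch's unpaired two-tailed t-test with
Welch–Satterthwaite df, and summaries report means ± 95 % CI from the
t quantile.

## Synthetic scenes: what they do and do not show

The generators reproduce the *geometry and statistics* the measurements
rely on: a smooth surface band with Poisson/Gaussian camera noise and
deep bright blobs; pixel-integrated Gaussian puncta at controlled speeds
with immobile/linear/erratic motion (erratic = fixed-step random walk
with a fresh direction each frame); analytic puzzle contours; margin
paint whose weight mixes standardized curvature with an independent
smooth random profile, `w = 1 + amp·(−c·κ̂ + √(1−c²)·u)`, so the
expected curvature–intensity correlation is −c exactly; and channel
pairs `B = ρA + (1−ρ)·independent`. They do not model full optics
(no empirical PSF, spherical aberration or depth-dependent blur),
MT dynamics or mechanics, photobleaching, or the intensity
heterogeneity of real tissue. Passing tests therefore demonstrate that
the measurement chains are correct and unbiased under controlled,
realistic noise — not that any particular biological value will be
reproduced from real recordings.

Validation problem sizes (256×256×40 surface scenes, 200-spot
localization fields, 300-track mixtures, 100-seed coupling ladders,
50-seed null calibrations) were chosen as the smallest at which the
Monte-Carlo variability is well below the tolerances being checked.

## Known limitations

- Single surface per column: anticlinal walls and multi-layer tissue
  are out of scope.
- The linker is greedy; very dense fields with frequent crossings need
  a global assignment method.
- The curvature window trades locality against noise; profiles at
  extrema are smoothed by construction.
- Automatic stomata recognition is not provided; exclusion masks are
  user-supplied.
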