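# Methods

`fragscan` implements an automated pipeline for counting, sizing and
classifying micro-fragments (particles and fibers, roughly 1–1000 µm)
deposited on circular filter membranes and imaged in dark-field
microscopy, together with the statistical machinery needed to turn
window-wise measurements into a filter-level count with a defensible
uncertainty.  This note records the model assumptions, the parameter
choices that matter, and the numerical decisions taken where the design
was genuinely open.

## Image model and preprocessing

The input is a single-channel raster with a physical resolution in
µm/pixel, always supplied explicitly (sizes downstream are physical, so
a silently wrong resolution would corrupt every size class).  Bright
objects sit on a dark but structured background: track-etched membranes
carry a dense quasi-periodic pore lattice, plus smooth illumination
gradients and sensor noise.

Preprocessing runs three stages in order, each individually switchable:

1. **Fourier-domain background filter.**  The image is split into N
   equal sections (default 4, a 2×2 grid — the smallest grid that
   samples background from distinct regions).  Each section is
   mirror-tiled back to full size (even-symmetric tiling, so seams are
   continuous and introduce no spurious frequencies), and the geometric
   mean H of the tiled sections' magnitude spectra is formed.
   Structure present everywhere (the pore lattice) reinforces in H;
   one-off objects are diluted.  The image spectrum F is attenuated by
   the gain |F|/(|F|+H), phase untouched, DC passed through, and the
   result inverse-transformed and clipped to ≥ 0.  The step is repeated
   3 times by default ("several" repetitions trade residual background
   against object erosion; three is where the background variance curve
   flattens on synthetic pore scenes).

   Two numerical choices here were open and are worth recording.
   First, the raw product of N magnitude spectra is dimensionally
   inflated (units of intensity^N); H is therefore rescaled to the
   geometric mean so it stays commensurate with |F|.  Second, the gain
   is computed from *frequency-smoothed* magnitudes (Gaussian, σ = 2
   coefficients).  Per-coefficient magnitudes are speckled by noise,
   and a speckled gain acts on the image like convolution with a random
   kernel: bright-object energy is scattered into background ripples
   that the adaptive threshold later picks up as ~13–25 px false
   objects (on the standard synthetic scene this produced roughly a
   hundred of them).  Smoothing the gain removes the speckle while the
   narrow pore-lattice peaks remain attenuated; the identity behaviour
   for structure-free images and the monotone attenuation in H are
   unaffected.  Setting `gain_smooth_sigma: 0` restores the raw gain.

2. **White top-hat** by a disc of radius 31 px: input minus its
   grayscale opening.  It rescues small particles near large, highly
   reflective ones at the cost of distorting the large ones.  For radii
   above 5 the disc is applied as scikit-image's decomposed footprint
   sequence (an octagonal approximation), an order of magnitude faster
   with sub-percent differences.

3. **Grayscale opening** with a 3×3 square: removes sub-minimum bright
   specks (the role a median blur plays in simpler pipelines).

## Detection

A pixel is foreground iff its intensity strictly exceeds the local mean
plus 6 (adaptive mean threshold, C = −6, reflected borders).  Two
passes run with block sizes 243 px and 91 px: the large block keeps
large dim objects whole (a 91-px window inside a large plateau sees a
local mean equal to the plateau and hollows it out), the small block
sees faint small objects near bright ones.  The two binary maps are
combined by pixelwise union and connected components extracted once —
double counting is structurally impossible.  Holes are filled (only
outermost contours are kept), and components are gated by pixel area
(≥ 13 px; below that a contour carries too few pixels for shape
classification) and by a physical min/max Feret range.  Block sizes are
pixel quantities of the constant-resolution export and are not rescaled
with magnification.

Objects touching the image border are dropped (their morphology is
undefined); in window mode an ISO 13322-1-style counting frame (70 µm
inside a 120 µm field of view) additionally keeps objects that
intersect the frame without touching its right/bottom exclusion edges.
The rule is implemented on object bounding extents, which makes the
frame exactly unbiased: tiling a plane with frames counts every object
(smaller than the frame period) exactly once, a property the test suite
checks by brute force.

## Morphology

Six dimensionless features feed the classifier: circularity
f1 = 2√(πa)/p, Feret-box fill f2 = a/(d_min·d_max), aspect ratio
f3 = d_min/d_max, solidity f4 = a/a_convex, elongation f5 = √a/d_max,
and the width-variation coefficient f6 = SD/mean of the local width
profile.  Measurement conventions (each chosen once, used everywhere):

- **Area** is the pixel count.
- **Perimeter** is the marching-squares boundary polygon resampled
  every 3 vertices.  Raw chain/polygon lengths overestimate smooth
  digitized boundaries by up to 8% (f1 of a disk would read 0.93); the
  coarse polyline is within ~2% for both digitized disks and true
  polygons, and is stable under raster rotation (< 3% feature change at
  37°), which prediction invariance depends on.
- **Feret diameters** are rotating-caliper widths of the pixel-centre
  convex hull plus one pixel (pixels as unit-diameter disks).  This is
  exact for axis-aligned rasters — a 4-px-wide fiber reads width 4 —
  and within rasterization error elsewhere; agreement with a 0.1°
  brute-force rotation oracle is ~1%.
- **Skeletons** come from `skimage.skeletonize`; the longest path
  through the skeleton's 8-connected pixel graph is found by a double
  Dijkstra sweep (exact on trees) and its length measured on the path
  resampled every 4 px, again to avoid digital-curve inflation.  A
  compact object whose skeleton collapses to a point is valid with
  length 0; only an empty skeleton is a failure, in which case the
  maximum Feret diameter stands in as fiber length.
- **f6's distance list** is, by default, the Euclidean distance
  transform sampled along the skeleton's longest path — a local width
  profile, ≈ 0 for constant-width fibers and large for irregular
  particles.  The alternative reading (skeletal branch lengths) is
  implemented behind `f6_mode="branch"`; the width profile is the
  default because it is the discriminative one for shapes with few
  branches.

The per-object measurement point (one Raman spot per fragment) is the
argmax of (once-eroded masked intensity) × (distance transform): bright
and deep inside the object, never on the boundary, ties broken
row-major for determinism.

## Fiber classification

A random forest (200 trees, unlimited depth, balanced class weights,
seed 42 — exposed in config; the problem is small-tabular and
insensitive to these within reason) maps f1–f6 to fiber/particle.  The
package ships the training path plus a synthetic labelled-set generator
(500 rasterized random smooth curves spanning straight to strongly
curved, against 1500 particles: ellipses, irregular blobs, small
agglomerate clusters).  Out-of-bag fiber recall on that set is the
quality gate (≥ 0.8).  Models serialize to a JSON of tree arrays with a
fixed feature order and a pure-numpy traversal predictor, so a loaded
model predicts identically anywhere; a round-trip test pins the loaded
predictions to the in-memory ones.  Real deployments should retrain on
expert-labelled contours; the synthetic set emulates the geometry of
that task, not the optics of any particular instrument.

## Adaptive de-agglomeration

Watershed splitting is restricted to plausible agglomerates: non-fiber
objects whose solidity f4 lies below a threshold calibrated once by an
exact 1-D Otsu (no histogram binning; degenerate single-valued input is
an error) on the convexity distribution of a representative image.
"Below" encodes the reading that agglomerates are the concave class; an
inversion flag exists for the opposite convention.

A candidate's eroded masked intensity times its distance transform
forms the topographic map.  Markers are the regional maxima of that map
— lightly smoothed (σ = 1.5 px) to merge texture-induced twin maxima
inside one grain — that reach half the global peak; watershed runs on
the negated map constrained to the parent mask.  A split is accepted
only with ≥ 2 children of ≥ 13 px (the detection area rule applied
globally; smaller children are discarded, not re-merged).  Accepted
children replace the parent in size classification while the
all-particles listing keeps the parent.  Regional maxima rather than a
thresholded super-level set matter: at moderate overlap two grains'
peaks connect through a high saddle, and a thresholded marker mask
would fuse them and reject the split.

## Subsampling and uncertainty

**RS** (full-filter imaging): if detected objects exceed the intended
measurement count (default 7000), a uniform sample without replacement
of exactly that size is measured.  The reported uncertainty for RS is
the binomial error of the measured subset only — the smallest possible
error, as it ignores spatial effects.

**RWS**: square windows (70 µm in a 120 µm FOV) are placed uniformly
over the region where they fit inside the filter disc (rejection
sampling; overlap permitted — forbidding it would bias placement near
the rim; a non-overlap mode exists behind a flag).  The filter total is
the area-proportion extrapolation N̂ = A_filter/(n·A_window) · Σcounts,
computed pooled and per material/size class.  Every 10th window a
percentile bootstrap (B = 1000, level 90%) of N̂ over the per-window
counts is computed; the campaign stops when the relative half-width
(half-width / point estimate) undercuts the configured threshold, or on
the window/fragment/time caps, caps being checked every window and the
uncertainty only at the cadence.  The percentile interval was chosen
over BCa/normal as the simplest defensible variant; all randomness
derives from a single campaign seed, so campaigns replay exactly.

Calibration at the defaults (100 windows, Poisson counts) is ~90%
coverage; at 30–40 windows the percentile interval undercovers by a few
points, which is the small-sample price of the method, visible in the
campaign simulations.

## Synthetic scenes

The generator emulates: jittered pore lattices (spacing 2.5 µm, radius
0.4 µm, matching 0.8 µm-pore membranes at high magnification), smooth
illumination gradients, Gaussian noise, bright particles (ellipses and
radially perturbed blobs), constant-width random smooth curves as
fibers, agglomerates as overlapping blob clusters, CSR or
parent–offspring (Neyman–Scott) clustered placement, and soft 1-px
Gaussian object edges to exercise threshold boundaries.  It does not
emulate diffraction, glare, stitching artefacts or focus gradients of
real exports — so passing tests demonstrate the pipeline's logic and
statistics, not instrument-specific detection rates.

The default scene resolution is 0.25 µm/px, chosen so the 1 µm lower
size limit corresponds to ~13 px of area — the same pixel count the
detection gate requires, keeping the size gate and the area gate
consistent at the lower end.

`VirtualFilter` serves whole-filter scenes window by window for
campaign simulations: object centres for the entire disc are drawn
once, so overlapping windows see consistent content; per-window
backgrounds derive deterministically from the window centre.  Campaign
simulations use a scaled-down 2 mm disc and 30–60 windows per campaign
(the extrapolation algebra is scale-free; a 20 mm disc at realistic
density would mean ~10⁸ planted objects) and plant particles of
2.5–5 µm so the smallest objects sit comfortably above the 13-px gate
rather than oscillating across it.  The recovery simulations plant
~3 objects per window area, at which ~98% of particles are isolated —
the operating regime the whole
detect-first-then-measure approach presumes (the CSR isolation bound:
400 particles of ~50 µm on 314 mm² already reduce isolation to 99%).
Denser scenes work but accumulate a percent-level count deficit from
deeply overlapped pairs that no splitter can separate — the
mitigate-but-not-eliminate behaviour expected of de-agglomeration, and
the reason aliquot volume matters in practice.

The repeated-measurement simulation adds a per-campaign optical
condition drift (`defocus_sigma`, a Gaussian blur of the rendered FOV)
on a clustered scene with a faint object subpopulation.  Clustering
alone cannot make the between-campaign spread exceed the bootstrap
interval: window counts within a campaign remain i.i.d. draws from the
(overdispersed) field, which the bootstrap estimates consistently, so
the spread stays near 0.6× the 90% half-width by construction.  An
excess requires a factor that varies between campaigns but is invisible
within one — drifting measurement conditions — and with it the spread
of final estimates exceeds the mean bootstrap half-width, which is how
the between-group variance of repeated real measurements presents.

## Reporting

Identification tables (spot coordinate, material, hit-quality index)
are joined one-to-one to objects by greedy nearest spot within 1 µm
(spots come from the same raster, so only rounding separates them);
the join is invariant under record permutation, unmatched objects are
flagged rather than dropped, and a material is assigned iff HQI ≥ 0.45
(inclusive).  Unassigned spectra count as non-plastic by default
(conservative plastic totals).  Size classes bin by minimum Feret with
default edges 1, 5, 10, 20, 50, 100, 500, 1000 µm (configurable; the
defaults span both subsampling regimes).  Outputs are
`final_result_all_particles.csv`,
`final_result_size_classification.csv`, a class-coloured contour
overlay PNG, and a metadata YAML carrying every parameter and seed
needed to replay the run.

## Known limitations

- Detection rates on real instrument images are not validated here;
  the synthetic scenes bound the logic, not the optics.
- The percentile bootstrap undercovers slightly below ~50 windows.
- Heavily overlapped grains (centre distance ≲ radius) are genuinely
  indistinguishable from single particles and stay merged.
- The shipped classifier is trained on synthetic geometry; expert
  retraining is expected for production use.
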