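# Methods

## The density estimator

Cone density at a query point is computed from the 150 nearest annotated
cone centers: one global Voronoi tessellation assigns each cone its
exclusive territory, and density is 150 divided by the summed areas of
the 150 nearest cones' cells (equivalently, the reciprocal of their mean
cell area), converted to cones/mm².  Summing per query from one global
tessellation is mathematically identical to re-tessellating per pixel
and far cheaper.  The window therefore adapts its size to local density:
its radius is ≈ √(150/πD), about 17 µm at the foveolar center and 27 µm
at 240 µm eccentricity.  The estimate is a harmonic-type local mean, so
maps are smooth at the scale of that window; the peak of a measured map
sits ~1% below the true central density of a steeply peaked field, which
is also the order of the PCD–D₀ gap seen in measured maps.

**Border handling.**  Cells of convex-hull cones are unbounded and carry
no area.  Cells with a vertex outside the convex hull of the cones are
treated the same way: nearly-collinear border cones produce formally
bounded but arbitrarily large cells, equally unusable.  Any query whose
150-cone neighbourhood touches such a cell returns an explicit invalid
marker rather than a hull-clipped, biased value.  Valid map regions
therefore end roughly one window radius inside the annotated field.

**Ties.**  k-nearest ties at exactly equal distance are resolved by the
k-d tree's deterministic internal order.  Ties occur only on perfect
lattices, where the tied cells have equal areas and the estimate is
unchanged.

## Landmarks

PCD is the single highest valid map value.  The CDC is the
density-weighted centroid of the 8-connected set of grid points with
density ≥ 0.8·PCD that contains the peak (density values as weights,
mirroring an intensity-weighted centroid); D₀ is the bilinear map value
at the CDC, and the top-20% region's cell count × spacing² is the
iso-density contour area.  A flag marks regions touching the valid-mask
border, where the centroid may be truncated.  Default grid spacing is
1 µm (configurable; the test suite uses 2–4 µm, which changes measured
landmarks by well under the tolerances tested).

## The sigmoid decay model

Density vs. eccentricity is modelled as `D(E) = D0/(1+(E/a)^b)^c`: `a`
(µm) sets where the drop-off begins, `b` its sharpness, `c` the tail
flatness.  Fitting is nonlinear least squares on raw density (matching
how residuals are reported), constrained to a ∈ [0.1, 150], b ∈ [1, 3],
c ∈ [0, 1], with Tukey-bisquare robustness (tuning constant 4.685, MAD
scale; the weights are iterated to a fixed point, declared at relative
parameter change < 1e-8, cap 400 iterations).  A perfect-fit guard
(zero robust scale) keeps noiseless data at unit weights.  D₀ is fixed
at the measured CDC density by default — it is a measured quantity, not
a free parameter — with a free-D₀ mode available.  All fits seed at the
normative radial triplet (55.50, 2.453, 0.2726) unless told otherwise;
on noiseless model samples the fitter recovers the generating triplet
from any seed in the constraint box.

Derived descriptors: the eccentricity where density falls to a fraction
f of D₀ has the closed form `a·((1/f)^(1/c) − 1)^(1/b)`; the maximum
(most negative) slope and its eccentricity are obtained by numerical
differentiation of the fitted model at 0.01 µm steps.  Slope metrics for
a raw profile fit the model first; they are model-based by definition.

## Profiles

Meridional profiles average valid map values inside isosceles triangle
sectors with a 5° vertex angle at the CDC, binned at the grid spacing;
full-meridian profiles average the two opposite sectors per
eccentricity.  Radially averaged profiles take the mean of bilinear map
samples on circles at 1° angular steps (the value at E = 0 is the map
value at the CDC), and stop at the first circle that leaves the valid
region — partial circles are rejected rather than renormalized.
Circular profiles sample one circle as a function of retinal angle
(0° = nasal, 90° = superior); left eyes and synthetic mosaics have nasal
at +x, right eyes are mirrored about the vertical axis so fellow eyes
are comparable in retinal coordinates.

Intercone distance is defined here as a cone's mean distance to its
Voronoi neighbours (the field uses ICD loosely; this is our concrete
choice), excluding boundary cones, binned by eccentricity and smoothed
by a centred 11 µm moving mean truncated at the domain ends.  On locally
hexagonal mosaics ICD ≈ √(2/(√3·D)).

Angular↔linear conversion uses the retinal magnification factor (RMF,
µm/degree): lengths scale by RMF, densities by RMF².  RMF is per-eye
metadata; 291 µm/degree (emmetropic approximation) is the default when
biometry is absent.

## Rugosity

Circular profiles (D₀-normalized; the analysis is amplitude-invariant)
are smoothed by an 11° circular moving mean — smoothing wide enough to
suppress annotation-scale noise but narrow against the 2-cycle structure
of interest.  Local extrema are found with wrap-around; adjacent
same-type extrema are reduced to the strongest so peaks and troughs
alternate.  Each flank between a peak and an adjacent trough crosses
half-height at the mean of the two extremum values; an extremum's width
spans its two flank crossings, so peak and trough widths tile the 360°
circle.  Rugosity is Σ(trough widths)/Σ(peak widths) ("combined" ratio
read as a ratio of sums); values above 1 indicate a horizontal ridge of
elevated density.  Profiles with angular CV < 1% are declared flat and
get no rugosity.  For `exp(k·cos 2θ)`-shaped modulation the half-height
geometry gives peak widths `2·arccos(ln cosh k / k)` < 90°, so rugosity
grows monotonically with k; a pure cosine modulation gives exactly 1.

## Occlusion recovery

A normative reference holds the cohort mean and SD of radial profiles on
a common eccentricity grid and, per candidate occlusion radius, an OLS
regression of measured D₀ on the mean z-score in the 50 µm ring adjacent
to the occlusion (ring z-scores are means of per-eccentricity z-scores;
the ring width is configurable but wider rings were not found to help).
Recovery of an occluded eye is: ring z-score → regression → D₀ estimate
→ constrained robust refit of the visible profile with D₀ fixed, seeded
at the cohort-average triplet.  Regressions are fitted per radius, not
pooled.  Validation uses a leave-one-out protocol — the reference never
contains the eye under test — and reports relative |D₀ error| per radius
and the relative profile error inside the occlusion.

## The synthetic mosaic generator

The generator emulates fully annotated foveolar mosaics.  The target
intensity is `D(E, θ) = D0 · f(E; a(θ), b(θ), c(θ)) · g(θ)`, with the
shape triplet interpolated between the horizontal and vertical normative
fits with cos²θ weights (smooth, symmetric, exact on both meridians) and
`g(θ) = exp(k·cos 2θ)^m / I0(k·m)` an optional rugosity modulation with
unit angular mean (k = 0 recovers isotropy; the exp shape makes troughs
wider than peaks, as observed).  Points are placed by laying a hexagonal
lattice at uniform density D₀ in a density-equalised plane and applying
the angle-dependent radial warp that matches cumulative radial mass,
`∫₀^r D(s,θ)·s ds = D0·u²/2`.  The warp's areal Jacobian is exactly
D₀/D(r,θ), so the realised intensity equals the target field; its
azimuthal shear distorts only cell shapes and stays mild for foveolar
anisotropies.  Annotation click noise is isotropic Gaussian jitter
(default SD 0.3 µm, ~12% of central cone spacing — the field does not
quantify click noise, so this is a fixed modelling choice), applied
after placement from one seeded generator per mosaic; the seed and full
config are recorded in the mosaic's provenance.  Measured fidelity on
jitter-free mosaics: the pipeline's own estimator matches the target
within ~1% up to 80% of the field radius (contract: ≤ 5%).

Defaults are the normative study conditions: D₀ = 175,500 cones/mm²,
horizontal triplet (61.95, 2.469, 0.2680), vertical (59.11, 2.012,
0.3568), 300 µm field radius.

**Cohort simulator.**  Cohorts of radial profiles are drawn with
D₀ ~ Normal(175,474, 20,543²) truncated to the observed range
136,001–216,209 cones/mm², the radial shape triplet jittered by a
between-eye SD of (4 µm, 0.12, 0.015) — chosen via the delta method so
the simulated 50%-crossing spread reproduces the normative 151 ± 17 µm,
since triplet SDs are not reported — and 2% multiplicative Gaussian
noise per bin, the typical residual of individual fits.  Occlusion
validation uses 57 eyes, the size of the multi-laboratory validation
set.

**What the generator does not model**, hence what passing tests do not
show about real data: cone reflectance variability, rods intruding near
0.5°–0.75°, the foveal avascular zone, montage seams and registration
distortion, and any higher-order spatial statistics of real mosaics
beyond quasi-hexagonal packing (each interior cone has 5–7 Voronoi
neighbours at realistic jitter).  Real anisotropy need not follow the
cos²θ interpolation, and real between-eye shape variation need not be
independent Gaussian jitter of (a, b, c).

## Problem sizes and degenerate inputs

The test suite runs mosaics of 120–300 µm field radius (≈7k–23k cones)
with 2–4 µm map grids, 10-seed replicates for isotropy/rugosity
statistics and a 57-eye cohort for recovery validation — sizes at which
every tested tolerance is stable with margin.  Degenerate inputs are
rejected loudly rather than coerced: < 4 or collinear cones (no
tessellation), configurations implying < 200 cones (too few for the
150-cone estimator), constant profiles (unfittable), sub-10-bin
profiles, zero cohort SD, double normalization, rings or circles not
fully covered by valid data.
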