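# Methods

This note documents the models and procedures implemented in `vncflow`,
the parameters that matter, and what the synthetic-data tests do and do
not establish about real measurements.

## Coordinate and unit conventions

Image axis 0 is y, axis 1 is x; x increases along the anterior–posterior
axis from head to tail, so tail-to-head motion has a negative
x-component and a directionality angle of π. Lengths are in µm, time in
minutes, forces in nN, moduli in Pa, membrane tensions in N/m. All
stochastic routines take explicit integer seeds and never touch global
random state; identical seeds give bit-identical outputs.

## PIV

Each grid node (spacing `grid_size`) centres a source window in frame
*t*, matched against a larger search window in frame *t+1* by the
zero-mean normalized cross-correlation coefficient, so the validity
threshold (0.5 or 0.3 depending on preset) lives on the familiar [0, 1]
correlation scale. Window sizes in µm are rounded to the nearest odd
pixel count (≥ 3 px) so windows are centred. The integer peak is refined
per axis by a three-point Gaussian fit on the log-correlations, falling
back to a parabolic fit when a neighbour is non-positive, and clamped to
±1 px; when the peak correlation is exactly 1 (a perfect match, as with
noise-free data) no refinement is applied, since the Gaussian model
could only add bias. Vectors are invalid when the peak correlation falls
below threshold, the source window has zero variance, or the node lies
outside the region-of-interest mask; invalid vectors never enter any
downstream statistic. Displacements are stored in µm per frame pair and
converted to µm/min only at reporting.

The measurable displacement is bounded by (search − source)/2; the
speckle renderer warns when an imposed flow exceeds a declared search
margin. The three acquisition presets (`confocal_whole`,
`confocal_hires`, `mosaic`) bundle window parameters with their
smoothing kernels (spatial 50 µm size / 10 µm sigma with temporal
90 min / 40 min, or spatial 10 µm / 2 µm with temporal 5 / 2 frames).

Smoothing is a truncated-Gaussian weighted mean: kernel *size* is the
full truncation width, sigma the Gaussian scale, applied separably in
x, y, and t over valid vectors only, with weights renormalized over the
contributors. The result is therefore a convex combination of observed
vectors — uniform fields pass through unchanged, and nodes with no valid
contributor stay invalid rather than becoming zeros. Iterative window
deformation, pyramidal multi-pass schemes, and 3-D PIV are out of scope.

## Flow statistics

Kymographs average |v| (or the signed x-component) over all valid
vectors in each grid column per frame; empty columns are missing values,
never zeros.

Local alignment coherence samples 256 reference locations per frame
uniformly among valid non-zero vectors (without replacement when enough
exist, with replacement otherwise — the sampling rule is exposed and
seeded). Each reference is compared by |cos θ| against every other
valid non-zero vector within an 8 µm radius; the reference is excluded
from its own neighbourhood because self-comparison contributes a
constant 1 and inflates the statistic. Per-reference means are averaged
per frame and the series smoothed with a centred 5-frame walking
average whose window shrinks at the edges. The statistic is invariant
to uniform magnitude rescaling and to global rotation; for iid uniform
orientations its expectation is E|cos θ| = 2/π, which the tests verify
by Monte-Carlo.

Directional coherence bilinearly samples the smoothed field on an
11×11 grid with 3 µm spacing centred on the region of interest and
averages the signed cos θ against the tail-to-head unit vector;
degenerate (zero or invalid) samples are excluded and an all-degenerate
frame is missing.

## Track analysis

A track enters a (region, window) set only if its portion inside the
time window has strictly more than 10 samples ("longer than 10 frames"
is read as ≥ 11 samples; at the 10-min frame interval that is the
100-min rule). The default windows are 0–180 min and 420–600 min from
condensation onset. Region is assigned from the track's *mean* x
position relative to the supplied boundary (first-position assignment
differs only for tracks straddling the boundary; the mean is the more
stable choice for drifting cells). Directionality is the angle of the
start-to-end vector with 0 on the head-to-tail axis, binned at 20° by
default; tracks with exactly zero net displacement have no angle and
are counted separately. Mean average velocity is path length over
duration — the tracking-software "average speed" convention — which is
invariant under time reversal, unlike the net-displacement velocity.

## Morphometry

The tissue is idealized as an elliptical cylinder: volume
π(W/2)(H/2)L; surface area = perimeter × L + two elliptical end caps,
with Ramanujan's first perimeter approximation (relative error < 1e-4
at the aspect ratios involved). End caps are included because the
tissue surface is closed; since that choice is a convention, all
surface-area claims in the package are about *relative changes*, which
are insensitive to it.

Outlines are fitted with the direct algebraic least-squares conic
(ellipse-constrained) estimator after centroid removal; eccentricity
e = √(a²−b²)/a equals the inter-focal distance over the major-axis
length. Collinear input is rejected — the e → 1 limit is not fittable.
An alignment helper centres an outline and rotates its major axis onto
the horizontal for presentation.

Sparse polygon annotations at distant z-planes are interpolated by the
shape-based method: each polygon is rasterized (0.25 µm default pixel),
its signed distance transform computed, and intermediate slices
obtained by linear interpolation of the signed distances; volume is the
trapezoidal integral of slice areas. For concentric circles this
reproduces the cone-frustum volume to well under the 2% test tolerance.
A triangulated-mesh re-slice would satisfy the same contract; the
signed-distance route has no meshing failure modes.

## Intensity dynamics

Moving averages are centred with shrinking edge windows, preserving
trace length. The AP-axis profile discards pixels above 70% of the
image *maximum* before column-averaging — the brightest objects are
intracellular puncta, and a relative cutoff keeps the rule invariant to
overall intensity scaling. The referent of the percentage is genuinely
ambiguous (maximum vs cumulative histogram), so a `quantile` mode is
provided behind a switch; fraction-of-max is the default. An image with
zero dynamic range has no outliers to reject and passes through.

Tail displacement is measured against the first clicked position,
either as Euclidean distance or as signed projection on the AP axis;
the condensation rate is its central difference, smoothed with the same
10-frame window as the intensity before correlation. The reported
Pearson r is a statistical association with no causal reading; inputs
with zero variance are flagged and r is undefined.

## Photobleach stripe analysis

Profiles are normalized to their own mean (the normalization target is
unstated in the protocol; the mean keeps the baseline at 1 and the
statistic scale-invariant), smoothed with a 150-point centred walking
average, and searched for local minima with a prominence floor of 5% of
the smoothed profile's range (a free choice, exposed in the API).
Minima are refined to sub-sample precision by a parabola through the
three points around each discrete minimum, and paired by rank order
between the two timepoints, which preserves ordering — displacements
cannot cross. Displacement is position(t1) − position(t0) on the
head-to-tail axis, so head-ward motion is negative; a graded magnitude
growing toward the tail is the anisotropic-motion readout.

## AFM Hertz fitting

Force is F = k·d and indentation δ = (z − z_c) − d: the piezo travel is
shared between cantilever bending and sample indentation. The modulus
follows the spherical Hertz law F = (4/3)·E/(1−ν²)·√R·δ^(3/2) fitted
over δ ∈ [0, 230 nm]. Defaults: R = 5 µm (a 10 µm bead), k = 0.2 N/m,
ν = 0.5 (incompressible soft tissue; exposed in the model), setpoint
3 nN. Only the approach segment is modeled.

The contact point is estimated jointly with E rather than by a separate
threshold detector, which is unreliable on soft samples: a fixed fit
window is established once from a rough baseline-noise crossing
(baseline statistics from the first fifth of the curve), and candidate
contact points on a grid are each scored by the residual of a linear
least-squares fit of F against clip(δ, 0)^(3/2) *over the whole
window*, including the flat pre-contact baseline — this anchors the
contact point, because windows placed too early or too late misfit the
rise. The best candidate is refined continuously by bounded 1-D
minimization, and the reported E is then re-fitted over the target
depth only. On noise-free curves this recovers E to better than 0.1%
and the contact point to a small fraction of a sample; at 5% force
noise (relative to the Hertz force at the target depth, the signal
scale of the fitted region) a 100-curve ensemble recovers the mean
modulus within a few percent. Tip-shape calibration, thermal spring
calibration, and viscoelastic models are out of scope.

## Core+shell mechanics

The model exists to reproduce *sign and ordering patterns* of the
tissue shape change, not magnitudes: the study's claims at this level
are qualitative, and no material constants, shell thickness, or load
magnitudes are available to match. Accordingly the core is small-strain
linear elasticity — in the linear regime every sign pattern is exactly
invariant under load rescaling, which is also why the ×10 load-sweep
tests are cheap.

Geometry: a capped elliptical cylinder, L = 200, W = 40, H = 20 µm by
default, head cap fully fixed ("attached to the brain"). The flat
cross-section (eccentricity ≈ 0.87) reflects the real tissue — two
nerve cords side by side — and is mechanically load-bearing: the
isotropic-tension outcome (length *and* width decrease, cross-section
rounds) arises from the stronger Laplace pressure at the
high-curvature lateral edges winning against the Poisson expansion
that accompanies axial shortening, and for nearly round sections the
two nearly cancel. Material defaults E = 100 Pa, ν = 0.49 (nearly
incompressible); load defaults (σ_ax = 2e-5 N/m, σ_circ = 2e-6 N/m,
P = 5 Pa) keep strains small.

Discretization: the ellipse cross-section is triangulated
(rings × angles + centre, Delaunay) and extruded into prisms along the
axis; each prism is split into eight tetrahedra through its centroid,
with quad faces triangulated by a smallest-global-index diagonal rule
so neighbouring prisms conform. Default mesh: 16 angles × 3 rings × 21
stations (≈ 2600 grid nodes, ≈ 13k linear tetrahedra); a 2× refinement
changes ΔL by under 1%. Linear tetrahedra lock somewhat at ν = 0.49,
so absolute displacements converge slowly and the unstructured
triangulation breaks exact mirror symmetry at the few-percent level —
both are documented discretization effects that leave the sign
patterns untouched.

Loads: normal pressure contributes −P·n̂·A/3 per surface-triangle node.
Membrane tension enters as the equivalent nodal force of a constant
in-plane prestress on each surface facet, −A·Bᵀσ in the facet's local
frame, with σ_ax along the projection of the tissue axis onto the
facet and σ_circ transverse; for isotropic tension this is exactly
−σ·∂A/∂x, the gradient of the membrane energy. End caps carry the
transverse tension component (the axial direction is normal to a cap,
so an "axial" in-plane tension is undefined there). The optional stripe
rescales the tension of lateral facets whose axial centroid lies
within the band; because the load vector is affine in the stripe scale,
the tail displacement is monotone in it.

Readouts: ΔL from the mean axial displacement of the tail cap (tail
displacement is its negative), ΔW and ΔH from the extremes of the
deformed mid-length boundary ring, mid-section eccentricity from an
ellipse fit of that ring, and relative volume change from re-summed
tetrahedron volumes. Abaqus-level nonlinearity, viscoelastic
remodeling, and contact with surrounding organs are out of scope.

## Synthetic data: what it emulates, and what passing tests show

The generators reproduce the *statistical structure* the analyses
assume, with known ground truth:

- Speckle stacks: Gaussian-blob textures advected by backward mapping
  with bilinear interpolation (no hole artifacts; exact for integer
  shifts, so phase correlation provides an independent oracle),
  exponential photobleaching, and additive Gaussian read noise clipped
  at zero and *not* advected. Texture statistics (density 0.05,
  sigma 1 px) are free knobs, not claims about Col4 texture.
- The condensation scene: phase 1 (0–180 min) shortens L by 40% along a
  smoothstep ramp while W and H grow by √(L0/L) each, conserving the
  elliptical-cylinder volume exactly; the implied surface-area drop is
  ≈ 15%, consistent with the geometry of an isovolumetric fast phase.
  Phase 2 (180–720 min) shrinks all dimensions linearly by 15%, losing
  volume. Intensity rises exponentially (20× over 4 h) until
  saturation; the tail follows a logistic ramp (midpoint 170 min,
  τ = 40 min) whose rate peaks late in phase 1 — the coupling between
  induction and condensation rate that the scene exists to emulate, and
  the reason the intensity–rate correlation on the default scene is
  strong (r ≈ 0.95). An early-midpoint logistic would decorrelate the
  two for purely geometric reasons.
- Force curves solve the implicit Hertz relation per sample (Newton
  iteration), so the generated deflection shares travel between bending
  and indentation exactly as the calibration assumes.
- Bleach profiles place five Gaussian dips of 20 µm FWHM at 50 µm
  spacing over 320 µm with multiplicative noise; the t1 pattern is
  displaced head-ward, uniformly or per-stripe.

Passing these tests establishes that the estimators are correct and
unbiased *under the generating assumptions* — rigid advection, Gaussian
noise, ideal Hertz contact, exact ellipses. Real recordings add
deformation within PIV windows, intensity inhomogeneity, drift,
non-Hertzian contact, and segmentation error, none of which the
generators model; the tests bound algorithmic error, not measurement
error.

## Numerical choices and degenerate inputs

Tolerances and tie-breaks that matter: PIV sub-pixel offsets are
clamped to ±1 px and ties break toward smaller displacement; featureless
(zero-variance) windows yield invalid vectors rather than NaNs that
would poison statistics; all-invalid kymograph bins and coherence
frames are missing values; the ellipse fit rejects < 6 points and
collinear clouds; the z-interpolator rejects single planes and
self-intersecting polygons; the Hertz fit refuses curves that never
reach the target depth, and warns on non-monotone post-contact force;
the FE mesh build refuses stripes narrower than the axial spacing and
verifies that no element is degenerate or inverted.
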