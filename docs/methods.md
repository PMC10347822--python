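# Methods

## The quantity and its estimator

Deuterium bound to carbon shifts C–H stretch intensity (~2800–3100 cm⁻¹)
into the C–D stretch region (~2040–2300 cm⁻¹).  Under the assumption that
incorporation is fully reflected in these two bands, the deuterated fraction
of carbon-bound hydrogen is

CD% = A_CD / (A_CH + A_CD) × 100,

with band areas taken as differences of the cumulative (primitive)
trapezoidal integral of the spectrum at integration limits snapped to the
nearest channel of the native axis.  Snapping makes areas reproducible
across axes whose channels do not hit the nominal limits; after snapping,
half-open versus closed window conventions are irrelevant.

Residual baseline is removed with the spectrum's own Raman-silent region:
biological samples have no bands between 2450 and 2650 cm⁻¹, so the level
b = [A_I(2650) − A_I(2450)] / 200 that survives pre-treatment there is
treated as a flat offset under the neighboring bands and subtracted as
b × band width.  This anchors the baseline in the data rather than in the
analyst's judgment.  The correction is exact for flat residuals and is the
reason the pipeline tolerates an imperfect background subtraction of a few
counts.

Pixels whose corrected C-H area is negative, or whose corrected total area
is non-positive, are marked undefined (NaN) and excluded from statistics;
this keeps every defined CD% ≤ 100.  Negative CD% from a negative corrected
C-D area is reported, flagged, and kept — strongly autofluorescent samples
produce exactly this signature in practice.  Values with |CD%| < 1 carry a
low-confidence flag (band-ratio quantification is unreliable below about
one percent) but are not suppressed.

## Integration windows

Literature windows (L-range): C-D 2040–2300, C-H 2800–3100, silent
2450–2650, lignin 1599–1606 cm⁻¹.  Data-derived windows (A-ranges) are
estimated per spectrum as the outermost wavenumbers where the lightly
smoothed intensity exceeds `edge_fraction` (default 0.05) of the band
maximum above the local baseline, averaged over spectra; the edge-fraction
criterion is this package's convention, since "averaging the band ranges of
all samples" admits several edge definitions.  Shipped A-range constants:
roots C-D (2093, 2309) / C-H (2779, 3075); glucose C-D (2033, 2303) /
C-H (2665, 3045).

## Pre-treatment

Order is fixed: cosmic-ray removal → rolling-ball background →
Savitzky–Golay.  Smoothing first would blur spikes into band-like features.

**Cosmic-ray removal** (width 2, dynamic factor 8): a channel is flagged
when it exceeds the median of its ±(2·width) neighbors (itself excluded) by
more than dynamic_factor × σ, where σ is the robust per-spectrum noise
estimate 1.4826 · MAD(first differences) / √2.  Only flagged runs at most
`width` channels wide count as cosmic rays — real bands span many channels —
and are repaired by linear interpolation of unflagged neighbors.  Spectra
with a zero noise estimate are left untouched (no noise, no spike
statistic).  The proprietary filter this emulates documents only the two
parameters; the neighborhood, the MAD estimator and the run-length rule are
declared conventions of this package.

**Rolling-ball background** (shape size 100 cm⁻¹, noise factor 1): 1-D
grayscale morphological opening with a flat structuring element of
round(100 / channel spacing) channels — the standard 1-D equivalence of
rolling a ball under the spectrum.  A median prefilter of width
6 · noise_factor cm⁻¹ suppresses the downward bias the minimum operation
would otherwise pick up from noise; medians cannot extend the support of a
spectral feature, so compact bands are untouched.  The estimate is then
smoothed over one element length.  "Noise factor" is not documented by the
originating software; tying it to the prefilter width is this package's
convention.  The opening never exceeds the signal except through that final
smoothing, which stays within the noise allowance.

**Savitzky–Golay** (order 4, window 11 channels, mirror padding):
reproduces polynomials up to degree 4 exactly, so smooth band shapes pass
through unchanged while white noise variance drops to about a third.

Pre-treatment of an already clean (noise- and background-free) cube is the
identity to within 10⁻⁶ of full scale, and idempotent within 10⁻⁵; the
residual comes from the smoothing filter's finite-order reproduction of the
band shape.

## Segmentation

Spatially resolved route: band-sum images of C-D, C-H and silent windows →
silent-level residual subtraction → Gaussian smoothing (σ = 0.5 px) →
Otsu threshold on the summed C-H + C-D structure image.  The Otsu maximizer
runs on a 256-bin min–max-scaled histogram in exact integer arithmetic
(cross-multiplied Python integers), with ties broken toward the lower
threshold; this makes the threshold bit-reproducible and provably equal to
exhaustive search.

Bulk route: the proprietary endmember analysis it replaces is described as
finding components, averaging member spectra, and de-mixing; the surrogate
here is seeded k-means (k = 2) on L2-normalized spectra, component spectra
as member means, and per-pixel non-negative least-squares de-mixing.  The
component with the larger C-H band area is the root; the labeling is
invariant to component order.  k = 2 (root, void) is the default; whether
the original analysis used more components before discarding non-root ones
is not documented.

## Uncertainty

Two perturbations per band: widening both integration limits by delta_E
(default 10 cm⁻¹) and a flat baseline shift of delta_I (default 1 count —
the scale of the residual CCD-offset mismatch that survives background
subtraction).  ΔA = √(ΔA_limits² + ΔA_baseline²) per band, then Gaussian
propagation through the ratio with ∂CD/∂A_CD = 100·A_CH/(A_CH+A_CD)² and
∂CD/∂A_CH = −100·A_CD/(A_CH+A_CD)².  The magnitude of the limit widening is
not specified by the procedure this follows; both defaults are exposed.
The budget is a worst-case instrument-systematics estimate and is larger
than the run-to-run scatter of the synthetic pipeline.

## Calibration

Measured CD% is regressed on true (prepared) CD% of a deuterated-glucose
standards series (0–40%); applying the model inverts the line.  The
intercept is fitted, not forced through zero, and reported so the choice is
auditable.  Whether the original trend line was fitted as measured-vs-true
or the transpose is unknown; measured-vs-true with inversion is fixed here.

## Lignification

Per-pixel lignin band area (silent-corrected, 1599–1606 cm⁻¹) is regressed
(unweighted OLS, fitted intercept) on the per-pixel C-H area over root
pixels; the slope is the lignification.  Pixels with non-positive corrected
C-H area are excluded and counted.  Both axes scale with laser power and
integration time, so the slope is invariant to global intensity rescaling.
The default maturity threshold is 0.12, with the boundary assigned to
mature-like.

## Registration

Default model is affine (6 dof): both scan stages are close to linear and
~10 landmarks over-determine the fit comfortably; similarity and projective
are available.  Landmarks are (x, y) pixel coordinates of each image — the
transform absorbs the scale difference between a 2 µm Raman raster and a
2048² micrograph, so no metadata pre-scaling occurs.  Warping is bilinear
for intensity/CD% images and nearest for masks (preserving {0, 1});
out-of-footprint pixels are NaN, never 0, so downstream statistics exclude
them.  Linked registration fits one transform on the structure-rich C-H map
and applies the identical coefficients object to every chemical map sharing
its grid.

## Synthetic scenes: what they emulate, and what they do not

Scenes mimic a vibratome-cut root cross-section: Voronoi cell walls inside
an elliptical footprint (walls = root, lumina and exterior = void),
alternatively concentric rings or a full rectangle.  Root pixels carry
window-normalized Gaussian bands: a C-H composite (2895 and 2935 cm⁻¹,
cellulose and lignin contributions), a C-D band at 2170 cm⁻¹, the lignin
aryl band at 1602 cm⁻¹, and fingerprint scenery below 1700 cm⁻¹; the
deuteration fraction f moves area from the C-H to the C-D composite so that
A_CD/(A_CH + A_CD) = f holds exactly in the noise-free limit.  Lignin
weight defaults to 0.1 × the pixel's C-H area, making 0.1 the expected
lignification slope.  Per-pixel total band area varies ±30% around
5000 counts·cm⁻¹ (a glucose droplet standard is set 8× stronger, matching
the sub-0.15% CD uncertainty such standards reach).  Nuisances:
an autofluorescence tail (broad Gaussian, σ = 350 cm⁻¹, centered below the
axis) decaying through the fingerprint region, a gentle linear ramp, a CCD
offset of a few counts, white noise (σ = 3 counts), and Poisson-rate
cosmic-ray spikes of 1–2 channels.

Three deliberate idealizations make the pipeline analytically invertible
and bound what passing tests prove:

* **Band supports are compact.**  Profiles are truncated at 5.3 σ and kept
  narrower than the 100 cm⁻¹ structuring element, so the rolling ball
  passes under them exactly.  Real C-H envelopes are broader and incur a
  percent-level baseline bite that the synthetic scenes do not show.
* **The axis is oversampled** (0.25 cm⁻¹/channel versus ~3 cm⁻¹ on a real
  CCD spectrograph), so the 11-channel smoothing window is effectively
  shape-preserving.  On real sampling the same filter distorts narrow bands
  at the percent level.
* **The autofluorescence is flat beyond ~2000 cm⁻¹.**  Morphological
  opening cannot descend into the "shadow" a band casts on a sloped
  baseline; with background slope under the C-D band the estimator eats
  band area.  The default scene therefore represents a moderately
  fluorescent sample whose background has decayed by the silent region —
  the regime in which the real workflow succeeds.  Strongly sloped or
  intense backgrounds reproduce the known failure mode (negative CD%), and
  can be simulated by raising the background parameters.

Amplitude scales are package conventions (no raw reference spectra are
published); only ratios are anchored.

## Problem sizes and numerical conventions

Test and acceptance runs use 6×8 to 20×30 pixel scenes, 50–100 Monte-Carlo
seeds for calibration/lignification, 500–1000 random histograms for the
Otsu oracle, and 10-landmark registration problems — sizes at which every
stochastic tolerance is comfortably resolved while the whole suite stays in
the low minutes.  All random draws flow from explicit integer seeds through
`numpy.random.default_rng`; k-means uses a fixed `random_state`.  Exact
claims (noise-free inversion, flat-offset cancellation, linked-transform
identity) are asserted at 10⁻⁹ absolute or tighter; stochastic claims at
the tolerances stated in the tests.

## Known limitations

Atom% conversion beyond the glucose line (isotope-ratio mass-spectrometry
comparison) is out of scope, as are peak fitting of C-H/C-D sub-bands,
wavenumber calibration, deformable registration, and reading proprietary
instrument files.  The generator does not model the instrument point-spread
function, polarization, or physically calibrated Raman cross-sections.
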