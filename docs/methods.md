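# Methods

## The measurement problem

Photochromic UV-C indicators (PCIs) are paper-like labels whose coating
changes color with accumulated germicidal (254 nm) dose.  They are cheap,
flat, and flexible, so unlike a radiometer they can be tiled across a
treatment plane or taped to the curved surface of an N95 respirator.  Their
native readout, however, is qualitative.  `pcidose` turns them into
quantitative dosimeters: it calibrates a color-difference metric against
known doses, inverts the calibration to predict unknown doses with a
defensible uncertainty, and assembles point measurements into spatial maps.

All comparisons are *differences* between an exposed indicator and an
unexposed reference measured under the same conditions; differences are far
less sensitive to illumination and instrument drift than absolute colors.

## Color metrics

The primary metric is CIEDE2000 ΔE, implemented in full (lightness, chroma
and hue weighting functions plus the blue-region rotation term, parametric
factors kL = kC = kH = 1 — the universal defaults of the published
definition).  The implementation reproduces the ten published
sample/reference validation pairs to four decimals and agrees with
scikit-image's independent implementation to 1e-9.

Also provided: the CIELAB 1976 Euclidean ΔC, Euclidean RGB ΔC, signed
component differences ΔR/ΔG/ΔB and ΔL\*/ΔC\*/ΔH\*, and per-channel
colorimetric absorbance −γ·log10(I/I0) (base-10 logarithm, the standard
absorbance convention; γ defaults to 1).  The metric hue difference uses
the CIE 1976 form ΔH\* = s·√(2(C\*_E C\*_R − a\*_E a\*_R − b\*_E b\*_R)) with
sign s = +1 when a\*_R b\*_E > a\*_E b\*_R and −1 otherwise; it is computed
through the algebraically equivalent, better-conditioned radicand
Δa² + Δb² − ΔC² (clamped at zero), which makes the Pythagorean
decomposition ΔL² + ΔC² + ΔH² = ΔC²_CIELAB exact at coincident colors.

Lab values carry an illuminant/observer tag (spectrocolorimeters report
D65/10°); differences across mismatched tags are refused rather than
silently adapted.  Lab↔sRGB conversion is delegated to scikit-image under
D65; out-of-gamut conversions are clipped to [0, 1] and flagged.

## Calibration model

Color change saturates with dose.  Two empirical forms are fitted,
motivated by first- and second-order kinetics of the color-forming
reaction:

    first order:   ΔE(d) = a(1 − e^(−d/b))            asymptote a
    second order:  ΔE(d) = ½ a² b d / (1 + a b d)      asymptote a/2

Doses are mJ/cm² internally (the dimensionally consistent unit for the
first-order dose scale b; J/cm² is accepted at I/O boundaries and converted
×1000).  Fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective with positivity
bounds, parameter tolerance 1e-10, ≤10 000 evaluations) with a
deterministic, scale-aware start: amplitude from the observed maximum ΔE
(doubled for the second-order form) and the dose scale from the dose
nearest half-amplitude.  The fit returns the parameter covariance from the
Jacobian, residual degrees of freedom ν = n − 2, SSE and R² = 1 − SSE/SST.
Datasets need at least 4 points over at least 3 distinct doses; an all-zero
response is rejected as degenerate.  Candidate fits are ranked by SSE
(stable sort, declaration order breaks ties).

The measurement noise s_ΔE — the standard deviation of replicate ΔE
readings of unexposed indicators, 0.273 ΔE for the first indicator model
studied and 0.083 for the second — is *not* used to weight the fit; it
enters only the inverse-prediction uncertainty, mirroring how the
measurement procedure was characterized.

## Inverse dose prediction and uncertainty

The unknown dose is the algebraic inverse of the fitted curve,
d(ΔE) = −b·ln(1 − ΔE/a) or d(ΔE) = ΔE/(½a²b − abΔE).  Its standard
uncertainty comes from the delta method,

    u²_dose = (∂d/∂a)² s²_a + (∂d/∂b)² s²_b + (∂d/∂ΔE)² s²_ΔE
              + 2 (∂d/∂a)(∂d/∂b) s_ab,

with analytic partials of the inverse function (validated against central
finite differences to 1e-6 relative and against 10⁵-draw Monte-Carlo
propagation to within 5%).  Confidence intervals are
d ± u_dose·t(1−α/2, ν) with α = 0.05 by default.  "Relative CI width" is
the full width divided by the dose; "relative uncertainty" is half of
that.  Simulated 95% intervals cover the true dose at ≈95% (mildly
conservative, 95–97% over 500 seeded repetitions).

The partials diverge at the asymptote, so inversion is refused above a
guard fraction of the asymptote (default 0.98, configurable) and estimates
above a warning fraction (default 0.90) carry a `near_saturation` flag.

Replicate exposures are equalized by multiplying each estimate — dose, CI
bounds and standard uncertainty alike — by target_dose/logged_dose (an
exact multiplicative rescaling, so relative CI widths are unchanged).
Replicate scatter then combines with the calibration uncertainty by root
sum of squares, u_total = √(u²_dose + u²_rep), with u_rep the sample SD
(ddof = 1) of the replicates.  Relative doses d_meas/d_ref propagate as
u_norm = |d_norm|·√((u_meas/d_meas)² + (u_ref/d_ref)²).

## Image readout

Device images (flatbed scanner, DSLR, phone) arrive as converted
linear-light or sRGB-encoded TIFF/PNG; raw demosaicing is out of scope.
Regions of interest are axis-aligned rectangles in 0-based pixel
coordinates with half-open bounds, supplied through an annotation CSV — a
file-based substitute for interactive selection, chosen for
reproducibility.  Images are white-balance/exposure corrected first (each
linear channel is divided by the white-region mean and rescaled so white
maps to the neutral gray 0.9 — a target that preserves headroom; the
operation is idempotent), then region means are taken in linear light and
converted to Lab.  Correcting before averaging is a documented assumption.
Both per-image references (camera workflow) and shared references (scanner
workflow, one white/unexposed/saturated region for all swatches) are
supported.  Pantone-match regions are carried but never used.

Per-pixel dose maps pass every pixel's ΔE against the unexposed reference
through the inverse fit; pixels at or above the saturation guard are
flagged NaN, never clipped.

## Radiometer logs

Dose is Σ I·Δt (left-Riemann over the logged intervals, trapezoidal
optional): 1 mW/cm² for 1 s is 1 mJ/cm².  Lamp shutoff is the first sample
that drops from its predecessor by more than 50% (configurable) of the
maximum recorded irradiance — the global maximum rather than a running
maximum, because warm-up traces start near zero and early noise would
otherwise mimic a shutoff; analysis windows stop two samples before the
detected index.  Warm-up rise time is the 10%→90% crossing interval of the
maximum recorded irradiance with linear interpolation (for an exponential
rise it equals τ·ln 9).  Output degradation is a linear least-squares
slope, fitted over the second half of the trimmed log in the summary
report so warm-up does not bias it.  Snapshot time-to-dose estimates
divide the target dose by the mean irradiance in the 10th–20th logger
iterations (1-based, matching data-logger conventions) and in the last 11
iterations before shutoff; their disagreement quantifies the error of
extrapolating a single snapshot reading.

## Attenuators

A filter of transmittance T rescales the dose axis:
ΔE_filtered(d) = ΔE(T·d), i.e. b → b/T (first order) or b → b·T (second
order), with the covariance transformed by the same Jacobian.
Transmittance is measured as the ratio of peak irradiance through the
filter to the open-beam peak; OD = −log10 T.  The dynamic-range extension
factor is the ratio of characteristic dose scales (b for first order,
1/(ab) for second).  "Quantifiable range extension" is operationalized by
ΔE-matching: the filtered dose whose predicted ΔE equals the unfiltered
prediction at a stated unfiltered limit.  This convention is deterministic
and needs no covariance; the uncertainty-based definition (<10% relative
uncertainty) is available through the ordinary CI machinery when a real
fit covariance exists.  Filter solarization, angular response and
inter-filter variability are not modelled physically; they can only enter
as user-supplied transmittance uncertainty.

## Spatial mapping

Maps hold labelled locations (mm coordinates, origin at the treatment-plane
lower left, 63.5 mm default grid pitch) with per-location replicate
estimates, optional multiplicative correction factors (consumed, never
derived — e.g. radiometer angular-response corrections), and a reference
label for relative maps.  On-respirator locations are label-identified
(apex, side, …) rather than coordinate-mapped.  Unmeasured locations are
explicit and excluded from summaries.  The uniformity summary reports the
min/max ratio, a corner-to-center ratio (locations nearest the bounding-box
corners vs the location nearest the centroid), and a dose histogram; all
are invariant under global rescaling.  Heatmaps use the perceptually
uniform `inferno` colormap; rendering is cosmetic, CSV values are the
contract.

## Synthetic fixtures

The generator module defines the study conditions for every test:

* **Calibration tables** — first-order truth a = 47.1 ΔE, b = 80.4 mJ/cm²,
  ΔE noise SD 0.273, 8 doses evenly spanning 0–250 mJ/cm² × 3 replicates
  (24 points).  These mirror a realistic single-session indicator
  calibration: the dose span covers the indicator's usable range and the
  noise is the replicate-measured s_ΔE.
* **Swatch images** — colors interpolate in Lab from unexposed yellow
  Lab(85, 5, 60) to saturated pink Lab(55, 45, 5), a fixed arbitrary pair
  whose full swing has CIEDE2000 magnitude (~49) comparable to a real
  indicator's ~45 span.  Because CIEDE2000 is nonlinear along the path,
  the default mode solves the path position whose ΔE from the unexposed
  endpoint equals the kinetic target exactly (`exact_delta_e=True`);
  the raw extent-interpolation mode is also available and follows the
  kinetics only approximately.  Frames carry a white card, device channel
  gains (with exposure normalization so nothing clips) and Gaussian pixel
  noise.
* **Irradiance logs** — (I_max + slope·t)(1 − e^(−t/τ)) plus noise, with a
  near-zero tail for shutoff; defaults (17 mW/cm², τ = 30 s, −0.002
  mW/cm²/s, 1 Hz) emulate a low-pressure lamp enclosure.
* **Spatial fields** — radial falloff
  dose(r) = center·(1 − (1 − f_corner)(r/r_corner)²) so the corner-to-center
  ratio equals the parameter exactly (default 0.4, the kind of falloff a
  box enclosure exhibits).

All randomness flows through `numpy.random.default_rng(seed)` (PCG64); a
fixed seed reproduces outputs byte-identically.

What synthetic fixtures do *not* emulate: real indicator chemistry
(temperature/humidity dependence, post-exposure color instability),
device spectral sensitivities, specular reflections and dust in images,
respirator self-shadowing geometry, and radiometer angular response.
Passing the synthetic end-to-end tests therefore demonstrates the
correctness of the computational pipeline, not the field performance of
any particular indicator product; claims that depend on physical
measurements (accuracy vs a calibrated radiometer, on-respirator dose
disparity) can only be echoed here as synthetic analogues.

## Problem sizes

Simulation-based checks use sizes chosen to make the statistics stable at
interactive cost: 200 seeded refits for the relative-uncertainty summary,
500 for CI coverage, 10⁵ Monte-Carlo draws for the delta-method
comparison, 64×64 swatch images, and 100-seed batches for detection
properties.

## Known limitations

* Reaction parameters (true rate constants) are not extractable from the
  calibration fits; the forms are calibration conveniences.
* The covariance between fitted a and b is taken from the local Jacobian;
  strongly saturated or sparse designs can make it optimistic.
* Equalization assumes dose–response linearity under exposure rescaling of
  each replicate, exact only within the calibrated range.
* The uncertainty-based dynamic-range definition requires a real fit
  covariance; with the ΔE-matching convention the extension factor for
  second-order fits depends on both a and b.
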