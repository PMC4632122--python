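# Methods

## Histogram bimodality as an image-contrast currency

The package treats "contrast" between two pixel populations (e.g. a fresh
and a water-stressed leaf in one frame) as a property of the image
histogram. A scalar index image is histogrammed over its valid pixels and
fitted, by bounded least squares, with a two-member Gaussian model

    f(x) = a1·exp(−((x−b1)/c1)²) + a2·exp(−((x−b2)/c2)²).

The width parameter of each component relates to the standard deviation
of the corresponding normal density by σ = c/√2. The two fitted modes are
compared with the Bhattacharyya distance for univariate normals,

    D_B = ¼ (b1−b2)²/(σ1²+σ2²) + ½ ln[(σ1²+σ2²)/(2σ1σ2)],

whose exponential C_B = exp(−D_B) is the Bhattacharyya overlap
coefficient (1 for identical modes, → 0 for disjoint ones). The identity
exp(−D_B) = ∫√(p·q) dx for normal densities is verified in the test suite
against adaptive numerical integration to 1e−6. Contrast classes follow
the D_B guideline bands: below 0.6 the histogram structure is noise-like
("poor"), above 1.0 the modes are usefully separated ("moderate"), above
3.0 strongly separated ("strong"). The guideline leaves (0.6, 1.0]
unassigned, so this implementation reports it explicitly as
"indeterminate" rather than forcing a side.

### Numerical choices

* **Binning.** Default bin count is the square-root rule √n clipped to
  [16, 256], where n is the number of valid pixels. A fixed fine binning
  makes small-image fits bin-noise dominated (tens of counts per bin are
  needed for a meaningful R²); the rule keeps the expected count per bin
  ≈ √n. Any explicit bin count is honored unchanged.
* **Range.** Default histogram range is the robust [0.5th, 99.5th]
  percentile window of the valid pixels; ratio images otherwise inherit
  long division tails that dominate the binning. Excluded pixels are
  counted and reported, never silently dropped.
* **Fit initialization and bounds.** The histogram is split at its
  median-of-mass bin; each half seeds one component (a = its max count,
  b = its centroid, c = √2 × its std). Bounds: heights in [0, 2·max
  count], centers within the histogram range, widths between half a bin
  and the full range width. Unweighted least squares on the binned curve
  (not a sample likelihood) with an analytic Jacobian; non-convergence is
  reported through a `converged` flag and never silently accepted.
* **R² filter.** Fits with R² < 0.9 (about the mean-count baseline) are
  flagged unusable. Published fits of this kind report R² > 0.96 on
  large images; 0.9 leaves margin for noisier, smaller synthetic frames.
* **Degenerate-fit guard.** An unsupervised least-squares fit of a
  mono-modal histogram will happily park its second component on a noise
  wiggle, producing a narrow pseudo-mode with an arbitrarily large D_B.
  Screening that was originally done by eye therefore needs an explicit
  false-positive control: a fit whose minor component carries less than
  10% of the total fitted area is declared *effectively unimodal* and
  excluded from rankings (with its reason recorded). The 10% floor was
  calibrated on the identical-leaves null scene, where genuine two-leaf
  fits carry ≈ 49% in the minor mode and all spurious high-D_B fits carry
  under 10%; it encodes the assumption that a real leaf population
  occupies at least a tenth of the masked pixels.
* **Constant images.** A single-spike histogram (e.g. the ratio of a band
  with itself) cannot define mode separation; it yields D_B = 0, class
  poor, flagged unusable, rather than an error.

## Index search

`search_indices` evaluates the full ordered band-pair grid (numerator ≠
denominator, both orientations — ratio images are not symmetric) at a
configurable stride, scoring each ratio image with the pipeline above and
ranking accepted candidates by descending D_B with deterministic
tie-breaks (lower numerator, then lower denominator wavelength). Excluded
candidates are retained with their exclusion reason, so the output is
always a complete accounting of the grid. The default stride of 4 keeps a
512-band search near 16k fits; the end-to-end checks in this repository
use stride 8 (≈ 4k fits, under a minute) on 64×64×512 scenes.

The contrast-space module provides the complementary intensity-ratio
screening: Simple Ratio (I1/I2), Weber ((I1−I2)/I2) and Michelson
((I1−I2)/(I1+I2)) contrasts of a single ROI's mean intensity at every
ordered band pair — a B×B matrix (262,144 entries at 512 bands).
Which region feeds these ROI formulas is genuinely open; the default uses
one ROI spanning the scene at two wavelengths (matching how the selected
pairs are printed, as wavelength ratios), and a two-ROI per-band variant
(`two_roi_contrast`, leaf A vs leaf B at one wavelength) is exposed
alongside it.

## Segmentation

Once a fit is strongly bimodal, the default threshold is the equal-density
point of the two fitted component curves — the interior root of
a1·exp(−((x−b1)/c1)²) = a2·exp(−((x−b2)/c2)²) between the centers, found
by bracketed root-finding on the log-difference; it minimizes
misassignment under the fitted model when the modes have unequal widths.
The midpoint of the centers and a manual threshold are alternatives, and
the midpoint is the fallback when no interior intersection exists.
Degenerate fits (non-converged, or centers closer than one pooled sigma)
are refused with a diagnostic. Pixels exactly at the threshold count as
"below", so keep-below and keep-above masks partition the valid pixels
exactly.

## Synthetic scene model

No leaf datacubes were deposited with the original experiments, so the
generator is the package's reference data source, built to reproduce the
statistical structure the analysis assumes rather than leaf anatomy:

    I(x, y, λ) = L(λ) · g(x, y) · exp(−[w·ε_w(λ) + ε_0(λ)]·d(x, y)·ρ(x, y))

* **Water absorptivity ε_w:** Gaussian bands at 975, 1200 and 1470 nm
  with peak optical depths 0.4/0.7/2.0 per unit thickness at full
  hydration (widths 30/35 nm). The dominant 1470 nm band is asymmetric —
  55 nm width on the short-wavelength side, 35 nm on the long side — so
  absorption is strong through 1390–1430 nm but largely recovered by
  1500–1590 nm, the steep long-wave recovery seen in leaf drying
  difference spectra. `w` is the leaf's water level, a unitless RWC/100
  proxy in [0, 1]; mapping to absolute water mass is not attempted.
* **Dry-matter baseline ε_0:** slowly varying, 0.60 → 0.75 across
  800–1600 nm.
* **Geometry d:** each leaf is a rotated ellipse whose thickness is a
  smooth dome (parabolic taper of 5% to the rim) with a narrow midrib
  ridge (+5%), times a smooth random roughness field ρ (CV 2.5%,
  ~2-pixel correlation). Smoothness matters: plateau- or shelf-like
  thickness profiles would imprint spurious sub-modes on every per-leaf
  histogram, which real leaf images do not show.
* **Scatter field g:** a lognormal, spatially correlated,
  wavelength-independent transmission heterogeneity (CV 25%) standing in
  for vein/mesophyll structural variability. This term is what makes the
  whole exercise non-trivial: it broadens every single-band histogram
  (the spatial variability that defeats single-band imaging) yet cancels
  exactly in any per-pixel band ratio — the physical reason ratio indices
  dominate the search.
* **Sensor noise:** multiplicative Gaussian, CV 1.5% (shot-like, per
  sample), plus additive Gaussian of 10 counts against a ~10⁴-count
  halogen-like source; negative counts clip to zero. The shot-noise
  floor is what differentiates candidate ratios — pairs with little
  differential water absorption are noise-limited — so the search
  concentrates on numerators in low-absorption windows divided by
  denominators on the 1470 nm band.
* **Determinism:** one seeded generator with a documented draw order
  (per leaf: scatter then roughness; then multiplicative, then additive
  noise). A fixed seed fixes the cube bit for bit.

The standard two-leaf scene places mirror-symmetric leaves (so
equal-water leaves are exactly exchangeable populations) with water
levels 1.0 vs 0.8, the ~20% RWC gap between recently detached and
naturally dried leaves.

### What passing tests on this generator do and do not show

The generator reproduces the *mechanism* — common-mode spatial
variability plus band-localized differential absorption — under which
histogram-bimodality search discovers water-band ratios. Passing tests
show the analytics are correct and that the discovery pipeline behaves
as published *under that mechanism*: ratio indices strong, single bands
and broadband poor, traditional indices intermediate, nothing discovered
on equally watered leaves. They do not validate the radiative transfer
of real leaves: there is no scattering phase function or PROSPECT-style
plate model, no specular or reflection geometry, no chlorophyll/VIS
range, no within-leaf water gradients (heterogeneity is thickness- and
scatter-driven only), and absolute D_B values on real cubes will differ
with leaf anatomy, optics and camera noise.

## Other reference computations

Relative water content is RWC = 100·(W − DW)/(TW − DW) from sample,
turgid and dry weights; sample weights slightly above turgid weight (wet
surfaces) warn rather than error. Transmittance/reflectance are ratios
of transmitted/reflected to incident power; replicate spectra average
elementwise. "Absorption" from transmission and reflection is the energy
balance A = 1 − T − R (clipped to [0, 1]) by default, with the
Beer–Lambert log form −ln T exposed separately as `log_absorbance` —
both are in circulation and the energy-balance reading is the package's
documented default.

## Interchange formats and conventions

Cubes are (rows, cols, bands), 0-based, pixel (0, 0) top-left; the
default spectral axis is 800 + 1.56k nm for k = 0…511 (the last center
at 1597.16 nm — the grid is step-exact rather than endpoint-inclusive;
literature wavelengths just past the last center, such as MSI's 1599 nm
reference, resolve to the edge band through an explicit widened
tolerance). ENVI I/O reads BSQ/BIL/BIP with the standard text header
(`samples`, `lines`, `bands`, `data type`, `interleave`, `wavelength`)
and writes float32 little-endian BSQ, with the light-reference spectrum
carried in a commented header extension; a NumPy `.npz` container stores
the full-precision array, axis and reference for lossless round-trips.
Wavelength-to-band mapping is nearest-center with ties to the lower
index. On-disk integer types are promoted to floats in memory;
normalization to the light source always produces reals and is recorded
in a `normalized` flag.

## Known limitations

* Two-component fits only; more than two pixel populations (overlapping
  leaves, backgrounds, specular patches) must be masked out upstream.
* The fit optimizes the binned curve, so very small masks (≲ 300 px)
  give unstable R² and are usually rejected by the validity filter.
* D_B classifications are guideline bands, not calibrated error rates.
* The generator's leaves do not overlap by construction; occlusion
  handling is out of scope.
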