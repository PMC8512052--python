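# Methods

This note documents the models, conventions and design choices behind
`pwus`, in the order of the processing chain.

## Coordinate and time conventions

Lateral `x` (mm, positive right) and axial `z` (mm, depth) span the
imaging plane; the array elements lie on `z = 0`, centred on the origin,
with uniform spacing equal to the pitch. Angles are stored in radians
(degrees at the CLI). Time zero is the instant the tilted plane
wavefront passes the array centre, so the transmit path to a pixel
`(x, z)` is `z·cosθ + x·sinθ` — the standard plane-wave-compounding
convention. All rasters are indexed `[z][x]`.

## Channel-data simulation

Each scatterer contributes, per angle and element, a windowed tone burst
arriving at `t = (z·cosθ + x·sinθ)/c + √((x−x_e)² + z²)/c`, scaled by
its reflectivity and 1/r receive spreading (plane-wave transmit carries
no spreading). Echoes superpose linearly; optional i.i.d. Gaussian noise
and 12-bit-style quantization follow. Two waveform choices matter:

* **Burst shape.** The default is a Hann-windowed cosine burst
  (`burst_cycles` = 3 by default, a typical imaging excitation); a
  hard-switched square burst, as driven by a tri-state pulser, is
  available via `burst_shape="square"`. The windowed burst avoids the
  harmonic-rich PSFs a square burst produces in a noise-free synthetic
  setting.
* **Arrival-time registration.** The burst is *centred* on the
  geometric arrival time (support ±Tb/2). With an onset-aligned burst
  the envelope peak would lag the geometric delay by half the burst
  duration and DAS peaks would be biased axially by c·Tb/4 (≈ 0.39 mm
  at 3 cycles/3 MHz); centring makes peak localization unbiased, which
  the localization tests exploit.

Elements are point-like on receive (no directivity model). For the
monochromatic transmit-field maps, each element is subdivided into 4
point sources across its active width (sub-wavelength spacing at 3 MHz),
which reproduces the element-size directivity that partially suppresses
grating lobes.

## Beamforming

Per angle, every pixel sums linearly interpolated channel samples at the
round-trip delay; out-of-record times contribute zero. Receive
apodization is off by default (optional Hann window and f-number-limited
aperture). Compounding is **coherent**: the mean of per-angle RF images
before envelope detection, which is what gives compounding its
synthetic-transmit-focusing effect.

Two adaptive pixel weights are provided, applied per angle before
compounding (a post-compounding variant is a one-line change through the
same functions):

* **Coherence factor**: `CF = |Σ_e s_e|² / (N·Σ_e s_e²)` ∈ [0, 1],
  defined as 0 for an all-zero aperture. For i.i.d. zero-mean noise its
  expectation is 1/N, which the tests verify by Monte Carlo.
* **Aperture-statistics (STD) weight**: `w = |µ| / (|µ| + σ + ε)` with
  µ, σ the mean and population standard deviation of the delayed
  aperture samples and `ε = 1e−12·max|s|`. The published variants of
  statistics-based weighting differ in detail; this form is the
  simplest monotone weight bounded in [0, 1] that preserves coherent
  signal and suppresses incoherent clutter, and it measurably narrows
  the lateral PSF relative to plain DAS (433 → 327 µm at 10 mm in the
  default configuration, recomputed by the test suite).

Envelope detection is the magnitude of the axial analytic signal
(Hilbert transform); log compression maps to `[−DR, 0]` dB relative to
the image maximum. The fan mask marks pixels inside the wedge bounded by
rays from the aperture edges tilted outward by the maximum steering
angle.

## Image-quality metrics

All metrics consume *linear* envelope values, before log compression;
the contrast ratio applies the logarithm itself. Standard deviations are
population (ddof = 0) throughout, which makes small closed-form examples
exact. FWHM locates the two half-maximum crossings nearest the peak by
linear interpolation between bracketing samples; a plateau at the
maximum resolves to its midpoint, and a truncated peak raises a distinct
`PeakTruncatedError`. The depth-SNR profile flags σ = 0 depths as +inf.
CNR supports both the variance-sum (default) and variance-difference
denominators, since both conventions appear in practice; the difference
mode refuses σ_bck ≤ σ_lesion.

The resolution studies beamform a local grid around the wire (25 µm
lateral spacing near, 40 µm deep, both ≤ 50 µm) whose lateral half-width
scales with depth so the whole mainlobe is captured.

## Synthetic phantoms

* **Wire phantom**: unit-reflectivity points at the requested depths
  (the classic 1–10 cm ladder by default at the CLI).
* **Lesion phantom**: Poisson-count uniform scatterers with
  Rayleigh-distributed reflectivities, scaled inside the lesion disk by
  the amplitude ratio (0 = anechoic). Density 4/mm² in the contrast
  study gives on the order of one scatterer per resolution cell — dense
  enough for the contrast trend, though not fully developed speckle.
* **Bladder scenes** are synthesized directly in image space so
  segmentation experiments stay cheap (the RF route remains available
  for small rasters). Background texture is spatially correlated
  Rayleigh speckle (complex Gaussian field blurred to ≈ 3 px grain,
  normalized to unit mean). The bladder is an ellipse whose semi-axes
  grow affinely with the fill level; its envelope is scaled by a
  contrast factor (default 0.15, ≈ −16 dB) and a near-field haze band
  (default clutter level 0.2) is added inside the upper part of the
  bladder. Scenario "partial" centres the ellipse on a fan border,
  "confounder" darkens an extra wedge excluded from the ground truth.
  Rendering is 50 dB log compression to 8-bit; the ground truth is
  (ellipse ∩ fan). Defaults were chosen so the classical threshold
  baseline succeeds on central scenes but fails on confounder scenes,
  mirroring the qualitative failure modes of real abdominal imaging.

What the synthetic scenes do **not** model: anatomical layering, bladder
wall echoes, attenuation/TGC, probe-contact artifacts, inter-patient
texture variability. Passing segmentation tests therefore demonstrate
that the training/evaluation machinery works and that the network can
learn fan-aware shape-from-darkness — not clinical performance on
proband images, whose intensity statistics are unpublished.

## Segmentation

The U-Net uses the channel plan `first·2^k` (6→96 at the bottleneck for
the reference configuration), 3×3 convolutions with ReLU, 2×2 max
pooling, and a decoder of factor-2 bilinear up-sampling followed by
convolution, skip concatenation and a double-convolution block; a 1×1
head yields 2 class scores. It is implemented in NumPy with exact
gradients (finite-difference-verified) and Adam. Loss is unweighted
pixelwise cross-entropy. Training stops at the epoch cap or when the
loss plateaus (relative improvement < 1e−4 over 20 epochs).

Preprocessing maps native 1056×720 rasters to 528×352×1: channel
averaging, bilinear resize to 528×360, then a centre crop of 4 rows top
and bottom (since 720/2 = 360 ≠ 352 an explicit convention is needed).

The fan-aware augmentation produces exactly 20 variants: five geometric
states — identity, each fan side rotated about the apex onto the
corresponding image border (with the accompanying translation), and the
two half-way alignments — times four flip states. Masks and fan rasters
are warped with nearest-neighbour sampling by the same transform, so
mask ⊆ fan is preserved exactly. The five-variant decomposition is an
engineering choice to realize the 20-fold expansion; other
decompositions would serve equally.

Desk-scale defaults for the training study: 200 training / 20 held-out
central-scenario scenes at 64×96 px, depth-3 network (6-12-24 channels),
batch 4, Adam at 1e−3, 15 epochs — about a minute on one CPU, reaching
median held-out IoU ≈ 0.93. The reference full-size configuration
(depth 5, 528×352, learning rate 2e−5, ≤ 400 epochs) is reached purely
through `UNetConfig`.

A deterministic classical baseline (Otsu dark-region threshold inside
the fan, morphological opening, largest component beyond a near-field
margin of 12 % of the fan height) makes the evaluation machinery
testable without training and serves as the reference the learned model
must beat on the hard scenarios.

## Evaluation

`seg_fractions` is exact integer pixel counting: missing fraction
|GT∧¬Pred|/|GT|, false fraction |Pred∧¬GT|/|GT| (may exceed 1), IoU.
Evaluation restricts to the fan-valid region when a fan mask is given.
Cohort summaries use the even-count median convention (mean of the two
central values) and fixed-width histograms over [0, max]. Polygon ground
truth is filled from a generic JSON point list; rasters are thresholded
at mid-range.

## Persistence

The frame container is HDF5 with a documented layout (root attributes
`format`, `schema_version`, `kind`; `payload/` and `meta/` groups) —
self-describing, versioned, and carrying enough metadata that
re-beamforming a stored channel-data frame with its embedded parameters
reproduces the stored B-mode bit-identically (the reconstruction is pure
deterministic NumPy). Foreign/corrupt files and newer schema versions
raise distinct errors.

## Degenerate inputs and numerical choices

Empty scatterer fields produce silent records; all-zero images refuse
log compression; empty ROIs, empty ground truth and σ-degenerate SNR
depths are signaled explicitly rather than returning NaN. Delay lookup
uses linear interpolation (error O(dt²) in the sample spacing);
reconstruction grids are regular with spacing range/(count−1). All
randomness flows from explicit seeds (`numpy.random.default_rng`);
seeded simulation, scene synthesis and training are bit-reproducible
within one platform.

## Known limitations

Two-dimensional in-plane physics only (elevation is metadata); no
attenuation, dispersion or nonlinearity; no element directivity on
receive; the COH/STD weights are representative forms of their families
rather than re-implementations of any specific published variant; the
bladder generator is a statistical surrogate, not an anatomical model;
and the NumPy U-Net is intended for small/medium rasters, not
production-scale training.
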