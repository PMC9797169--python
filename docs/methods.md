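# Methods

## Scope and model overview

The package quantifies how a parameterized noise-reduction algorithm
reshapes detector noise in portable chest radiography, using only
second-order image statistics: ROI standard deviations on repeat-subtraction
(noise-only) images, line-profile edge metrics, and noise power spectra
(NPS). All analyses run identically on real DICOM/TIFF acquisitions and on
the package's synthetic radiographs; the synthetic path is what the tests
and the acceptance script exercise.

## Noise model

A radiograph is a deterministic scene plus zero-mean Gaussian noise with
signal-dependent variance:

    Var[x] = gain · mean + electronic_sd²

`gain` (detector units) plays the role of the quantum-noise coefficient —
Gaussian rather than true Poisson, which is immaterial here because every
analysis uses only means and (co)variances and detector units are
arbitrary. Signal scales linearly with mAs through a reference station
(exposure reciprocity), so halving dose halves both mean and variance.

Two optional correlation terms act on the quantum component only:

* `blur_sigma` (px): pre-sampling Gaussian blur.
* `sharpen_amount`/`sharpen_sigma`: an unsharp mask `q + a·(q − G_σs(q))`
  standing in for the detail-enhancement stage of a clinical processing
  chain. With it the noise transfer is
  `H(f) = (1 + a·(1 − e^{−2π²σs²f²}))·e^{−2π²σb²f²}`, giving the measured
  NPS the mid-band peak characteristic of clinically processed
  radiographs. The study defaults (`a = 0.8, σs = 1.5, σb = 0.7`) place the
  peak at ≈ 0.29 of Nyquist with ≈ 1.5× prominence over the low-frequency
  level; `a` was chosen from this closed form so that the spectral peak is
  displaced by every default denoiser setting, including the weakest
  (filter F at the highest dose station), while remaining clearly interior.
  Both terms default to 0, in which case the variance identity above is
  exact (the calibration tests use that configuration).

Both members of a repeated pair draw from distinct `SeedSequence` substreams
of the user seed: independent, yet bit-reproducible.

## Synthetic chest scene

The chest scene is a flat map of detector signal levels — background soft
tissue 1000, lungs 2800 (most transmissive), ribs 1600 where they cross the
lung fields, liver 700 — composed of two lung ellipses, four rib bands and
a liver rectangle on a 512² grid, smoothed with a Gaussian of `edge_blur`
= 2 px. Level ordering (lung > rib, lung > liver) is enforced. The
noiseless scene is retrievable separately (`render_chest_scene`) for oracle
tests. The geometry is schematic: it provides plateaus, edges and a
realistic density range, not anatomy; rib bands are wide enough (20 px)
that a profile from lung into a rib sees one plateau-to-plateau edge.

## Surrogate denoiser

The image is decomposed into four octave Gaussian band-pass bands
(σ = 1, 2, 4, 8 px) plus a low-pass residual — an exact decomposition.
Band k is multiplied by `1 − s_k·g` with

    s_k = clip(enhancement · w_k(balance) · d(filter, r) · ρ(density, v), 0, 1)

* `d(C, ·) = 1`; `d(F, r) = min(2, r^−0.5)` with `r = mAs/mAs_ref`, so F
  suppression strictly increases as dose falls (α = 0.5, cap 2 give visible
  but bounded adaptivity over the ~3× clinical mAs range).
* `w(G)` is uniform; A/C/E are low/mid/high-frequency weighted vectors.
* `ρ(A, ·) = 1`; `ρ(B, v)` ramps linearly from 1 to 0.2 as the local mean
  `v` (a σ = 32 px smoothed image) rises from the reference density (image
  median) to 1.5× it; `ρ(C, v)` mirrors below. The ramps are one-sided and
  equal to 1 *at* the reference, so on a uniform phantom all three density
  types coincide to within ~0.01 detector units — reproducing the observed
  redundancy of density options on flat-field images — while on the chest
  scene B protects the bright lung side and C the dark liver side.
* `g = exp(−(|∇|/τ)⁴)` is the edge gate, with `τ = 5 × median` of the
  smoothed gradient magnitude: gradients at the noise floor pass (g ≈ 1,
  full smoothing), resolved edges several times the floor are protected
  (g → 0). On a noiseless image the median gradient is ~0, so any edge is
  protected and the half-maximum crossing of a step moves < 0.5 px even at
  enhancement 0.9.

`enhancement = 0` short-circuits to a bit-identical copy. The surrogate
makes no attempt at the directional (structure-following) smoothing the
real algorithm may use; it reproduces behaviors, not the filter.

## NPS estimation

Per ROI: detrend (least-squares plane by default; mean-subtraction retained
for exact Parseval checks), no taper window, then
`pitch²/(N·N)·|DFT₂|²`, averaged over the ten circle ROIs and halved when
the input is a repeat subtraction (differencing doubles noise power; the
flag makes the convention auditable). Frequency axes are DC-centered in
cycles/mm. The integral `Σ NPS·Δu·Δv` equals the mean detrended ROI
variance — exactly for mean detrending, to < 1% for plane detrending.

Radial averaging assigns each off-DC bin to the radial bin of its frequency
magnitude (bin width = ROI frequency resolution, 0.052 cycles/mm at the
defaults); empty bins are NaN, never zero. The peak frequency is the argmax
after a 3-bin moving average, ties toward lower frequency. ROI centers are
rounded to integer pixels to avoid interpolating noise statistics. The
high-frequency texture index integrates the texture NPS above half Nyquist
by default.

### Estimator variance and how "flat" is tested

A periodogram bin of Gaussian noise is exponentially distributed (100%
relative SD); a radial bin at radius index j pools ≈ 2πj bins × 10 ROIs ÷ 2
(Hermitian pairs), so single-bin levels carry 4–30% noise by construction.
Flatness of the white-noise NPS is therefore asserted on the profile mean
(≲ 0.4% estimator noise), on five count-weighted coarse frequency bands
(each ≲ 2%), and on a known-variance weighted regression slope — not on
individual fine bins, which no correct estimator could hold to 5%.
Similarly, the linear-filter transfer check compares processed and
unprocessed spectra of the *same* realization per fine radial bin (the
stochastic periodogram factor cancels), and the texture-NPS closed form
|1−H|²·σ²·pitch² is checked where it is within a decade of its maximum —
toward DC it falls like f⁴ beneath the rectangular-window leakage floor of
the high-pass texture field.

## Study configuration

Defaults mirror the clinical acquisition grids: chest at 0.7/1.0/1.4/1.8/2.2
mAs (reference 1.4 mAs, the station with deviation index DI = 0 for the
synthetic exposure index EI ∝ mAs with target 625); solid water 10 cm at
0.32–0.8 mAs (reference 0.4) and 20 cm at 0.9–3.6 mAs (reference 1.8). The
20 cm arm transmits less per mAs, so its reference sits ~4× higher in mAs at
the same detector signal (2000 units at reference) — which is why its dose
grid is ~4× the 10 cm grid. Settings default to the six surviving unique
codes (C/F × densities A/B/C at enhancement 0.5, balance G) plus the
baseline; the full parameter grid is available by listing codes explicitly.

Solid-water images are 768² (the smallest comfortable size for the
600 + 128 px ROI geometry); chest images 512². These sizes keep the full
default sweep — both experiments, all doses and settings — under a minute
on one CPU while leaving every ordering far outside sampling noise.

Pixel-identity of settings ("no pixel value difference") is judged at a
quantization step of 1 detector unit — one grey level of the 16-bit output
representation at unit scaling: two settings are one class when their
outputs differ by at most half a step everywhere. Classes are the
transitive closure of the pairwise relation; in practice within-class
differences (~0.01 units) and between-class differences (~tens of units)
are so separated that the closure is the pairwise relation.

## What the synthetic study shows — and what it cannot

With the defaults, the study reproduces the qualitative structure expected
of a dose-adaptive multi-band denoiser: reductions grow as dose falls for
filter F (constant for C); the repeat-subtraction NPS peak moves below the
baseline peak for every setting; stronger settings leave larger
high-frequency texture indices, with the dose-adaptive density-constant
default exceeding the density-limited C-filter variant at low dose; and
density options collapse into equivalence classes on uniform phantoms while
separating on the chest scene. Absolute numbers — reduction percentages,
NPS scales, texture indices — are properties of the surrogate and the
synthetic noise chain, *not* of the proprietary vendor algorithm or any
physical detector, and are not comparable to measurements. Passing tests
demonstrate the correctness of the measurement pipeline and the internal
consistency of the surrogate's parameter semantics, nothing about any
specific commercial implementation.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviation for ROI statistics.
* ROI coordinates 0-based, row-major, half-open; geometry in pixels,
  converted to mm only in outputs (pixel pitch default 0.15 mm).
* Line profiles: bilinear interpolation, width-averaged over an odd number
  of unit-spaced perpendicular offsets; positions in mm from the start.
* Rise distance: plateau levels are the 10th/90th percentiles of the pooled
  first and last sample quartiles; crossings by linear interpolation; a
  plateau span below 5× the plateau noise SD raises a no-edge error rather
  than returning a meaningless width. The metric is invariant to intensity
  offset and positive rescaling.
* Whether repeat-subtraction ROI SDs are √2-corrected does not affect
  reduction percentages (the factor cancels in the ratio); SDs are reported
  uncorrected, the NPS path applies its factor 2 explicitly.
* All-zero spectra have no peak (error), constant images are fixed points
  of the denoiser, and undersized images for the ROI circle raise a
  geometry error naming the required minimum (728 px at the defaults).

## Known limitations

No scatter or anti-scatter-grid emulation, no detector MTF/DQE physics
beyond the blur term, no bone-edge enhancement, no normalized NPS, no MTF
estimation, no automatic anatomical ROI placement. The deviation index uses
a synthetic EI strictly proportional to mAs; real exposure indices saturate
and depend on segmentation.
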