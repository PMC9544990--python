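# Methods

`ctqa` implements an objective, task-based image-quality chain for CT on
synthetic phantom images: phantom simulation, noise power spectrum (NPS),
circular-edge task transfer function (TTF), non-prewhitening-with-eye-filter
(NPWE) detectability, and dose matching between reconstruction presets.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data can and cannot show.

## Phantom and acquisition model

The simulated object is a 20-cm water-equivalent cylinder (0 HU, air at
−1000 HU outside) with circular inserts; the standard configuration places
a 25-mm polyethylene insert (−95 HU) and a 25-mm air insert (−1000 HU) at
±45 mm. Truth images are rendered on a 512-pixel grid with 250 mm field of
view (0.488 mm pixels) using 4× sub-pixel area weighting, so pixels
straddling a disc edge take partial-volume values and insert means are
exact to well under 0.1 HU.

A reconstruction preset is modelled as

* a Gaussian in-plane PSF of width `psf_sigma` (mm), applied to the truth,
  whose modulation transfer is `exp(-2 pi^2 sigma^2 f^2)`;
* stationary correlated noise added after the blur, with radial power
  spectrum `S(f) ∝ f exp(-f / f_peak)` (white when `f_peak = 0`), peaking
  at `f_peak` cyc/mm;
* a per-slice noise SD of
  `reference_noise_sd * sqrt(reference_dose / dose) * noise_scale`,
  the quantum-limited inverse-square-root dose law.

Noise fields are synthesized by frequency-domain colouring of white
Gaussian noise on a 2× oversized grid, centre-cropped to suppress periodic
boundary correlation, then demeaned and rescaled so the sample SD equals
the target exactly. All randomness derives from a single plan seed through
`numpy.random.SeedSequence` keyed on (preset, dose, phantom section), so
every stack is reproducible and stacks of different sections are
independent.

The default study emulates a five-dose chest protocol — CTDIvol 9.5, 7.5,
6, 2.5 and 0.4 mGy, five acquisitions per dose, 50 slices per acquisition
for NPS (250 pooled) and 30 for TTF (150 pooled composite) — with a
reference noise SD of 10 HU at 9.5 mGy and three presets spanning the
smooth-to-sharp trade-off:

| preset    | psf_sigma (mm) | noise_scale | f_peak (cyc/mm) |
|-----------|----------------|-------------|------------------|
| smoother  | 1.1            | 0.45        | 0.15             |
| reference | 0.8            | 1.00        | 0.25             |
| sharper   | 0.6            | 1.60        | 0.40             |

The reference preset stands in for the clinical-routine hybrid-IR
reconstruction against which the others are compared; the smoother/sharper
presets bracket it the way smooth and sharp deep-learning reconstruction
levels bracket their standard setting (less noise and coarser texture on
one side, more noise and finer texture on the other).

**What the generator does not emulate.** No projection/sinogram physics,
beam hardening, or anthropomorphic anatomy. Blur is linear and
noise-independent, so the contrast- and dose-dependent resolution of
iterative and learning-based reconstructions is *not* reproduced: in this
simulator TTF50 is essentially flat in dose, and any dose dependence of a
measured TTF enters only through the CNR-gated ESF conditioning. Slice
noise is independent in z (no overlap correlation). Passing tests therefore
validate the estimators and their wiring, not scanner-specific behaviour.

## Noise power spectrum

Four 128×128 ROIs per slice, at (±35, ±35) mm so they stay inside the
uniform section, pooled across acquisitions (1000 ROIs in the default
study). Each ROI is detrended by subtracting a least-squares plane —
removes low-frequency shading without eating texture — and

    NPS(u, v) = (dx dy / (Nx Ny)) * <|DFT2(roi)|^2>    [HU^2 mm^2].

The radial profile averages the 2-D NPS over annuli one DFT bin wide
(half-open bins, zero-frequency bin excluded). Summary metrics:
`noise_magnitude = sqrt(∫∫ NPS du dv)` (equal to the detrended ROI SD by
Parseval), the spectral centroid `f_av = Σ f·NPS1D / Σ NPS1D` computed on
the raw profile, and `f_peak` from the argmax of an 11th-order polynomial
fitted to the profile (on a normalized abscissa for conditioning; the fit
is descriptive and never feeds the detectability computation). Plane
removal slightly depresses the first radial bin (~8%); this is visible in
the white-noise flatness check but negligible for band-pass spectra, whose
first-bin power is small.

## Circular-edge TTF

The composite image is the pixel-wise mean of the pooled slices (150 by
default), reducing noise by √n. The insert centre is found to sub-pixel
accuracy by an intensity-weighted centroid of above-half-contrast pixels,
refined once. Pixels in the annulus 0.5–2 insert radii contribute
(distance − R, HU) to radial bins of 0.1 pixel; empty bins are filled by
linear interpolation. Contrast is the interior mean (edge ring of
max(2 px, 0.15 R) excluded, so PSF tails do not leak in) minus the mean of
the outer half-annulus, and `CNR_total` divides its magnitude by the
background SD of the composite.

When `CNR_total < 15` the ESF is conditioned to a monotone profile before
differentiation. Conditioning is a monotone rearrangement: the binned
values are sorted along the contrast direction. This is parameter-free,
exactly monotone, preserves the value histogram and hence the plateau
levels (bias well under the bin noise), and empirically tracks the
noiseless edge to < 2 HU RMS at gate-level noise. A running-extremum pass
was rejected because its plateau follows the maximum noise excursion
(≈ sigma·sqrt(2 ln n_bins) ≈ 3 HU at realistic bin noise).

The LSF is the first difference of the ESF at bin midpoints (a one-bin
edge stays a one-bin LSF; the attenuation of a first difference at 0.0488
mm spacing is < 0.1% over the measured band). A Hann window suppresses the
tails: it is centred on the ESF half-contrast crossing with full width 8×
the estimated LSF FWHM, where the FWHM comes from the interquartile ESF
rise (× 2.355/1.349, the Gaussian ratio). Anchoring the window on the raw
derivative peak is unusable here: on 0.1-pixel bins the derivative of even
a conditioned noisy ESF is spiky and the window collapses. TTF is the
magnitude of the zero-padded DFT of the windowed LSF, normalized at zero
frequency; TTF50 is the first downward 0.5 crossing, linearly
interpolated. On a Gaussian-blurred insert the chain recovers
`exp(-2 pi^2 sigma^2 f^2)` to ~0.01 max-abs and TTF50 to ~1% (the residual
positive bias is the circular-edge curvature term, O((sigma/R)^2)).

## NPWE detectability

Tasks are "designer" lesions: flat core of radius R(1−t), raised-cosine
edge to R(1+t), with t = 0.1 by default (t = 0 is reserved for analytic
oracles). The three chest tasks are 5-mm lesions of 50 HU (low-contrast
nodule, LCN), 200 HU (ground-glass opacity, GGO) and 950 HU (high-contrast
pulmonary lesion, HCP); contrast magnitudes are used since d′ is
sign-invariant. Task functions live on a fixed 300 × 300 grid of 0.05 mm
pixels (Δf = 1/15 cyc/mm, Nyquist 10 cyc/mm), with
`W = |DFT2(profile)| · dx·dy` approximating the continuous transform.

    d'^2 = [ΣΣ W^2 TTF^2 E^2 Δu Δv]^2 / ΣΣ W^2 TTF^2 NPS E^4 Δu Δv

Measured TTF and raw (unfitted) radial NPS are interpolated onto the task
grid assuming radial symmetry, with flat extrapolation beyond the measured
band (conservative: the task spectrum beyond the image Nyquist is tiny).
The eye filter is `E(rho) = rho^1.3 exp(-0.325 rho)` in cycles/degree,
normalized to unit peak (at 1.3/0.325 = 4 cyc/deg, a standard
visual-response peak), with `rho = f · (distance/zoom) · pi/180`; the
default display is zoom 1.5 at 500 mm. Both exponent and decay are
configuration values, and `viewing=None` gives the plain NPW observer.
LCN and GGO are paired with the polyethylene-insert TTF and HCP with the
air-insert TTF, matching low/medium-contrast tasks to the low-contrast
edge and the high-contrast task to the high-contrast edge; the pairing is
recorded in each result's provenance hash.

## Preset comparison and dose matching

Two presets are compared by the per-dose relative differences
`100·(value − reference)/reference`, summarized as mean ± population SD
over the five dose levels. Dose-reduction potential fits `d' = a·dose^b`
by least squares in log-log space (under the white-noise dose law the
exponent is exactly 0.5, a useful oracle), evaluates the reference
preset's fitted d′ at the 10 mGy matching dose — above the highest
measured dose, so the evaluation is an extrapolation and is flagged as
such — and solves the other preset's curve for the matched dose
`(d'_ref/a)^(1/b)`. The reduction `100·(matched/10 − 1)` is reported at
full precision and rounded to integer percent with ties to even, the
convention consistent with every reported matched-dose/percentage pair
this package cross-checks.

## Numerical choices and degenerate inputs

* ROI detrending uses the orthogonality of {1, x, y} on a full grid, so the
  plane fit is exact and fast.
* Radial NPS bins are half-open `[kΔf, (k+1)Δf)` with mid-bin centres;
  annuli beyond the axis Nyquist (square-grid corners) are kept — their
  annular mean is unbiased for a radially symmetric spectrum.
* Zero background SD makes CNR_total infinite → conditioning never fires.
* A flat ESF, an all-zero NPS, a non-increasing d′–dose curve, and a
  reference of 0 in a relative difference raise explicit errors rather
  than returning NaNs.
* DICOM output stores HU as unsigned 16-bit with rescale intercept −1024
  (≤ 0.5 HU quantization); the raster writer is lossless float32.

## Problem sizes

Default tests and the acceptance script run the study at the full design
size (5 doses × 3 presets, 250 NPS slices and 150 TTF slices per point,
512² pixels), which completes in a few minutes; unit tests use smaller
grids (128²) and slice counts chosen to keep each check seconds-scale
while preserving the property under test.

## Known limitations

* The simulator cannot exhibit contrast- or dose-dependent resolution, so
  dose-matching numbers from synthetic presets characterize the pipeline,
  not any scanner or reconstruction product.
* Monotone-rearrangement conditioning assumes the underlying edge is
  monotone across the whole annulus; a non-monotone artefact (e.g. edge
  overshoot from sharp reconstruction kernels) would be sorted away.
* The NPWE model adds no internal observer noise; d′ values are therefore
  upper bounds relative to human observers and are meaningful mainly in
  ratios across presets and doses.
* Noise stationarity is assumed everywhere; no non-stationarity maps are
  produced.
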