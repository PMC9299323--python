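# Methods

## Scope and model

`ctqa` evaluates 2-D CT slices in Hounsfield units, one slice at a time,
given a binary mask of a reference organ (contrast-enhanced liver is the
intended setting; segmentation itself is out of scope — masks are
inputs).  Slices whose mask area is not strictly greater than 100 cm²
are excluded, as are slices whose mask vanishes under erosion or whose
SCF is constant ("unpartitionable"); every exclusion is reported with
its reason so that included + excluded always equals the input count.

The structure coherence feature (SCF) at a pixel is the ratio of summed
edginess to summed directional entropies over the window centred there
(window ∩ mask).  Definitions and conventions:

* Gradients are central differences with edge replication, divided by
  the per-axis pixel spacing (HU/mm).  Anisotropic spacing is supported;
  nothing is ever measured in raw pixels.
* The structure tensor uses pointwise products by default
  (`tensor_smooth_sigma_px = 0`).  Pointwise tensors are rank one, so
  `λ₁ = |∇I|²` identically and the ω₂ term scales with the *square* of
  contrast while the ω₁ term is linear — the default edginess is
  deliberately contrast-inhomogeneous, and λ₁ dominates at clinically
  typical noise levels.  A Gaussian smoothing option is provided for
  full-rank tensors.
* The first eigenpair comes from the 2×2 closed form
  `λ₁ = ((t11+t22)+D)/2`, `v₁ ∝ (2·t12, t22−t11+D)` with
  `D = √((t11−t22)² + 4·t12²)`, which satisfies `T·v₁ = λ₁·v₁`
  (verified against a numeric eigensolver to 1e−10).  When `t12 = 0`
  the formula degenerates and the axis-aligned eigenvector is taken.
* Directional entropies use natural log, 8 equal-width unweighted bins,
  gradient angles on [−π, π), eigenvector orientations on [0, π) (an
  eigenvector's sign is arbitrary).  Zero-magnitude pixels have no
  defined angle and are excluded; a window empty after exclusion has
  entropy 0 by convention.  `entropy_floor = 1e−6` guards the division
  for perfectly coherent windows.
* SCF offset invariance — SCF(I+b) = SCF(I) — is exact whenever the
  addition I+b is itself exact in floating point (integer-valued HU
  images with integer shifts, the realistic CT case); for arbitrary
  float offsets it holds to rounding error of the shifted input.

## Parameters

| key | default | meaning |
|---|---|---|
| scf.window_px | 9 | SCF window side (≈ 6 mm at 0.7 mm spacing) |
| scf.omega1 / omega2 | 1 / 1 | edginess weights of |∇I| and λ₁ |
| scf.n_angle_bins | 8 | orientation histogram bins |
| partition.low_pct / high_pct | 10 / 70 | R_H / R_S percentile cuts |
| partition.erosion_px | 7 | mask erosion element (square or disk) |
| noise.roi_size_px | 21 | noise ROI side, shrinks by 2 down to 5 if R_H cannot host it |
| noise.n_rois | 5 | ROIs averaged per slice |
| ssi.coef_a / coef_b | 6.1398 / 4.2813 | SSI→edge-slope calibration |

Percentiles use linear interpolation between order statistics and are
computed per slice inside the eroded mask only.  Ties at a cut value are
included in the region; when the two cuts coincide (constant SCF) all
pixels go to R_H, R_S is empty and the slice is flagged.  Noise ROIs are
drawn without replacement from all centres whose full square fits inside
R_H, may overlap (logged), and use sample SDs (N−1), as does the SAI.
The SSI calibration defaults are scanner- and protocol-specific; fitting
`fit_ssi_calibration` on one's own edge-slope measurements is the
supported path.

The SAI partition is computed once, from the reference reconstruction,
and reused on the difference image.  The edge-slope reference samples
profiles by bilinear interpolation every quarter pixel spacing (finer
than the grid so that sub-2-pixel edges keep ≥ 4 samples inside the
10–90 % clip), with profile origins every 1 mm and half-length 5 mm.
The 10 %/90 % thresholds are taken relative to a baseline estimated as
the mean of the first quartile of samples, not to the raw maximum — a
raw-percent-of-max rule breaks down when the tissue floor is far above
0 HU.

## The synthetic phantom

The generator renders an elliptical parenchyma (100 HU) on a −50 HU
background with circular and tubular vessels at +100 HU contrast,
applies Gaussian edge blur and/or unsharp sharpening to the noiseless
scene, then adds seeded Gaussian noise (optionally correlated by a
Gaussian kernel, renormalized to the requested SD).  Blur precedes noise
so the edge-blur parameter controls structure sharpness without
attenuating noise; the paired stand-in "reconstructions" (structure-
sparing, uniform, blurring denoisers) model algorithms that affect both.
In the sharpness ladders the unsharp branch keeps the base's intrinsic
0.8-px edge blur, since sharpening physically acts on an already
band-limited reconstruction.

What the phantom does *not* emulate: anatomical parenchyma texture,
streak or stationary-correlated CT noise beyond the simple correlation
knob, beam hardening, and sinogram-domain effects.  Passing tests
therefore demonstrate the internal consistency and orderings of the
metrics, not clinical accuracy.

## Known limitations

* **The automated noise level is a biased, strongly linear surrogate.**
  R_H is the bottom decile of the SCF; on homogeneous tissue the SCF is
  driven by the local gradient energy of the *same* noise realization
  being measured, so SD estimates conditioned on "calmest" regions read
  low — on the flat phantom by roughly a fifth, uniformly across
  σ ∈ {5…40} HU (the selection is scale-equivariant, so correlation with
  the true σ stays above 0.99).  This matches the behaviour of the
  method on patients, where automated readings sit systematically below
  manual ROIs placed by an observer.  Comparisons *between*
  reconstructions of the same anatomy, the intended use, are unaffected
  by a common scale factor.  On textured real parenchyma the selection
  is driven largely by anatomy rather than by the noise itself, so the
  flat phantom is the worst case for this bias.
* SAI ≈ 1 holds for difference fields independent of the reference
  noise; when ΔI is proportional to the reference's own noise (a
  perfectly uniform denoiser) the same selection effect inflates SAI
  slightly above 1.  The structure-sparing and blurring stand-ins
  bracket it from below and above.
* The SSI is a relative index: its raw scale depends on window size,
  weights and pixel spacing, and the default calibration to HU/mm does
  not transfer across protocols without refitting.
* No noise-power-spectrum or noise-texture analysis is performed.
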