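# ctqa — automated CT image-quality metrics

`ctqa` scores CT reconstructions per slice with three quantitative
image-quality metrics — **noise level**, **structure sharpness index
(SSI)** and **structure alteration index (SAI)** — computed fully
automatically from the image and an organ mask, with no manual ROI
placement.  It is aimed at medical physicists and imaging researchers
comparing reconstruction or denoising algorithms (FBP vs iterative
reconstruction vs deep-learning denoisers) on patient scans, where manual
ROI drawing does not scale.

## Method

Everything rests on the per-pixel **structure coherence feature (SCF)**.
For a square window W centred on a pixel inside the organ mask,

```
SCF = Σ_{(i,j)∈W} I_E(i,j) / (H_G + H_T)
I_E = ω₁·|∇I| + ω₂·|λ₁|
```

where `∇I` is the image gradient (HU/mm), `λ₁` the first eigenvalue of the
structure tensor `T = [Ix², IxIy; IxIy, Iy²]`, and `H_G`, `H_T` are the
Shannon entropies of the orientation histograms of the gradient vectors
(on [−π, π)) and of the tensor's first eigenvectors (on [0, π)).  A
coherent anatomical edge produces strong, aligned gradients (large
numerator, small entropies); homogeneous tissue or unstructured noise
produces weak or randomly oriented gradients.  High SCF therefore marks
structure.

After eroding the organ mask (7-pixel element) the SCF distribution is
cut at two percentiles:

* **R_H** (≤ 10th percentile): homogeneous region. Five randomly placed
  square ROIs inside it give the **noise level** = mean of their HU
  standard deviations.
* **R_S** (≥ 70th percentile): structure-edge region. The mean SCF over
  it is the **SSI**; a linear calibration (`ξ = 6.1398·SSI + 4.2813` by
  default, refittable with `fit_ssi_calibration`) maps it to a physical
  edge slope in HU/mm.
* For a co-registered reconstruction pair, the **SAI** is
  `σ_RS(ΔI) / σ_RH(ΔI)` on the difference image ΔI = reference − target:
  ≈ 1 for spatially uniform noise removal, > 1 when the target smears
  structure into the difference, < 1 for conservative, structure-sparing
  denoising.

The reference sharpness measure the SSI is validated against is also
included: perpendicular line profiles along a drawn edge polyline,
clipped to the 10–90 % intensity rise, each fitted by the OLS slope
`ξ_l = cov[s_l, I_l]/var[s_l]`, plus Pearson / Bland–Altman agreement
statistics.  A fully parameterized synthetic liver-slice phantom
(elliptical parenchyma ≈ 100 HU, vessels +100 HU, tunable edge blur,
unsharp sharpening and noise) makes every metric testable without any
patient data.

## Worked example

```python
import ctqa

bundle = ctqa.generate_phantom(ctqa.PhantomSpec(noise_sigma_hu=15.0, seed=42))
target = ctqa.apply_denoiser(bundle, "ideal", strength=0.6)
report = ctqa.evaluate_slices([bundle.image], [bundle.organ_mask], targets=[target])
row = report.rows[0]
print(f"noise level : {row.noise_hu:.2f} HU")
print(f"SSI raw     : {row.ssi_raw:.1f}")
print(f"SAI         : {row.sai:.3f}")
```

prints

```
noise level : 12.87 HU
SSI raw     : 17439.3
SAI         : 0.865
```

The measured noise (12.87 HU for a true σ of 15 HU) sits below the truth:
R_H is by construction the *calmest* decile of the organ, so the
automated reading is a scaled-down, strongly correlated surrogate of the
true noise — the same systematic offset the manual-vs-automated
comparison of this method shows on patients.  The SAI of 0.865 < 1
identifies the target as a structure-sparing denoiser; a blurring
denoiser on the same slice scores ≈ 1.6.

The same pipeline is available from the shell:

```
ctqa make-fixtures --n-slices 3 --seed 5 --out fx/
ctqa evaluate --images fx/images --masks fx/masks --out report.csv
ctqa compare  --reference fx/images --target denoised/ --masks fx/masks --out cmp.csv
ctqa validate --seed 1 --out validation.json
```

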