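# Methods

## Model overview

`endospec` implements a three-part pipeline for RGB endoscopic frames:

1. **Colorimetric calibration + spectral reconstruction.** The camera
   is treated as an sRGB device whose scene white (the endoscope lamp)
   differs from the white under which a reference color checker was
   measured. Per pixel: sRGB decode → Bradford chromatic adaptation
   (via the sRGB primary matrices) → degree-≤3 polynomial expansion of
   linear RGB (20 monomials, fixed documented order) → linear map to
   the coefficients of a mean-centered PCA basis of a spectral library
   → re-synthesis of the reflectance spectrum on the 380–780 nm grid.
2. **IPCL segmentation.** Grayscale (luma 0.299/0.587/0.114) →
   min–max contrast stretch to [0, 255] → Otsu binarization →
   inversion → Guo–Hall two-subiteration thinning → 8-connected
   component labeling with a minimum-size filter → seeded sampling of
   up to 1000 skeleton coordinates.
3. **Triangle-region staging.** Scores on the first two principal
   components; per stage, the maximum-area triangle over training
   scores; membership by the area-sum identity with a relative
   tolerance; severity-descending test order; one-vs-rest sensitivity
   and specificity.

## Assumptions

- Reflectance spectra of mucosa are smooth and low-dimensional, so a
  small PCA basis (k = 6 by default) spans them; the estimator cannot
  represent spectra outside that span.
- The camera is linear up to the sRGB transfer function, and its
  color processing is stable between the checker exposure and the
  tissue exposure. Exposure/vignetting correction is out of scope.
- Three camera channels cannot determine more than three independent
  coefficients; components beyond the third are predicted only insofar
  as they correlate with the first three over the calibration set.
  This is visible in the per-component training residuals and is an
  inherent limit of RGB-based reconstruction, not a fitting defect.
- Vessels are darker than mucosa in NBI, which is why the binarized
  image is inverted before thinning.

## Parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| wavelength grid | 380–780 nm, 5 nm step (81 samples) | nm | visible range; configurable |
| basis dimension k | 6 | – | smooth visible reflectances are classically low-dimensional |
| polynomial degree | 3 (20 features) | – | standard camera-characterization expansion |
| chromatic adaptation | Bradford | – | field standard for camera characterization |
| output clip band | [0, 1.2] | reflectance | values above 1 flag calibration failure; clip events are counted, not hidden |
| Otsu binarization | – | – | a fixed 0.5 level fails on dim NBI fields; the choice is recorded in output metadata |
| min component size | 5 | px | suppresses salt noise in the skeleton |
| coordinate budget | 1000 | points | per-image spectral sampling budget |
| membership tolerance | 1e-9 (relative) | – | floating-point replacement for the exact area-sum equality |
| test order | V3-SCC, V1-SCC, V1-HGD, IV | – | severity-descending; configurable |

## Synthetic study conditions

The fixture module emulates what the pipeline needs and nothing more:

- **Tissue spectra** are smooth Gaussian-bump mixtures with a
  severity-scaled amplitude, ±3 % per-draw amplitude jitter and i.i.d.
  noise σ = 0.01, clipped to [0, 1]. White-light class means decrease
  strictly with severity; Lugol means increase; the four NBI IPCL
  classes differ in both amplitude and the weights of the ~415/~540 nm
  bands, so they separate in PC-score space.
- **Scenes** are a class spectrum modulated by smooth ±5 % shading,
  with (for NBI) 5–20 dark curvilinear strokes of width 1–3 px drawn
  by seeded momentum random walks and recorded in a ground-truth
  vessel mask. An `n_strokes` argument controls vessel density when a
  denser field is needed (e.g. skeletons larger than the coordinate
  budget).
- **Camera**: Gaussian spectral sensitivities peaking at 455/540/615 nm
  with σ = 20 nm under a flat (xenon-like) illuminant, exposure-
  normalized so a perfect reflector renders (255, 255, 255); a
  Planckian "daylight" illuminant is available so chromatic adaptation
  is exercised with genuinely different whites. Narrow, well-separated
  bands keep the channel→coefficient map well conditioned.
- **Color-matching functions** are the Wyman–Sloan–Shirley analytic
  multi-lobe Gaussian fit of the CIE 1931 2° observer — accurate to a
  few parts per thousand, ample for synthetic-camera colorimetry.

What the fixtures do **not** model: lesion texture, specular
highlights, mucus, motion blur, NBI's proprietary color reproduction,
or any photometric property of real endoscopes. Passing tests
demonstrate the correctness of the algorithms under the stated model,
not clinical performance.

## Numerical choices

- **Exact-recovery studies** use an exactly affine rank-3 spectral
  family (fixed base + three bounded smooth modes, never clipped) and
  a k = 3 basis: with three camera channels the RGB→coefficient map is
  inside the polynomial model class only when the spectral family is
  at most three-dimensional. Under the continuous (quantization-free)
  render the round-trip error is at machine precision; 8-bit
  quantization alone contributes ≈ 2 × 10⁻³ reflectance RMSE and is
  reported separately as a diagnostic.
- **PCA sign convention**: each component is flipped so its
  largest-magnitude element is positive, making serialized bases
  reproducible across library orderings.
- **Least squares** via `numpy.linalg.lstsq`; designs whose expansion
  is rank-deficient (duplicate patches) are rejected with an explicit
  error rather than silently regularized.
- **Contrast stretch rounding** is half-up at the 8-bit boundary only;
  internal arithmetic is floating point. A constant image (zero
  dynamic range) is rejected.
- **Area-sum membership**: the printed form of the boundary condition
  reads as "edge of or outside", which contradicts the strict-outside
  inequality; the only consistent reading — boundary inclusive,
  equality within a relative tolerance means *inside* — is
  implemented.
- **Max-area triangle**: the maximizer's vertices always lie on the
  convex hull, so the exhaustive search is restricted to hull vertices
  (exact); ties are broken by the lexicographically smallest sorted
  vertex tuple. Manually chosen peripheral vertices can be supplied
  instead.
- **Patient-level scores** are the mean of per-pixel scores; by
  linearity this equals the score of the mean spectrum, and both are
  computed and cross-checked at 1e-10 on every call. For NBI the
  default is to score the IPCL-sampled pixels rather than the whole
  frame; both paths are supported.
- **Determinism**: every stochastic step takes an explicit seed; no
  output format embeds timestamps (scene sidecars are plain `.npy`
  rather than zipped archives for exactly this reason), so seeded
  re-runs are byte-identical.

## Problem sizes

The shipped studies run at desk scale: 192–256 px scenes, 30–100
checker patches, 500 points per class for classifier recovery, 50
random blobs for thinning properties, three scenes per segmentation
measurement. These sizes give the geometry and recovery checks
comfortable statistical margins while keeping the full suite fast.

## Known limitations

- Reconstruction fidelity beyond three effective spectral degrees of
  freedom depends entirely on correlations learned from the
  calibration set; the per-component residuals quantify this.
- 8-bit quantization bounds per-pixel spectral accuracy at roughly the
  10⁻³ reflectance level regardless of calibration quality.
- The thinning-based detector finds dark curvilinear structures; it
  does not grade IPCL morphology (Inoue subtype scoring from shape is
  out of scope).
- Triangle regions are convex by construction; a class whose score
  cloud is non-convex or multi-modal will be under-covered, and points
  outside every region are reported as undetected rather than
  force-assigned.
- Clinical score ranges and cohort sensitivities/specificities cannot
  be reproduced without the original patient images; any reference
  ranges can be loaded as metadata only and are never hard-coded.
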