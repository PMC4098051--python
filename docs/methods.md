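# Methods

## Problem and pipeline

`pneumotex` implements a computer-aided detection scheme for diffuse lung
texture of the pneumoconiosis type, operating on small square regions of
interest (ROIs) cut from the lung fields of digitised chest radiographs:
32 × 32 pixels at 0.175 mm/pixel on a 12-bit-like intensity scale. The task
is binary: does an ROI show normal parenchymal texture, or the small rounded
(p/q/r) or irregular (s/t) opacities of pneumoconiosis at some profusion
subcategory (1/1, 2/2, 3/3)?

The pipeline is:

1. **Trend correction** — least-squares fit and subtraction of a
   second-order polynomial surface f(x,y) = c₀₀ + c₁₀x + c₀₁y + c₂₀x² +
   c₁₁xy + c₀₂y², removing gross anatomy gradients (lung vs chest wall).
2. **Enhancement**, three parallel branches:
   - *Radial window function* (Hanning, Hamming or Blackman), evaluated at
     the Euclidean radius n = √(x²+y²) from the ROI centre and multiplied
     into the image, suppressing the spectral-leakage lines that the ROI
     edge otherwise puts on the u and v frequency axes.
   - *Top-hat transform*: image minus its grayscale opening with a flat
     square structuring element (13–25 px), keeping bright structures
     smaller than the element (nodules, irregular opacities) and removing
     larger ones (large vessels).
   - *Co-occurrence feature image*: the 2^bits × 2^bits joint probability
     matrix of gray-level pairs at displacement d along the 45°/225°
     diagonal of the 6-bit-quantized ROI. The probability matrix itself is
     treated as an image.
3. **Power spectrum**: squared magnitude of the unnormalized 2-D DFT,
   centred. Along every quantized radial direction through the centre the
   spectrum is sampled at integer radii 1 … N/2 (nearest lattice point);
   the two directions with the highest aggregate energy are the *main* and
   *second* axes. Their profiles are concatenated and divided by the pair
   maximum, giving per-branch feature vectors of 32 (image-domain branches)
   or 64 (co-occurrence branch) values in [0, 1]; window ‖ top-hat ‖ glcom
   concatenate to the 128-value combined vector.
4. **Classification**: a rule stage using the main-axis values at radial
   bins 1 and 2 (0.179 and 0.357 cycles/mm — nodular-pattern frequencies)
   declares ROIs "obviously" abnormal (either bin above the training-normal
   maximum) or "obviously" normal (both bins below the training-abnormal
   minimum); per-branch decisions are OR-fused with abnormal precedence.
   Undecided ROIs are scored by a three-layer perceptron (sigmoid hidden
   and output units) trained on squared error against targets 0.1 (normal)
   and 0.9 (abnormal). Architectures follow the input width: 32-17-1,
   64-33-1, 128-65-1. Rule-forced decisions score 1.0 / 0.0 so ROC ranks
   them extremal.
5. **Evaluation**: ten independent class-stratified random halvings into
   training/test sets (odd counts send the extra ROI to training,
   e.g. 117 → 59/58). All methods share each split's halves, licensing a
   two-tailed paired t-test on the per-split AUCs. ROC curves are averaged
   vertically (mean TPR on an FPR grid of 0, 0.01, …, 1) and the reported
   spread is the SD across splits.

## Synthetic data

The generator stands in for the standard-radiograph ROI library, which is
not redistributable. A normal ROI is polynomial trend + correlated Gaussian
noise (white noise smoothed with a Gaussian kernel, renormalised to the
target SD — so the per-ROI noise SD is exact by construction) + a Poisson
number of vessel-like ridges (Gaussian cross-section). An abnormal ROI adds
a Poisson number of opacities: isotropic Gaussian blobs with FWHM drawn
from the ILO diameter range of the size class (p ≤ 1.5 mm, q 1.5–3 mm,
r 3–10 mm) for rounded classes, short random-walk strokes (3–10 px long,
1–2 px wide) for irregular classes. Every ROI has its own RNG stream
derived from (master seed, id), so datasets are reproducible and
order-independent; opacities draw from a separate substream so a
zero-density override reproduces the normal background bit for bit.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| roi_size / pixel_mm | 32 px / 0.175 mm | the scheme's native ROI geometry |
| trend_coeffs | (2048, 8, −5, 0.4, 0.15, −0.25) | a gentle 12-bit-scale anatomy gradient |
| noise_sd | 30 | parenchymal granularity, a few percent of signal |
| noise_correlation_px | 1.2 | film/detector blur scale |
| opacity density (1/1, 2/2, 3/3) | 3, 7, 14 per ROI | ordered to mimic profusion |
| contrast | 2.5 × noise SD | a conspicuous but noise-embedded opacity; calibrated so the classes are separable in the nodular-frequency bins while single-feature discrimination stays far from perfect |
| ridge_rate / amplitude / FWHM | 1.5 / 1.5 × SD / 20 px | large-vessel scale (~3.5 mm): wide enough that opening with the default structuring elements suppresses most of it, which is the premise of the top-hat branch |

What the generator does *not* emulate: radiographic physics (scatter, heel
effect), rib shadows and other periodic anatomy, inter-patient exposure
variation, and the full-field context around an ROI. Passing tests
therefore show that the pipeline's stages behave as specified and that the
method ordering reproduces on texture with the assumed statistical
structure — not that clinical AUC levels are reproduced. Absolute AUCs on
this synthetic family (≈0.70–0.75 at the default scale) are a property of
the generator's difficulty setting, not a clinical estimate.

## Numerical choices

- **Surface fit**: centred pixel coordinates condition the design matrix;
  solved by `numpy.linalg.lstsq` and verified against an explicit
  normal-equations solve to 1e-8. Fitting is over all pixels (no mask).
- **Window clamping**: the radial index exceeds (N−1)/2 in the ROI
  corners; it is clamped there so the cosine terms cannot wrap into
  negative weights. Weights therefore lie in [0, 1].
- **Morphology**: flat square structuring element, borders by edge
  replication (`scipy.ndimage.grey_opening`, mode `nearest`). Even element
  sizes are rejected (no defined centre).
- **Quantization**: linear min–max per ROI to 0 … 2^bits−1 (constant image
  → 0). Anchoring to the per-ROI range of the trend-corrected image makes
  the co-occurrence branch scale-invariant up to ties at bin edges.
- **Co-occurrence counting** is done in-package with the exact diagonal
  offset (d, d): library implementations that compute the offset as
  round(sin θ · d) collapse d = 2 onto d = 1 at 45°, and the distances
  1–3 px must stay distinct here. Both directions are accumulated, making
  the matrix symmetric; normalisation is to a joint probability (sum 1).
- **FFT convention**: unnormalized forward transform; the Parseval check
  (Σ PS / N² = Σ pixel²) pins the convention.
- **Axis search**: candidate directions are all lines from the centre to
  lattice points on the boundary of the upper half-grid, folded to
  [0°, 180°). Each is scored by the sum over radial bins 1 … N/2 (the DC
  bin is never a feature); ties break toward the smaller angle. The second
  axis needs only a different quantized angle — no minimum separation.
  Note a consequence of nearest-lattice sampling: directions within ~10°
  of an axis sample the same lattice bins at small radii, so a spectrum
  dominated by one very-low-frequency peak yields a second axis nearly
  parallel to the main one. Sampling positions that fall off the grid
  (only the Nyquist column/row for even N) fold to the centrally symmetric
  point, which is exact for real images.
- **Normalization** is by the maximum over the concatenated (main ‖
  second) pair, so the pair shares one scale and the branch maximum is
  exactly 1; an all-zero profile is returned unchanged with a warning.
- **Rules** read the *normalized* main-axis features (bins 1 and 2) for
  consistency with the network inputs. Overlapping classes are legal; the
  rules then fire rarely. Conflicting OR votes resolve abnormal-first to
  minimise false negatives.
- **Network training**: full-batch gradient descent, learning rate 0.05,
  momentum 0.9, 500 epochs, weights initialised uniform(−0.5, 0.5) from a
  seed; deterministic for fixed seed. Hidden width is input//2 + 1. These
  hyperparameters are exposed everywhere.
- **Degenerate t-tests**: identical AUC lists give (t, p) = (0, 1);
  zero-variance nonzero-mean differences report signed infinite t and
  p = 0 with a warning rather than a spurious division.

## Experiment scale

The packaged comparison experiment uses 150 ROIs per class (100 normals
would satisfy the protocol; 150 stabilises the 128-input network, which
sees ~150 training patterns per split) and 10 splits, with master seeds
0–9 for the seed-robustness check. A full run of that check takes on the
order of a minute on one CPU.

## Known limitations

- The rule stage rarely fires on the synthetic family at default contrast
  (normalized bin values saturate similarly across classes), so most of
  the combined method's margin comes from the 128-input network.
- The window branch cannot show its clinical advantage here: synthetic
  ROIs have milder edge discontinuities than patches cut from a full
  radiograph, so leakage suppression removes little class-relevant
  confounding.
- Per-subcategory parameter presets (structuring element 17/21/none,
  displacement 1/2/3) are shipped, but the default experiment uses the
  general preset (one parameter set, combined features) because
  subcategory is unknown at inference time.
- AUC levels depend on generator calibration; only orderings and the
  stage-level contracts are meaningful test outcomes.
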