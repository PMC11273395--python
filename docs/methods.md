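# Methods

This package implements two complementary unsupervised anomaly detectors
for 2-D en face OCT-angiography (OCTA) projections, trained on healthy
scans only, together with a synthetic vessel-phantom generator that makes
both detectors trainable and testable on a single CPU.

## The detection models

### VQ-VAE with an autoregressive latent prior

A vector-quantized autoencoder compresses an image `x` into an `h×w` grid
of `d`-dimensional encoder vectors `E(x)`; each vector is replaced by its
nearest prototype from a learned codebook `{e_k}, k=1..K` (Euclidean
distance, ties to the lowest index).  Training minimizes

    L = |x − D(e)|₁ + ‖sg[E(x)] − e‖² + w_c·‖sg[e] − E(x)‖²

with stop-gradient `sg`: the alignment term moves only the codebook, the
commitment term only the encoder, and the decoder's reconstruction
gradient passes straight through the quantizer.  L1 reconstruction is the
default (configurable to L2).

Two anomaly scores derive from the trained pair of models:

* **Alignment Loss Map (ALM)** — the per-cell squared distance between
  `E(x)` and its selected code.  Codes are fitted to healthy structure
  only, so abnormal structure lands far from every prototype.  The ALM is
  upscaled to image resolution (nearest-neighbour, value-preserving),
  thresholded at `t_al`, and morphologically refined into a pixel-wise
  anomaly segmentation.
* **Latent negative log-likelihood** — a causal convolutional network
  (PixelCNN-style masked convolutions, optional causally-masked
  self-attention) models `p(z) = Π p(z_i | z_<i)` over codebook indices in
  raster order.  The scan-wise anomaly score is the sum of per-cell NLL
  values strictly above a threshold `t_ar`.

Thresholds are calibrated on the healthy validation split: `t_ar` is the
95th percentile of pooled per-cell validation NLLs (linear-interpolation
percentile); `t_al` is a percentile (default 98th) of pooled validation
ALM cells.  Both are recomputed per run rather than hard-coded, since
their scale depends on the trained model.

### Bayesian U-Net epistemic uncertainty

A dropout-equipped U-Net (3×3 conv + batch-norm + ReLU + dropout blocks,
2×2 max-pool encoder, transpose-convolution decoder) is trained to segment
the vasculature of healthy scans against weak labels, with loss
`CE + β·(1 − Dice)`, β = 0.6.  At test time dropout stays active and `n`
stochastic passes are drawn (batch-norm uses running statistics).  The
epistemic uncertainty at pixel `P` is

    u(P) = (1/K) Σ_k σ²_k(P),   σ²_k(P) = (1/n) Σ_i (y_i^k(P) − μ_k(P))²

— the population variance of the class probabilities across dropout
samples, averaged over the K = 2 classes.  Healthy vasculature is
segmented consistently (u ≈ 0); abnormal vasculature is segmented
inconsistently, so u is the pixel-wise anomaly score, thresholded at
`t_un = 0` (strict `>`, so any nonzero uncertainty counts) and refined
like the ALM.  Scan-wise scores sum u above `t_un`.

## The phantom generator and what it emulates

Healthy en face projections of the macula are highly stereotyped: a dark
foveal avascular zone (FAZ) at the centre, bright curvilinear vessels
radiating outward, branching as they go.  The generator reproduces exactly
this geometry: vessels start on a ring around the FAZ and perform a
bounded-curvature random walk with a weak radial restoring term, a
Gaussian cross-sectional intensity profile (ridge-like by construction, so
Hessian-based vesselness responds to it), and quasi-regular branching —
branch events occur at jittered intervals of the configured rate rather
than memorylessly, which keeps per-image vessel density repeatable
(coefficient of variation ≈ 0.07).  The vessel mask is the set of pixels
whose rendered profile exceeds half its peak.  Gaussian background noise
(σ = 0.03) and a soft FAZ attenuation complete the image.

Three lesion classes are injected into diseased phantoms, mirroring the
lesion types of diabetic retinopathy angiography:

* **dropout** (capillary non-perfusion): intensities inside a disk are
  attenuated toward the local background level.  Default severity is
  drawn from U(0.3, 0.55) — subtotal attenuation that leaves a residual
  dimmed flow signal, as real non-perfusion does; total erasure of a
  region that then looks like plain background is neither realistic nor
  detectable by any healthy-reference method.
* **tuft** (neovascularization): a dense bright tangle of fine vessels is
  added inside the disk (severity scales its gain).
* **tortuosity** (abnormal vessel course): a smooth sinusoidal
  displacement field, windowed to vanish at the disk boundary, warps the
  image locally.

Dropout and tortuosity lesions are placed over vascularized tissue (the
candidate centre with the highest vessel coverage among 60 draws, stopping
early at coverage ≥ 0.25): a perfusion anomaly must alter perfused tissue.
Diseased scans carry 2–3 lesions with radii of 10–20 % of the image side.
These choices calibrate the lesions for detectability, not for clinical
realism.

What the phantoms do **not** emulate: scanner artifacts (motion,
shadowing), real OCTA speckle statistics, the capillary meshwork between
larger vessels, and inter-subject anatomical variation beyond random
vessel layout.  Passing the synthetic studies therefore demonstrates that
the mechanisms work as designed — codes/prior fitted to healthy structure
flag deviations, dropout variance concentrates on ambiguous structure —
not that clinical-scale performance transfers.

## Scale presets and numerical choices

Every model has a **desk** preset (default, 128-px images) and a
**clinical** preset (480-px geometry: 512→480 standardization,
K = 128 / d = 256 codebook, 60×60 latent grid, depth-5 / 64-channel U-Net,
200–300-epoch schedules).  Desk-scale choices that differ from a plain
shrink of the clinical configuration, and why:

* **Latent ratio 4× instead of 8×.**  At 128 px an 8× ratio yields a
  16×16 grid; tail-sum scan statistics over only 256 cells fluctuate
  between healthy scans as much as anomalies move them.  The desk preset
  uses 4× (32×32 = 1024 cells, the same order as the clinical 60×60), which
  stabilized the scan score and quadrupled the latent footprint of each
  lesion.  The clinical preset keeps the 8× ratio.
* **Two-phase VQ-VAE training.**  At desk-scale step counts (a few
  thousand), training the quantized model from random codes collapses the
  codebook onto a single prototype.  Training therefore runs an
  autoencoder-only warm-up for the first 60 % of epochs, initializes the
  codebook by k-means on encoder features, and fine-tunes with the
  quantizer in place.  Inside the optimizer the VQ terms use element-mean
  scaling with commitment weight 0.25, keeping them commensurate with the
  reconstruction term regardless of `d`; the reporting surface
  (`vqvae_loss`) keeps the per-cell squared-distance convention with unit
  weights by default.
* **Codebook is gradient-trained** (through the alignment term), not
  EMA-updated; codes never selected in an epoch stay where they are.
* **VQ-VAE augmentation** at desk scale is horizontal flips and 90°
  rotations (exact symmetries of the phantom distribution, applied without
  resampling); the clinical-scale recipe additionally uses random resize
  crops and Gaussian blur, which matter for scanner variation but not for
  phantoms.
* **AR prior:** embedded indices (1×1 embedding, dimension 16 — causal
  because the type-A first convolution excludes the centre tap), three
  masked residual blocks of 64 channels, no attention at desk scale
  (config flag; the causality contract is unchanged and is tested with
  attention enabled too).  Desk schedule: Adam, lr 1e-3, batch 16,
  24 epochs; the clinical preset restores lr 5e-4, 300 epochs, attention.
* **U-Net desk preset:** depth 4, 16 base channels, trained on random
  64-px crops (vessels are local structure; inference is fully
  convolutional at full resolution), 16 epochs, dropout 0.1, n = 20
  Monte-Carlo samples.  Dropout rate and n are nowhere fixed by the
  method; higher dropout rates (0.2–0.3) were found to raise the healthy
  baseline uncertainty faster than the anomaly response and are not the
  default.
* **Vesselness** is a Frangi-style two-eigenvalue ridge filter (β = 0.5,
  structureness scale c = half the maximal Frobenius norm per scale),
  maximum over scales {1, 2, 4} px, bright-ridge branch only (λ₂ < 0).
  The image is de-meaned before differentiation so the response is exactly
  invariant to constant offsets, and derivative kernels use a wide
  truncation (8σ) so polynomial test surfaces behave like their analytic
  derivatives.  Enhancement is applied on the segmentation (U-Net) path
  and off on the scan-wise (VQ-VAE) path by default; both expose the flag.
* **Eigenvalues** of the symmetric 2×2 Hessian are closed-form, ordered by
  |λ₁| ≤ |λ₂| with absolute-value ties broken by signed value ascending.
* **Thresholding is strict** (`>`), so `t_un = 0` means "any nonzero
  uncertainty is anomalous".
* **Morphology defaults** scale with resolution: opening radius 1,
  dilation radius 2, minimum component area 64 px² at 480 px (≈ 5 px² at
  128 px); components use 8-connectivity.  Dice and IoU use the
  both-empty = 1 convention so anomaly-free evaluation images do not
  poison averages.
* **Youden operating point** candidates are the midpoints between
  consecutive sorted unique scores plus one candidate below the minimum
  and one above the maximum (the all-positive and all-negative operating
  points, needed when one class dominates); ties are broken toward higher
  specificity.  The operating point is computed on the evaluated score set
  itself, with calibration on a separate set available as an option.
* **Splits:** healthy scans 80/10/10 train/val/test (rounded); diseased
  scans half to validation, half to test, never to training — both
  trainers refuse manifests violating this.

## Problem sizes

The test suite's end-to-end studies use 200 healthy + 40 diseased
128-px phantoms (VQ-VAE 16 epochs, AR prior 24 epochs, U-Net 16 epochs);
`scripts/acceptance.py` runs the same two studies at 120 + 30 phantoms
with proportionally shorter schedules (12 / 18 / 12 epochs).  Unit tests
run on 32-px phantoms with miniature models.

## Known limitations

* All networks run on a compact NumPy reverse-mode autodiff engine
  (`octa_anomaly.nn`) written for this package; it is single-threaded
  BLAS-bound and has no GPU path, so clinical-preset schedules are reachable
  but slow.
* The ALM segmentation inherits the latent resolution: one latent cell
  spans 4 px at desk scale, so lesion boundaries are blocky and small
  lesions can vanish.
* Scan scores correlate with total vessel content; the quasi-regular
  branching of the generator reduces this confound for phantoms, but on
  real data the same effect would add healthy-score variance.
* Validation-percentile threshold calibration assumes the validation
  healthy split is representative; with very few validation scans the
  percentile estimate is noisy.
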