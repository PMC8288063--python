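# Methods

This note documents the models, estimators and design choices behind
`visfill`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic stimuli

Scenes are synthesized in the Fourier domain.  Each of the 6 categories
owns an amplitude spectrum concentrated on a category-specific orientation
(18° angular bandwidth, π-periodic) and spatial-frequency band (centres
geometrically spaced over 8–40 cycles/image, 0.35-octave bandwidth) on a
0.25/f background, plus a shared random prototype phase field.  Each
exemplar jitters the prototype phase (σ = 0.7 rad) and is robustly
rescaled to [0, 1] (1st–99th percentile clip).  This yields within-category
pixel correlations of roughly 0.6 against ≈ 0 between categories — real
category structure without external images.  What it does **not** emulate:
natural-scene content, 1/f² luminance statistics, semantic regularities, or
the sky-heavy upper quadrants of landscape photographs.  Passing recovery
tests on these stimuli therefore demonstrate correctness of the analysis
chain, not claims about natural images.

The occluder sets the lower-right quadrant (exactly the half-open
rectangle `[H/2, H) × [W/2, W)`) to 1.0 and touches nothing else.

## Visual-field geometry and pRF maps

The stimulus spans 19.5° × 14.7° of visual angle, mapped to 256 × 256 px
(horizontal scale 13.1 px/°, vertical 17.4 px/°; conversions are per-axis
linear).  Voxels tile the two lower quadrants on a jittered grid; the
Gaussian pRF spread follows σ = intercept + slope·eccentricity with
defaults intercept = 0.229° and slope = 0.081 (V1) / 0.112 (V2), chosen so
that σ converted at the horizontal scale spans ≈ 3–16 px in V1 and
≈ 3–21 px in V2 across the quadrant — matching the ranges the pipeline's
RF-comparison table reports.  Inclusion requires the 2σ disc around the
pRF centre to lie inside the quadrant rectangle (equivalent to four box
inequalities, tested against a dense circular-sampling oracle).  Per-ROI
voxel counts after exclusion are configurable and are *not* presented as
empirical values; no public count exists for the original recordings.

## Voxel-response simulation

The planted geometry is a non-negative mixture of candidate feature spaces
(each column-centred and globally scaled to unit mean variance, then
weighted by √w and concatenated).  Its squared-Euclidean RDM (divided by
dimensionality) is stored as ground truth per quadrant.  Each voxel reads
**one** dimension of the quadrant-appropriate mixture — subject-specific
stacked random permutations with per-voxel lognormal gains
(σ_gain = 0.2) — a sparse non-negative readout.  With gains off and the
group's voxel count a multiple of the mixture dimensionality, population
pattern distances are an exact positive multiple of the planted distances,
which pins down the noiseless limit exactly (split-half rank correlation
1.0 with ground truth).  The pRF aperture acts at quadrant granularity:
planted spaces are PCA-reduced (non-spatial) features, so a voxel's
quadrant tag decides which feature space drives it; sub-quadrant aperture
weighting is not modelled.

Run-level noise is Gaussian with covariance D^{1/2} R D^{1/2}: lognormal
heteroscedastic scales (σ = 0.3) and AR(1)-style neighbour correlation
(ρ = 0.3), scaled by noise_sd/√(reps-per-run).  The default
noise_sd = 3.0 was chosen once to put split-half RDM reliability near 0.5,
typical of early-visual condition-rich designs; reliability decreases
monotonically in noise_sd (tested over a 5-point grid).  Inter-subject
variability comes from subject-specific readouts and gains; there is no
hemodynamic model, no GLM estimation, and no trial-order structure.

All randomness descends from one master seed through a named SeedSequence
hierarchy; identical configs are bit-identical.

## Network

A symmetric U-Net built on an in-package numpy layer library (strided
convolution, transposed convolution, batch normalization, leaky-ReLU/ReLU/
sigmoid, inverted dropout, Adam).  Backprop is hand-written per layer and
gradient-checked against central finite differences; transposed
convolution is verified to be the exact adjoint of convolution.

Default architecture: 8 encoder layers, kernel 4 / stride 2 / padding 1,
channels (64, 128, 256, 512, 512, 512, 512, 1024), leaky-ReLU, batch norm
from layer 2; the mirrored decoder uses transposed convolutions (ReLU,
sigmoid output) with skip concatenations from the matching-size encoder
layer.  At 256 × 256 input the bottleneck is 1 × 1 × 1024 — the minimum
flattened dimensionality among the 15 analyzed layers, and the component
cap of the reduction stage.  The kernel size is 4 because only kernel 4
reproduces the 4 px / 22 px receptive fields of encoder layers 1 and 3
that anchor the RF analysis; kernel 3 (as an architecture text might
suggest) gives 3 px / 15 px and is supported via config but not default.
The exact channel progression is a reconstruction constrained by the
1024-dimensional bottleneck, not a verbatim architecture.  Desk-scale
profiles shrink channels (bottleneck 32) — all structural properties
(layer count, sectioning, RF sizes) are channel-independent.

Training is self-supervised: occluded image in, original out, with loss
L1(occluded quadrant) + 0.1·L1(full image), Adam (lr 1e-3), dropout in the
first three decoder layers during training only, batch-norm statistics
frozen at inference.  An optional adversarial head (small convolutional
patch discriminator, BCE) exists but is off by default; at a few hundred
images it mainly adds variance.  Held-out reconstruction error is
full-image L1: the network's output is the complete image, and at desk
scale the occluded-quadrant error is dominated by irreducible phase
uncertainty while the full-image error cleanly tracks learning.
Divergence (non-finite loss) aborts with the epoch/batch in the message.

The baseline topology is the standard 16-layer classification network
(5 conv blocks with 2×2 pooling); analysis uses the block-final
convolutions (conv1_2, conv2_2, conv3_3, conv4_3, conv5_3).  Weights are
random by default — the package analyzes topology and layer selection and
never downloads pretrained weights; user-supplied weights can be loaded.

## Receptive-field geometry

The RF recursion (r ← r + (k−1)·j; j ← j·s; start ← start +
((k−1)/2 − p)·j) runs over any conv/pool cascade.  Unit-to-patch mapping
returns the *discrete support*: the r consecutive pixels centred on the
unit (rounded outward at half-integer centres), clipped to the image.
Clipping matters at corners — with padding 1 the corner unit of a
kernel-4 layer truly depends on 3 × 3 image pixels — and the analytic
rectangle is tested to equal the numerical gradient support for every
kernel/stride in {3, 4} × {1, 2} up to depth 4.

Quadrant selection keeps units whose **full** RF rectangle lies inside the
quadrant (the strictest reading of border removal); the empty set signals
lost spatiotopy.  For the default architecture this makes encoder layers
1–5 spatial (layer 5: 2 × 2 units per quadrant at RF 94 px) and layers 6+
latent, reproducing the layer-5 boundary.  Whether "spans the entire
image" meant RF > image or RF > quadrant is ambiguous in the source; the
quadrant criterion is the default and both are reachable via config.
Decoder units formally see the whole input through the bottleneck, so
decoder quadrant assignment uses output-position retinotopy: grid cells
mapped linearly onto the image, cells adjacent to an internal quadrant
boundary dropped.  Decoder layers with grids below 16 × 16 are grouped
with the latent section (configurable; the source's exact grouping is not
printed).

## Dimensionality reduction

One incremental PCA per (layer, quadrant) — whether the original fit one
transform per layer over both quadrants is unstated; per-(layer, quadrant)
is the default.  The fit stream uses synthetic images disjoint from the
24 test stimuli (ids asserted disjoint), desk default 2 000 images
(scaled down from a 10 000-image stream), single pass, batches of ≥ the
component count.  Components are capped at min(dimensionality, stream
length) with the effective count recorded, never silently; signs are fixed
so each component's largest-magnitude loading is positive (platform
determinism).  Keeping the first n columns of a fitted transform equals an
n-component reduction, which is how the component sweep (8…1024, powers of
two) is computed without refitting.

## RSA estimators

* **Splits.** 70 = C(8,4) role-distinct fitting/testing halves; quarters
  pair the sorted run indices lexicographically (first two vs last two).
  The quarter composition and the role-distinct reading are inferences
  from the count 70; both are documented, not sourced.
* **Noise covariance.** Sample covariance of within-condition deviations
  across the half's runs, shrunk toward its diagonal with the analytic
  (Schäfer–Strimmer-style) intensity, positive-definiteness certified by
  Cholesky.  The synthetic setting has no GLM residuals, so repetition
  deviations are the source.
* **LDC.** d(i,j) = (ā_i − ā_j)ᵀ Σ̂⁻¹ (b̄_i − b̄_j)/V between quarter
  condition means; symmetrized; unbiased under cross-validation (checked
  by Monte Carlo against the planted Mahalanobis contrast and under the
  null).
* **Model RDMs** use squared Euclidean distance over component count:
  activations are deterministic, making this the natural degenerate case
  of the discriminant contrast (whether the original applied LDC with
  some noise surrogate on the CNN side is unstated; configurable).
* **Regressors.** `pc-blocks(64)` (one RDM per consecutive block of 64
  components; 16 regressors at 1 024 components) makes the leave-two-out
  NNLS fit non-vacuous; `single` reduces to a per-entry scaled-RDM
  comparison with a closed-form vectorized fit.  The regressor
  construction of the original is not printed; both modes are first-class
  and results name the mode used.  Full-study pc-blocks costs ~20 M NNLS
  solves (70 splits × 276 pairs × 15 layers × 18 subjects × 4 groups) and
  is out of desk-scale reach; study-scale runs use `single`.
* **τ-a**, not τ-b: all pairs in the denominator, ties counting to
  neither side — appropriate when candidate RDMs contain ties.
* **Ceilings.** Upper: mean τ-a of each subject's (split-averaged) test
  RDM against the all-subject mean; lower: against the leave-one-out
  mean.  The upper bound carries a small O(1/√S) inclusion bias.
* **Group tests.** Paired t-test for between-model contrasts, Wilcoxon
  signed-rank for encoder-vs-decoder section contrasts, raw p-values by
  default with an optional Benjamini–Hochberg column.

## Pipeline and problem sizes

Stages generate → train → extract → reduce → rsa → report, each appending
a manifest entry (config snapshot, derived per-stage seed < 2³¹, wall
time, SHA-256 digests); deterministic stages re-run to identical digests.
Voxel simulation lives inside the rsa stage because the planted geometry
is a *reduced* feature space that only exists after reduce.

Desk-scale profiles used by the examples and the test suite keep every
study-design constant (24/6 scenes, 18 subjects, 8 × 2 presentations, 70
splits, 15 layers) and shrink only implementation sizes: encoder channels
(4, 8, 8, 16, 16, 16, 16, 32), 16 components, 48–96 fit images, `single`
regressor mode.  A full recovery study at these sizes takes ~25 s on one
CPU.

## Known limitations

* Readout sparsity (one mixture dimension per voxel) is a convenience that
  makes the noiseless limit exact; dense non-negative readouts would blur
  planted distances with a rank-one mean component.
* The baseline network is topology-only by default; comparisons against
  it speak to layer selection and geometry of random features, not to
  ImageNet-trained features.
* Desk-scale training (hundreds of synthetic images, 5 epochs) learns
  reconstruction but not the full inpainting competence of a
  100 k-image, GPU-scale run; nothing downstream depends on trained
  weights (random-weight activations are valid candidate spaces).
* Group tests are provided per (ROI, quadrant) without multiplicity
  correction by default, mirroring raw-p reporting.
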