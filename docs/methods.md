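# Methods notes

This note records the models implemented in `cardiomorph`, the assumptions
behind them, the defaults that matter, and the design decisions taken where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic phantom

`phantom.generate_phantom` emulates the statistical structure of segmented
cardiomyocyte volume-EM data, not its appearance:

- **Myofibrils** are stripes in y spanning the full z and x extent — the
  longitudinal (x) axis of the cell. Whole stripes of `myofibril_width_um`
  (default 0.4 µm) are laid out evenly to approach
  `myofibril_fill_fraction` from below; the achieved coverage is therefore a
  step function of the requested fraction.
- **Z-discs** are x-slabs of `zdisc_thickness_um` (default 0.1 µm) at every
  multiple of `sarcomere_period_um` (default 2.0 µm), *inside myofibrils
  only*. The Z-disc voxel fraction is consequently
  `fill × n_planes × thickness_vox / n_x` — about `fill × 3.9 %` for the
  default 5.12 µm longitudinal extent.
- **Mitochondria** are ellipsoids (semi-axes default 0.3/0.3/0.45 µm with
  ±25 % jitter) rejection-sampled into the inter-myofibril space: a
  candidate is accepted only if every voxel of the ellipsoid is still
  background, so mitochondria can never overwrite Z-discs or each other.
  After `max_placement_retries` (default 1000) failures a placement error is
  raised rather than silently under-filling.
- **Intensity** is `contrast_map[label] + N(0, noise_sd²)` clipped to
  [0, 1]. Defaults put Z-discs darkest (0.20), then mitochondria (0.35),
  myofibrils (0.47) and cytosol (0.60), with `noise_sd = 0.08` — low
  contrast relative to EM dynamic range, which is the property downstream
  training tests need. Real EM noise (shot noise, charging, curtaining) is
  deliberately not modelled.

**Why `myofibril_fill_fraction` defaults to 0.2.** With the thickness/period
ratio fixed at 0.05, the Z-disc class fraction is `≈ fill × 3.9 %`. The
defining statistical feature of this class is its rarity — under 1 % of
voxels — which is what makes its segmentation hard and motivates the joint
multi-class design. A fill of 0.2 (achieved ≈ 0.16 after whole-stripe
rounding) puts the Z-disc fraction at ≈ 0.6 %, under that bound with margin.
Real cardiomyocytes have higher myofibril fractions; the parameter is
exposed for users who prefer realism of the fill over realism of the class
imbalance. Voxel size defaults to 20 nm isotropic so µm↔voxel conversions
are exact; anisotropy is supported per axis throughout the package.

What passing tests on phantoms do **not** show: robustness to the texture,
anisotropic point-spread and annotation noise of real FIB-SEM/SBF-SEM data.
The phantom's classes are separable by mean intensity alone, so segmentation
scores on phantoms are upper bounds, not forecasts.

## The segmentation network

A symmetric encoder/decoder with skip connections: four encoder blocks (two
3×3 convolutions + ReLU each), one densely connected bottleneck, four
decoder blocks — nine blocks. 2×2/stride-2 max-pooling halves resolution and
doubles channels between encoder blocks; nearest-neighbour 2× upsampling
followed by convolution (transposed convolution would be the obvious
alternative; nearest+conv avoids checkerboard artefacts) halves channels in
the decoder, and skips merge by channel concatenation. The output head is a
1×1 convolution to `n_classes` (default 4) followed by SoftMax with
max-subtraction stabilization.

Open details fixed as package defaults:

- **Bottleneck**: 4 densely connected 3×3 convolutions; every layer sees the
  concatenation of the block input and all previous layer outputs; growth
  rate defaults to `base_channels`; a final 1×1 convolution projects to
  `2^4 × base_channels` so the doubling/halving channel ladder is exact.
- **TLU**: a two-slope trainable piecewise-linear unit
  `f(x) = p·max(x,0) + q·min(x,0)` with per-channel learnable `p` (init 1)
  and `q` (init 0.25). It reduces to ReLU at `q = 0` and to the identity at
  `p = q = 1`.
- **Loss**: categorical cross-entropy over the SoftMax, the canonical
  pairing; optional per-class weights. **Optimizer**: Adam at 1e-3
  (desk-scale experiments use 3e-3), configurable. No augmentation.
- **Prediction tiling** averages overlapping tile probabilities before the
  per-pixel argmax (default overlap: half a tile), so tile seams cannot
  appear in the label map; volumes smaller than a tile are reflect-padded
  unless the caller forbids padding.

Training is deterministic for a fixed seed on one device: one seeded
generator drives initialization, epoch shuffling and updates. The returned
checkpoint is the epoch with the best validation loss; early stopping by
patience is available.

**Desk-scale study sizes.** The repository's training experiments use a
64×64-input, 8-base-channel instance trained for 45 epochs on 24 patches
from a 32×128×128-voxel phantom (~30 s per run on one CPU); held-out
evaluation uses the last 4 z-slices, which the patch extractor never sees.
These sizes are the package's reference experiment; all of them scale by
config. In the binary-vs-multiclass Z-disc comparison, neither arm reliably
learns the Z-disc class within the 30-epoch budget, so the median comparison
mostly certifies that joint training is *not worse* — on phantoms the
Z-disc has a unique intensity, so binary training does not collapse the way
it does on real data, and the advantage of joint training is correspondingly
smaller.

## Segmentation metrics

Per-class one-vs-rest counts give accuracy, specificity, PPV, NPV, recall
and Jaccard. Any zero-denominator metric is reported as NaN with a warning —
never silently as 0 — so aggregate tables cannot hide degenerate cases.

`v_rand_thinned` and `v_info_thinned` are the foreground-restricted,
border-thinned Rand and Information F-scores used by EM segmentation
challenges. Evaluation is restricted to truth-foreground pixels; with
thinning radius `r ≥ 1` the truth-boundary pixels themselves plus an
`(r−1)`-pixel dilation are excluded (radius 0 evaluates everything). On the
joint histogram `n_ij` of (prediction segment, truth segment) with marginals
`s_i`, `t_j`:

- Rand F-score = `Σ n_ij² / (½ Σ s_i² + ½ Σ t_j²)`;
- Information F-score = `2 I(S;T) / (H(S) + H(T))`, defined as 1 when both
  entropies vanish (two single-segment maps agree by definition).

Both are 1.0 iff the evaluated segmentations agree and are invariant to
permuting segment ids. Inputs are treated as segment maps as given; whether
to pool foreground classes or evaluate one class's components at a time is
the caller's choice (both are a one-liner via `label_components`).

## The generative model

A conditional style-based GAN at configurable resolution (desk default 32²,
paper-scale resolutions are a config change away, not a tested regime):

- the generator starts from a learned constant tensor (4×4×`base_channels`),
  the scaled analogue of a full-scale 4×512×512 constant — there is no
  latent input layer;
- a mapping network (2 dense layers by default) turns the latent `z`
  concatenated with the embedded one-hot *slice-pair label* into a style
  vector `w`; each synthesis block applies upsample → conv → noise injection
  (per-channel learned scale on fresh Gaussian noise) → leaky ReLU →
  instance normalization → per-channel affine styling from `w`;
- the output is a 4-channel class-probability slice (channel SoftMax); label
  slices are its argmax. The discriminator is a small conv net with
  projection conditioning on the same pair-label embedding;
- losses are the non-saturating logistic pair; Adam with β₁ = 0.5. Records
  are consumed in stack order — **no shuffling** — so the pair label's
  meaning (position of a consecutive-slice pair in the source stack) is
  preserved during optimization. Progressive growing, equalized learning
  rates, style mixing and perceptual-path-length regularization of the
  full-scale architecture are intentionally omitted at desk scale.

**FID.** `fid` computes `||µ₁−µ₂||² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2})` with a
stabilized matrix square root (tiny negative eigenvalues clamped; an
epsilon-regularized retry with a warning if the root is non-finite).
Covariances use the population convention (divide by n) by default,
configurable. The feature extractor is pluggable; the default deterministic
average-pool pixel embedding (8×8 → 64-d) keeps the distance exact and
CPU-testable, and a pretrained feature network can be slotted in as a
callable at full scale. Convergence is tracked by evaluating FID between
generated and training slices every `fid_interval` iterations; the reported
checkpoint is the trace minimum (no fixed threshold is assumed).

**Generation.** `generate_model_volume` samples `n_seeds` latents (pair
labels cycle in stack order by default; random draw available), orders the
slices by Jaccard distance and assembles them at `z_spacing_um` (default
0.4 µm) and `xy_extent_um` (default 10 µm), so the volume depth scales
linearly with the number of seeds — 25 seeds give 10×10×10 µm.

## Slice ordering

The objective is the total Jaccard distance along an open path (a stack has
two ends), in either `foreground` (pooled nonzero mask) or `per_class_mean`
(default) mode; two empty masks are at distance 0 by convention. Exhaustive
search (n ≤ 10) returns the global minimizer with ties broken by the
lexicographically smallest permutation, which also resolves the reversal
degeneracy (the representative starts at the smaller end index). The greedy
method seeds with the globally closest pair and repeatedly appends the
nearest unused slice to the nearer end; exhaustive cost ≤ greedy cost always
and the exhaustive route doubles as the oracle for the greedy one in tests.

## Morphometry

Connected components (6 or 26 neighbourhood; default 26) are labelled in
deterministic scan order. For each component with volume V, surface S and
principal second moments λ1 ≥ λ2 ≥ λ3 of the physically scaled voxel
coordinates (anisotropy handled by scaling coordinates before the
covariance):

compactness `C = 36πV²/S³`, sphericity `ψ = C^{1/3}`, elongation
`√(λ1/λ2)`, flatness `√(λ2/λ3)`, spareness `V / (4/3·π·abc)` with
covariance-matched semi-axes `a_i = √(5λ_i)`, and SA:V = S/V.

Surface area defaults to the triangulated marching-cubes estimate computed
on a Gaussian-smoothed (σ = 0.8 voxel) copy of the binary mask: meshing the
raw 0/1 field overestimates a ball's area by ~9 % (staircase artefact),
while the anti-aliased mesh is within a fraction of a percent for radii
≥ 15 voxels. The voxel-face estimator is provided for comparison but biased
high (≈1.5× for a ball) and documented as unsuitable for compactness, whose
S³ denominator cubes the bias. Components under 4 voxels are kept but
flagged `reliable = False`; degenerate moments yield NaN ratios rather than
infinities.

Density maps slide a cubic kernel (default 4 µm, stride 0.4 µm) over the
volume using summed-area tables, counting only fully interior windows; cells
whose window contains no myofibril voxels are NaN and their count is
reported so histograms can state exactly what was excluded.

`compare_distributions` reports one-way ANOVA (F, p) on means, a two-sided
F-ratio test on variances, η² as effect size and both sample sizes; two
zero-variance samples short-circuit to a flagged degenerate report.

## Data handling

Coordinates are 0-based (z, y, x) with half-open extents. Patch extraction
draws from randomly offset per-slice grids, which guarantees non-overlap by
construction and makes the capacity bound exact:
`⌊Y/s⌋·⌊X/s⌋` patches per slice. K-fold splits rotate one seeded permutation
by the validation-block size, so validation sets are disjoint across folds
whenever `n_folds × val_count ≤ n` and all counts are exact. Slice-pair
records (two consecutive slices + one-hot pair index) replace an
ecosystem-specific record container with plain HDF5; pairs spanning a
missing slice are dropped with a warning rather than silently bridged.

## Numerical core

`cardiomorph.nn` is a ~500-line reverse-mode autograd on float32 numpy
arrays: broadcasting elementwise ops, matmul, concat/reshape, stride-1
convolution via im2col, 2×2 max/average pooling, nearest upsampling, and a
fused stabilized softmax cross-entropy. All gradients are verified against
central finite differences in the test suite. It exists to make the
networks self-contained and deterministic on CPU; it is not, and does not
aim to be, a general deep-learning framework.

## Known limitations

- Phantom realism is structural, not textural (see above).
- The GAN's conditioning signal on near-z-invariant phantoms is weak because
  consecutive phantom slices are almost identical; the conditioning test
  therefore uses a translated-disc stack where consecutive slices differ
  sharply.
- Exhaustive ordering is factorial and capped at n = 10; greedy ordering is
  O(n²) but heuristic.
- Full-scale (512–1024 px) GAN training is out of scope for the CPU core;
  the architecture and training loop are faithful at reduced width/depth.
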