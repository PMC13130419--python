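# Methods

`ldq` quantifies intramuscular fat (IMF) in the lumbar-spine muscles from
Dixon MRI. A Dixon acquisition yields co-registered water (W) and fat (F)
images plus the in-phase image IP = W + F; the voxel-wise proton-density
fat fraction is FF = F / (W + F), and the IMF of a muscle is the mean FF
over its 3D mask. The package provides the full processing chain around
that measurement: a synthetic phantom cohort, dataset homogenisation,
anatomy-aware training-set augmentation, a 3D U-Net segmentation engine
with a multi-atlas baseline, and the evaluation/statistics layer (Dice,
relative volume difference, Hausdorff distance, Bland–Altman agreement,
Kruskal–Wallis tests, Type III ANCOVA with partial η², normative
median/IQR reference tables).

Segmented structures are the four bilateral muscle groups relevant to
lumbar muscle health: psoas (P), iliacus (I), quadratus lumborum (QL) and
the erector spinae + multifidus complex (ES+M). Label codes are fixed,
left before right: 1..8 = P_L, P_R, I_L, I_R, QL_L, QL_R, ESM_L, ESM_R;
0 is background.

## Axis and index conventions

Grids are indexed `(x, y, z)`: x = left–right (medial–lateral),
y = anterior–posterior, z = superior–inferior (the axial slice axis).
Voxel indices are 0-based; axial crop ranges are inclusive at both ends.
Flips mirror across the medial–lateral axis (swapping left/right label
codes); rotations model in-plane patient positioning variability and are
applied about the slice axis. Both choices are configurable.

## Synthetic phantom cohort

Clinical Dixon data cannot be redistributed, so the package generates
synthetic subjects that preserve the quantities the pipeline measures.

Each phantom is an axial "abdomen": an elliptical body with a high-fat
subcutaneous ring (FF 0.90, thickness 7 mm), interior soft tissue
(FF 0.25), and eight elliptic muscle tubes running along z with per-muscle
generative FF. Default muscle FFs (P 0.156, I 0.116, QL 0.143, ES+M 0.218)
sit at values reported for healthy adults, with ES+M highest and iliacus
lowest. Tissue follows a two-compartment model: `fat = FF * d`,
`water = (1 − FF) * d` with a per-tissue-class signal density d (muscle
0.80, other soft tissue 0.90, adipose 1.00). Density cancels in the FF
ratio, so FF recovery is unaffected, while the in-phase image shows the
anatomy with realistic muscle/fat contrast (on in-phase TSE images muscle
is darker than fat). An optional "epimuscular fat" shell posterior to ES+M
lets tests verify that high-fat tissue outside the mask does not
contaminate muscle FF.

Inter-subject anatomical variability is a smooth random displacement
field: white noise smoothed with a 12 mm Gaussian, rescaled to a 3 mm peak
amplitude. The deformation is applied by warping the *coordinate field*
before evaluating the analytic shape membership tests, with the identical
warp for every channel and the labels. Deformed phantoms therefore have
crisp, perfectly consistent boundaries and constant FF inside every
structure: at zero noise the measured mean FF equals the generative FF to
float32 precision, so any disagreement downstream is attributable to the
pipeline, not the phantom. Channel noise is zero-mean Gaussian
(sd 0.02 in signal units, i.e. 2% of the adipose signal) added to W and F
independently, clipped at zero, with IP recomputed as W + F afterwards so
the Dixon identity holds exactly. Gaussian (not Rician) noise keeps the FF
error analytically tractable; at this SNR the difference is negligible.

What the phantoms do *not* emulate: MR physics (T2*/multi-echo effects,
chemical shift, bias fields), bone, organs, realistic muscle cross-section
shapes, or pathological fatty replacement. Passing phantom-based tests
shows the pipeline's machinery is correct under known ground truth; it
does not certify clinical accuracy on real scans.

Cohorts draw per-subject covariates (age uniform 20–70 y, sex, BMI
N(25.7, 5.6²) kg/m², activity group) and link per-muscle FF linearly:
`FF = intercept + β_age(age−40) + β_sex·male + β_BMI(BMI−25) +
β_active·active + ε`, ε ~ N(0, 0.02²), clipped to [0.01, 0.95]; sides share
the muscle FF up to a small asymmetry term (sd 0.005). Default β magnitudes
follow the reported pattern for these muscles — age strongest in QL/ES+M
(0.0018–0.002 per year), activity strongest overall (−0.03 to −0.065),
sex mattering mostly for ES+M (−0.066), BMI minor (0.001–0.0025 per
kg/m²) — so covariance analysis has a realistic, known ground truth to
recover.

## Homogenisation

Volumes are rigidly registered to a reference subject (first by sorted id
unless configured) using normalised cross-correlation on the in-phase
channel; the recovered transform is applied to all three channels (linear
interpolation) and to labels (nearest neighbour). Images are then
downsampled in-plane by 2: block averaging for images (anti-aliased) and
nearest-neighbour sampling for labels, which preserves structure volumes
in expectation (a block-mode variant with lowest-code tie-break exists
but erodes boundary-heavy structures, since background wins split
blocks). The slice axis is untouched, so 0.47 × 0.47 × 1.95 mm volumes
become 0.94 × 0.94 × 1.95 mm with a four-fold voxel-count reduction.

## Augmentation

Linear: each training subject yields {unflipped, flipped} × {0°, ±5°,
±10°} = 10 variants — the identity rotation counts among the variants,
which is the only reading under which 18 training subjects give exactly
180 linear images. Nonlinear: every ordered pair of training subjects is
registered with a deliberately small B-spline iteration budget, so the
optimisation stops early and the warped moving image is an intermediate
"virtual anatomy" between the pair — n(n−1) = 306 synthetic subjects from
n = 18, for 486 training images in total. Plans are data structures
checked against the validation ids before any image is produced, making
augmentation leakage-free by construction.

## 3D U-Net engine

The network is the classic symmetric encoder–decoder with skip
connections, implemented directly in numpy/float32: convolutions run as
sums of shifted GEMMs (BLAS) with exact hand-derived backward passes;
2×2×2 max-pooling, up-convolutions that halve the feature channels (a
1×1×1 compression at the lower resolution followed by nearest-neighbour
upsampling), instance normalisation after every convolution, ReLU
activations, and a 1×1×1 head producing one sigmoid channel per
structure plus background. Training minimises
per-channel binary cross-entropy against the one-hot target with Adam,
and early stopping restores the weights of the epoch with minimum
validation loss. Inference reduces the channel stack by argmax with ties
broken toward background. Head biases initialise at the
background/foreground prior logits (±2) so optimisation starts from the
correct marginal prediction.

Two documented configurations:

- `UNetConfig.full_scale()` — 4 encoder/4 decoder levels, 16 filters in
  the first layer, one conv per block, growth 2: 2 396 633 parameters,
  intended for full-resolution (400 × 320 × 145) volumes at the stated
  learning rate 1e-4. Whole-volume training at this scale needs tens of
  GB of memory; this configuration is documented, not exercised in tests.
- `UNetConfig.desk()` — 3 levels, 8 base filters, learning rate 1e-2,
  ≤30 epochs, patience 5: the scaled-down study condition used for the
  64 × 64 × 32 phantom benchmarks. Three levels are the minimum at which
  the receptive field spans enough of the body cross-section to localise
  interior muscles; the larger learning rate reflects the few hundred
  gradient steps available at desk scale.

The leakage guard is structural: `train()` refuses any subject id present
in both training and validation, and augmented samples carry their source
ids so provenance is checked, not file names.

## Multi-atlas baseline

Every atlas is registered to the target (affine, then B-spline
free-form), atlases are ranked by descending NCC of the registered
in-phase image against the target, the top k = 5 label sets are propagated
(nearest neighbour) and fused by strict per-voxel majority (> k/2), and
the fused mask is post-processed: labeled voxels whose FF exceeds 0.80
are removed (subcutaneous fat leakage), then holes are filled per
structure in 3D. Post-processing is idempotent. Each registration stage
carries a "never worsen" guard: if the full-volume NCC after optimisation
is below the NCC before, the stage returns its initial transform — the
contract NCC(after) ≥ NCC(before) then holds unconditionally.

At desk scale the B-spline control-point spacing is 16 mm (matched to the
12 mm correlation length of the phantom deformations) and the optimiser is
LBFGSB with full sampling (deterministic); full-scale settings (2000
iterations, 2048 samples, 8/4/2/1 pyramid) are exposed in
`FULL_SCALE_PARAMS`.

## Fat-fraction measurement

FF maps flag voxels with W + F ≤ ε (default 1e-6 × max(W+F)) as invalid
(air) rather than silently dividing 0/0; muscle means are arithmetic means
of valid voxels, reported in percent. Axial crops take inclusive slice
ranges. Left/right combine as the unweighted mean of the two side means
(not voxel-weighted) — reference tables report per-muscle values, so each
side contributes equally regardless of volume; a voxel-weighted variant
would differ whenever side volumes differ, and a test pins the unweighted
choice.

## Evaluation and statistics

- Dice 2|A∩B|/(|A|+|B|); Dice(∅,∅) := 1.0 (perfect agreement on absence).
- RVD = (V_pred − V_truth)/V_truth × 100, signed, pred minus truth.
- Hausdorff distance: boundary voxel centers (mask minus its erosion) in
  mm; maximum of the two directed max–min distances via KD-trees, checked
  against an all-pairs brute-force oracle; a 95th-percentile variant is
  available but the maximum is the default.
- Monte-Carlo CV planning: random train/validation splits, resampled
  (bounded retries) until every subject appears in at least one
  validation set; subjects may repeat across folds. (26, 5, 8) gives 18
  training subjects per fold and 40 pooled validation segmentations.
- Bland–Altman: bias = mean(y−x), limits of agreement ±1.96 sample SD,
  with y-on-x regression slope/intercept/R².
- Kruskal–Wallis with tie correction (used even for two groups).
- Type III ANCOVA: sum-to-zero contrasts for the categorical group,
  model-comparison sums of squares (each effect adjusted for all others),
  F against the full-model residual, partial η² = SS_eff/(SS_eff+SS_res),
  which equals df1·F/(df1·F + df2) — an identity asserted to 1e-9 on every
  fitted table. Rank-deficient designs are rejected naming the aliased
  terms.
- Reference tables: median and 25th/75th percentiles with linear
  interpolation, per muscle, optionally stratified by activity or sex;
  empty cells are flagged, never fabricated.

## Numerical choices and degenerate inputs

- Geometry comparisons use a 1e-4 mm tolerance; NIfTI round-trips are
  bit-exact for float32 grids and integer labels.
- One-hot encoding places background in channel 0; argmax ties therefore
  resolve toward background.
- Label downsampling ties resolve toward the lowest code.
- The strict-majority fusion rule means at most one code can win a voxel;
  the resolution rule (highest count, then lowest code) is stated for
  completeness and pinned by an exhaustive per-voxel oracle test.
- All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from the run seed through a stable stage-name hash, so
  stages are independently reproducible.

## Problem sizes used by the test suite and acceptance script

Unit tests run phantoms at 32 × 32 × 16 (4 × 4 × 6 mm) and 16 × 16 × 8,
preserving the 128 × 128 × 96 mm field of view. The segmentation benchmark
uses a 24-phantom cohort at 64 × 64 × 32 (2 × 2 × 3 mm): 16 training / 8
validation subjects for the U-Net (desk configuration, ≤30 epochs) and a
10-phantom leave-one-out for the multi-atlas baseline. These sizes keep
the full benchmark within desk-scale compute while leaving every
algorithmic path identical to the full-scale configuration.

## Known limitations

- The numpy engine trains whole volumes with batch size 1 and is
  CPU-bound; it is not intended to compete with GPU frameworks at full
  resolution.
- Phantom anatomy is geometric; Dice values obtained on phantoms are not
  comparable to values on clinical data.
- The multi-atlas desk settings are tuned to smooth, small-amplitude
  deformations; strongly displaced anatomy would need the full-scale
  pyramid and iteration budget.
- No multiple-testing correction is applied in the statistics layer.
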