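# Methods

This note documents the models, default parameters, numerical choices
and limitations of `usexpand`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted about real clinical data.

## The study design

A classifier for a scarce imaging domain (point-of-care breast
ultrasound, "POCUS") is trained on 16 combinations of a small POCUS
training cohort and expansions of a larger cart-based
("standard"-domain) cohort. The eight base combinations are: POCUS
alone; + standard; + histogram-matched standard; + equalized standard;
+ CycleGAN1-translated standard; + CycleGAN3-translated standard;
+ standard and CycleGAN1; + standard and CycleGAN3. Combinations 9–16
repeat these with random spatial augmentation during training. The
assembled sizes obey n_P, n_P + n_S and n_P + 2·n_S at any cohort
scale. All classifiers are evaluated on one held-out POCUS test set,
split patient-exclusively (no patient contributes images to both
sides). In the equalization combinations the transform is applied to
the standard training images and to the test images.

## Phantom model

Each image is built in order:

1. **Echogenicity map** — uniform background (default 0.55) times 2–3
   low-frequency horizontal sinusoidal bands (amplitude 0.12),
   emulating tissue layering.
2. **Lesion insertion** — benign: a smooth, wider-than-tall ellipse
   whose interior echogenicity is multiplied by 0.45, with the column
   band beneath brightened ×1.35 (posterior enhancement); malignant: an
   irregular, taller-than-wide region with boundary
   r(θ) = r₀·Π(1 + a·cos(kθ + φ_k)) over harmonics k = 2…6
   (total relative amplitude 0.25), interior ×0.25, column band beneath
   darkened ×0.55 (acoustic shadow). Lesion radius is uniform in
   12–22 % of the image side.
3. **Speckle** — the map multiplies the squared magnitude of a complex
   Gaussian field smoothed with a Gaussian PSF (σ = 1.5 px at 180 px,
   1.0 px in the small presets), giving a Rayleigh envelope; then
   log compression log(1 + gI)/log(1 + 1.5g) with gain g = 30.
4. **Device operator** — standard: additive Gaussian noise σ = 0.01;
   POCUS: gamma compression with exponent 1.8 (pushing intensity mass
   into the dark range) then additive Gaussian noise σ = 0.06, clipped
   to [0, 1]. The POCUS noise level is a free parameter; it is not
   calibrated against any published histogram.
5. **Heterogeneity** — background level, lesion multipliers and the
   POCUS gamma are jittered per image by a factor 1 + 0.3·U(−1, 1).
   This models between-patient variability; without it a handful of
   images suffices to learn the classes and training-set size stops
   mattering, which would defeat the purpose of a data-expansion study.
6. **Annotations** — optionally (probability 0 by default) small bright
   caliper-like crosses are burnt in, emulating residual radiologist
   markings.

Patients receive one primary finding class (largest-remainder
allocation to the requested class mix, default 0.57/0.21/0.22
normal/benign/malignant) and 1–3 images; lesion patients additionally
contribute a normal (contralateral) image with probability 0.15.

What the phantoms do **not** model: acoustic wave propagation,
refraction or reverberation artifacts, depth-dependent gain, probe
geometry (sector vs linear), BI-RADS-level morphology. Passing tests
therefore demonstrate that the pipeline's machinery behaves as
specified under a controlled two-domain shift — not that any particular
clinical performance would be achieved.

## Preprocessing

Crop (configurable margins, default 0 for synthetic data) → zero-pad to
square, content centred with floor offsets → resize to the network
side. Downscaling uses local-mean (area) averaging, upscaling bilinear
interpolation; pad-then-resize order is fixed.

## Intensity transforms

Pooled class histograms use the native 256 8-bit bins and are always
built from POCUS *training* images only. Specification maps
x → Q_t(F(x)) with the right-continuous quantile
Q_t(p) = min{u : F_t(u) ≥ p}; source ties map to one output level, so
the mapping is monotone. A single-intensity image maps entirely to the
target median. Equalization is x → round(255·F(x)); a constant image
maps to 255. The output CDF deviates from linearity by at most the
largest tie-group mass plus 8-bit rounding (1/510).

## Augmentation

Spatial: zoom U(0.9, 1.1), shear factor U(−0.1, 0.1) (the range is a
shear *factor*, not degrees), shifts U(−0.1, 0.1) of the side per axis,
rotation U(−30°, 30°), horizontal flip with probability ½ — composed
into a single affine warp (bilinear, zero fill) so each image is
resampled once. Brightness/noise: scale the [0, 1] image by U(0.7, 1.3)
(factor > 1 brightens; the sampled distribution is symmetric, so this
plain convention is statistically equivalent to toolkits that invert
it), then add N(0, 0.01) noise, then clip; noise follows brightness.
Parameters are redrawn per image per epoch; stored images are never
modified. The multi-combination study uses spatial-only augmentation;
the three-way policy comparison is available separately
(`study augment-study`).

## CycleGAN

Per model: generators G_st, G_ts (conv → strided conv → residual
blocks → upsample+conv → conv, instance-normalised, tanh output on
[−1, 1] single-channel images) and patch discriminators; least-squares
adversarial losses, cycle loss λ = 10, identity loss 0.5·λ, Adam
(β₁ = 0.5), a 50-image replay buffer for discriminator updates and
linear lr decay over the second half of training. `cyclegan1` trains
one model on all classes; `cyclegan3` one per class, independently
seeded. Translation maps every standard-domain record to a
`translated` record conserving class label and patient id — the
labelling assumption under which generated images enter training. A
per-epoch probe records the cycle reconstruction error and the mean
darkening of translations; translation artifacts are observable there
but not corrected.

Paper-scale defaults (width 64, 6 residual blocks, 200 epochs,
lr 2·10⁻⁴, 180 px) follow the standard reference configuration. The
desk preset — width 8, 2 residual blocks, 2 discriminator stages,
32 px, batch 4, 20 epochs, lr 8·10⁻⁴ — was chosen so that a full
multi-combination study (translators plus 16 classifiers) runs in
minutes on one CPU with the package's numpy backprop engine; the raised
learning rate compensates for the small number of optimisation steps.

## Classifier

The reference network: five 3×3 'same'-padded conv stages
(32, 64, 128, 128, 128), each ReLU → dropout 0.20 → 2×2/stride-2 max
pool (floor for odd sizes, hence the 180→90→45→22→11→5 trace and
flatten width 3200); dropout 0.50; dense 512 (ReLU, dropout 0.50);
dense 3 + softmax — 2,028,291 trainable parameters, locked by test.
Inputs are scaled to [0, 1]. Training: Adam lr 10⁻⁴, class-weighted
categorical cross-entropy (w_c = N/(3·n_c), probability floor 10⁻⁷),
50 epochs, batch 32, no validation set or early stopping; the final
epoch's model is evaluated.

The desk preset keeps the five-stage structure at 32 px with widths
16/32/64/64/64, fc 128, lighter dropout (0.10/0.25/0.25), lr 10⁻³ with
linear decay over the final third, 30 epochs, batch 8. The reduced
dropout is deliberate: at desk width the full-size rates leave the
network unable to fit even its training set (loss pinned at ln 3).

## Evaluation statistics

* **AUC**: Mann–Whitney probability with half-weighted ties,
  malignant vs normal+benign (the malignant probability is the score).
* **Operating point**: maximise J = Se + Sp − 1 over ROC thresholds
  subject to Se ≥ 0.90; ties break toward higher specificity, then
  higher threshold; if no threshold meets the floor (only possible with
  zero positives) the unconstrained maximiser is returned.
* **Bootstrap**: percentile 95 % intervals over B = 1000 image-level
  resamples (patient-level resampling available as a flag); for
  sensitivity/specificity the threshold is frozen before resampling;
  degenerate single-class resamples are redrawn and counted.
* **Balanced accuracy**: unweighted mean of the three per-class recalls
  of the argmax prediction.
* **FID**: Gaussians are fitted to features of the two image sets;
  the default extractor is a fixed-seed two-layer random-convolution
  embedding (64-D: per-map mean and standard deviation), so values are
  comparable only within one extractor instance. The matrix square
  root uses `scipy.linalg.sqrtm`; imaginary noise from rank-deficient
  products is clipped and its magnitude recorded.
* **DeLong**: paired/correlated variant using placement-value
  empirical covariances; var(Δ) = Σ₁₁ + Σ₂₂ − 2Σ₁₂; zero variance with
  equal AUCs yields p = 1 by convention.
* **Holm–Bonferroni**: standard stepdown over the *full* set of
  pairwise comparisons (C(k, 2) for k models); cells are marked ** for
  adjusted p < 0.01, * for < 0.05, else ns.

Calibration of this machinery is verified by simulation: the paired
DeLong type-I error under a correlated equal-AUC null (1000 datasets,
n = 200) lies in [0.03, 0.07]; the single-model DeLong variance agrees
with a 2000-rep bootstrap within 25 %; the 95 % bootstrap AUC interval
covers the binormal population value Φ(1/√2) in ≥ 90 of 100
replications.

## Study conditions at desk scale

Cohorts: 50 standard-domain patients (≈100 training images) and 140
POCUS patients with test fraction 0.9 (≈28 POCUS training images,
≈250 test images), class mix 0.57/0.21/0.22. The deliberately scarce
POCUS training set is the premise of the design; the large held-out
fraction exists purely to give the paired DeLong comparisons power at
this scale and does not affect any training input. Problem sizes used
by the acceptance checks: combinations {1, 2, 6, 10, 14} (study
property, three whole-study seeds), {1, 2, 5, 6, 10, 14} in the
acceptance script, 25+25 patients per domain for the translation-FID
property, 300/150 images at 64 px for the class-learnability check.

## Determinism and leakage

Every random stage derives its generator from an explicit seed
(`numpy.random.SeedSequence` spawning per stage); repeated runs with
one configuration are bit-identical, and per-combination score CSVs
are cached and reused when an output directory is given. A leakage
audit hashes every test image and asserts that none appears among the
inputs of any fitting stage (histogram pooling, translator training,
classifier training) and that no patient id spans the train/test split.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; paper-scale training
  (180 px, 200-epoch CycleGAN) is supported by the code but slow — the
  desk preset is the practical configuration.
* One pooled histogram per class ignores within-class heterogeneity;
  per-image matching is not implemented.
* FID with the random-convolution extractor is suitable for relative
  comparisons within a run, not for comparison against published
  Inception-based FID values (an Inception backend can be plugged in
  via the `extractor` argument).
* Desk-scale classifier runs occasionally collapse to a single argmax
  class (balanced accuracy ≈ 1/3) while still ranking malignancy
  usefully; the AUC-based comparisons are the robust readout at this
  scale.
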