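# usexpand

Training-data expansion and evaluation for cross-device breast-ultrasound
classification.

Point-of-care ultrasound (POCUS) probes produce darker, noisier B-mode
images than cart-based systems, and labelled POCUS training sets are
scarce. `usexpand` implements a complete, reproducible version of a
common study design for this setting: expand a small POCUS-style
training cohort with images derived from a larger standard-ultrasound
cohort — added as-is, histogram-matched, histogram-equalized, or
translated with a cycle-consistent adversarial network (CycleGAN) —
train a fixed small CNN on each of 16 data combinations, and compare
the resulting classifiers with a shared statistical protocol. Because
clinical breast-ultrasound cohorts are private, the package ships a
seeded synthetic phantom generator that emulates the two-domain,
three-class (normal / benign / malignant), patient-grouped structure of
such data, so the entire pipeline is testable end to end on any machine.

It is aimed at researchers studying domain adaptation and data
augmentation for small medical-imaging cohorts, and at anyone needing
well-tested building blocks for the evaluation statistics below.

## What it computes

* **Phantom cohorts** — Rayleigh speckle (squared magnitude of a
  PSF-smoothed complex Gaussian field) modulated by an echogenicity map
  with lesion insertions: benign = smooth hypoechoic ellipse with
  posterior enhancement; malignant = irregular taller-than-wide region
  (harmonically perturbed boundary) with posterior shadowing; then log
  compression and a device operator (POCUS = gamma compression with
  γ > 1 plus Gaussian noise).
* **Intensity transforms** — pooled 256-bin per-class histograms;
  histogram specification `x → Q_target(F_image(x))`; equalization
  `x → round(255 · F(x))`.
* **CycleGAN** — two ResNet-style generators + patch discriminators,
  least-squares adversarial loss, L1 cycle loss (λ = 10) and identity
  loss (0.5 λ), replay buffer, linear lr decay; one model for all
  classes (`cyclegan1`) or one per class (`cyclegan3`). Built on the
  package's own numpy layer library (`usexpand._nn`) with explicit
  backprop and Adam.
* **Classifier** — five 3×3 conv stages (32, 64, 128, 128, 128) each
  with ReLU, dropout and 2×2 max pooling, then dense 512 → 3 softmax;
  2,028,291 parameters at the 180 px input; class-weighted categorical
  cross-entropy with w_c = N/(K·n_c).
* **Evaluation** — malignant-vs-rest ROC and Mann–Whitney AUC; the
  operating point maximising the Youden index J = Se + Sp − 1 subject
  to Se ≥ 0.90; percentile bootstrap CIs (B = 1000); balanced accuracy;
  Fréchet distance ‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½) between feature
  Gaussians (FID with a pluggable extractor; the default is a fixed-seed
  random-convolution embedding, so no pretrained weights are needed);
  paired DeLong tests via placement-value covariances; Holm–Bonferroni
  stepdown over all pairwise comparisons.

## Worked example

Run a reduced ("desk"-scale, 32 px) study on synthetic cohorts for five
data combinations and print each classifier's test AUC:

```bash
usexpand study run --scale desk --seed 1 --combinations 1,2,6,10,14 --out-dir scratch/study
```

```
combination  1 (P): AUC 0.573 [0.480, 0.673], ACC 0.448
combination  2 (P + US): AUC 0.725 [0.638, 0.805], ACC 0.460
combination  6 (P + CycleGAN3): AUC 0.692 [0.608, 0.769], ACC 0.485
combination 10 (P + US + Aug): AUC 0.792 [0.717, 0.857], ACC 0.333
combination 14 (P + CycleGAN3 + Aug): AUC 0.708 [0.615, 0.795], ACC 0.351
```

Combination 1 trains on the scarce POCUS-style cohort alone (~28
images here) and performs worst; every expanded combination improves
on it, and the Holm-adjusted paired DeLong test flags the difference to
the strongest combination (p ≈ 4·10⁻⁴ on this seed). The out-dir
receives the score CSVs, a JSON report, and three CSV tables
(balanced accuracy/AUC with CIs, sensitivity/specificity at the
constrained Youden threshold with CIs, and the pairwise significance
star matrix). FID confirms the domain translation: on this seed,
standard→POCUS-train distance 0.63 versus 0.02–0.03 for the
CycleGAN-translated images (random-convolution features).

The same machinery is exposed per stage: `usexpand simulate`,
`preprocess`, `histmatch`, `histeq`, `translate train/apply`, `train`,
`predict`, `evaluate`, `compare`, and `study augment-study` (the
three-way augmentation-policy comparison). All stages are importable
as plain functions from `usexpand`.

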