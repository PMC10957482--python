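# Methods

## Overview

`lesionfm` implements lesion-centric self-supervised representation learning
for 3D CT. A convolutional encoder is pretrained with a contrastive
objective on cubic patches extracted around lesion seed points, then adapted
to downstream tasks either by training a linear probe on the frozen features
or by fine-tuning all layers. The package also implements the surrounding
measurement apparatus: classification metrics with bootstrap/permutation
inference, Kaplan–Meier risk stratification with log-rank and Cox tests,
test–retest and simulated inter-reader stability, smooth guided
back-propagation saliency, and a gene-expression association screen. A
synthetic cohort generator supplies CT-like data with known structure so the
entire pipeline is testable without patient data.

## Preprocessing

Volumes are resampled with trilinear interpolation to 1 mm isotropic voxels.
A cubic patch of edge L (50 voxels for the full-size configuration, 24 for
the desk-scale toy configuration) is extracted so the seed lands in the
centre voxel at index ⌊L/2⌋; out-of-volume regions are padded with air
(−1024 HU). Intensities are clipped to [−1024, 2048] HU and mapped linearly
onto [0, 1] (subtract −1024, divide by 3072). Seeds come from the midpoint
of a RECIST diameter or the unweighted centre of mass of a contour mask;
world coordinates are millimetres with a voxel-centre convention and
0-based indices.

## Contrastive pretraining

Two augmented views of each lesion patch form a positive pair; negatives
are (i) the views of the other lesions in the batch and (ii) one random
patch per scan whose window does not overlap the lesion's own window
(uniform over admissible centres by rejection sampling). For n seeds this
yields n positive pairs and n × 2(n − 1) unordered cross-lesion
comparisons. The loss for anchor i with partner j is NT-Xent,

    ℓ_i = −log  exp(cos(z_i, z_j)/τ) / Σ_{k∈N(i)} exp(cos(z_i, z_k)/τ),

averaged over all 2n anchors, with τ = 0.1 and N(i) containing the partner,
the other seeds' views and the negative-patch embeddings (each source
toggleable). Embeddings are L2-normalized outputs of a 2-layer projection
head that is used only during pretraining and discarded for feature
extraction.

Pretraining augmentations: random flips, free rotations (≤20°), scaled
crop-resize (0.8–1.0), Gaussian noise (SD 0.05 of the normalized range),
spatially correlated noise matched to the 2 mm background texture scale
(SD 0.02), and a random monotone histogram intensity shift (PCHIP through
jittered control points, endpoints pinned at 0 and 1) replacing colour
jitter. Gaussian blur and integer translations are implemented and
available but not in the default pretraining set: at the 24-voxel desk
scale both measurably degraded the class information in the learned
features.

The optimizer is momentum SGD with layer-wise adaptive rate control (LARS
trust coefficient 0.005), weight decay 1e−6, linear warmup over the first
20% of steps followed by cosine decay, base learning rate 0.5, batch of 8
positive pairs (gradient accumulation reproduces larger effective batches
when desired). After the last epoch, batch-norm running statistics are
re-estimated with two passes over the unaugmented training patches: during
pretraining the statistics are computed over augmented views mixed with
air-dominated negatives, which otherwise mis-normalizes plain lesion
patches at evaluation time. Recalibration touches no weights and uses no
labels.

## Encoders

All layers (3D convolution, batch-norm, ReLU, max-pool, global pooling,
linear, residual bottleneck) are implemented in numpy with explicit
forward/backward passes, single precision, fully deterministic on one
thread. Two configurations are registered:

* **toy** — three stride-2 conv/BN/ReLU stages (8, 16, 32 channels) on
  24-voxel patches; global average- and max-pooling concatenated → 64
  features. One forward pass takes milliseconds on one CPU core.
* **r3d50** — a 50-layer residual network (bottleneck blocks 3/4/6/3,
  widths 64/128/256/512, expansion 4) on 50-voxel patches; pooled
  2,048-channel map → 4,096 features.

The toy network needed batch normalization to train at all: without it the
projection embeddings collapse to a single direction and NT-Xent sits at
its uninformative plateau log |N(i)|.

## Downstream adaptation

*Features route*: frozen-encoder features feed a multinomial logistic
regression with internal standardization; regularization strength (log-grid
1e−4…1e4) and class weighting are selected by balanced accuracy on a
tuning split. No feature selection.

*Fine-tuning route*: all layers plus a linear head are trained with
cross-entropy, random flips / 90° rotations / integer translations
(±10 voxels at the 50-voxel patch scale, scaled proportionally for smaller
patches), momentum SGD with step-wise learning-rate decay, and best-epoch
selection on the tuning split. Layer-wise adaptive rates are enabled here
too: with plain momentum SGD the numpy network's training loss stays pinned
at ln K because raw gradient magnitudes differ by orders of magnitude
between the first convolution and the head.

The reduced-training-data protocol draws stratified subsets (50/20/10%),
optionally nested, with tuning and test sets untouched. In the bundled
benchmarks each reduced point is the mean over three independent draws.

## Evaluation statistics

Balanced accuracy is the mean per-class recall (argmax rule for K > 2, 0.5
threshold for binary scores); mAP macro-averages one-vs-rest average
precision; AUC is the midrank Mann–Whitney normalization (ties count half).
Confidence intervals are case-resampled percentile bootstrap (B = 1000,
95%); degenerate resamples are redrawn and an error is raised if more than
20% fail. Model pairs are compared with a two-sided label-permutation test
that refits both pipelines per permutation, with add-one smoothing
(p ≥ 1/(n_perm+1)). Survival stratification thresholds the risk score at
the tuning-set median (configurable quantile), plots Kaplan–Meier curves
with Greenwood bands, and tests with the two-group log-rank statistic and
a univariate Cox model (Efron ties) via lifelines. The Wilcoxon signed-rank
test uses the exact null for n ≤ 25 without ties, otherwise the corrected
normal approximation.

## Stability

Test–retest agreement of continuous predictions uses ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from the
ANOVA mean squares; feature reproducibility uses Spearman ρ and R² on
flattened matrices. Inter-reader variability is simulated by perturbing
each seed with independent per-axis normal offsets ("variance 16 voxels"
is read as per-axis variance, SD 4 voxels) over 50 trials by default; the
study reports per-case feature MSE against the unperturbed reference (and
against the trial mean), prediction mean/variance across trials, and a
per-trial discrimination AUC when labels are supplied. For comparisons
*across* models the features can be standardized by their across-case SD,
since raw MSE is scale-dependent.

## Interpretation

Saliency is smooth guided back-propagation: the gradient of the predicted
class logit with respect to the input, with negative gradients zeroed at
every rectifier, averaged over n_noise = 25 noisy copies of the input
(Gaussian, SD 0.1 of the normalized range); absolute values are returned,
signed maps retained. The gene screen keeps genes whose mean strictly
exceeds the overall matrix mean, ranks survivors by SD and keeps at most
500, correlates each gene with per-case predictions (Pearson, on the given
scale), and selects |r| > 0.1; the ranked table is written as TSV for
external enrichment tools. Enrichment analysis itself is out of scope.

## Synthetic cohorts

The generator emulates the statistical structure the method relies on, not
anatomy. Background is mean −800 HU with spatially correlated Gaussian
noise (SD 60 HU, 2 mm kernel), the dynamic range of aerated lung. Lesions
are soft-tissue-density ellipsoids (radius 5–9 mm, offset 720–780 HU above
background — the contrast scale of real pulmonary lesions) with a radial
cosine texture; class identity is carried by texture frequency (0.07, 0.18,
0.35 cycles/mm) and a 30 HU density step between classes. Laminar and
lattice texture arrangements are available for harder phantoms. Survival
cohorts draw exponential event times with log-hazard linear in lesion
radius (closed-form ground truth for Cox/log-rank checks), independent
uniform censoring calibrated by bisection to the requested rate, and a
2-year binary label that is right-censored (None when censoring precedes
730 days). Retest twins apply a small random rigid shift plus fresh
acquisition noise. Expression matrices give a chosen gene subset a known
population correlation with the phenotype, with heterogeneous per-gene
means and scales so the mean/SD filter is non-trivial.

What passing tests show — and do not show. The phantom classes are
separable from texture statistics, so desk-scale results demonstrate that
the pipeline's machinery is correct and that contrastive pretraining
extracts the intended structure; they do not demonstrate transfer to real
anatomy, scanner effects, or class structures that require deep semantic
features. One known inversion: the toy pretrained encoder reads fine
texture phase and is therefore *less* tolerant of large seed displacements
than an untrained encoder's diffuse averages, so the cross-model stability
comparison that holds for the full-size setting does not hold at desk
scale (the within-model properties — zero MSE at zero variance,
monotonicity in variance — do).

## Numerical choices and degenerate inputs

Double precision in all statistics, single precision in networks. Seeds:
every experiment derives per-component generators from one seed via
`numpy.random.SeedSequence.spawn` in a fixed order, so adding a component
never shifts another's stream. Ties in the gene SD ranking and in probe
hyperparameter selection resolve to the first candidate (stable order).
Degenerate inputs raise: empty masks, all-zero paired differences,
single-class labels, zero-norm embeddings, non-positive temperatures.
Patches with even edge centre the seed at index L/2 (documented
asymmetry). The negative sampler falls back to the farthest in-volume
window, with a warning, when no non-overlapping window exists.

## Problem sizes

Bundled benchmarks use 240-volume three-class cohorts (72 mm grids), a
toy encoder on 24-voxel patches pretrained for 20 epochs, survival cohorts
of 160 training / 120 test cases, retest studies of 26 pairs, perturbation
studies of 24 cases × 10 trials, and 1,000-gene expression matrices over
130 cases; these sizes were chosen so a full run completes on one CPU core
in minutes while leaving every statistical contrast detectable.
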