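# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Problem setting

Binary classification of numeric feature tables with label 1 for the
minority (abnormal) class and 0 for the majority class. The regime of
interest is small `N` (tens to a few hundred rows), moderate `M` (8–30
correlated real features) and imbalance ratio `IR = N⁺/N⁻` between about
0.1 and 0.6. In this regime the cost of missing a minority sample is
high, so evaluation centres on G-mean = √(TPR·TNR), F-measure and AUC
rather than accuracy.

## Preprocessing

Features are z-scored with the **training** mean and sample standard
deviation (ddof = 1); constant columns are rejected with an error naming
the column, and missing values are rejected outright (imputation is out
of scope; a table with many missing values should be cleaned upstream).
Because the input is standardized, the covariance `R = X̃ᵀX̃/(N−1)` is the
correlation matrix; its eigenvalues sum to `M` and the contribution rate
of component k is `λₖ/M`. The retained count `M′` is the smallest r with
cumulative contribution ≥ the threshold (default 0.85). The divisor is
the sample count minus one — the standard sample-covariance convention.
Numerical choices: symmetric eigensolver (`eigh`), eigenvalues clipped at
0 before forming contribution sums, and a deterministic sign convention
(largest-magnitude entry of each eigenvector made positive) so fitted
models are reproducible across BLAS builds. Test rows are always
transformed with training statistics; nothing is refit.

## Dynamic GAN oversampler

The whole minority chunk is the GAN's training set. The generator maps
`M′`-dimensional standard-normal noise through one hidden ReLU layer
(default 100 nodes) to a sigmoid output; features are min–max scaled to
[0, 1] before training and inverse-scaled after sampling so the sigmoid
range covers the data. The discriminator uses a two-piece maxout hidden
layer and a sigmoid scalar output. Training alternates full-batch
gradient ascent on `E[log D(x)] + E[log(1−D(G(z)))]` for D with descent
on `E[log(1−D(G(z)))]` for G, at learning rate 0.01 with no momentum
(momentum is available via config). Dropout is applied to the hidden
layers as keep-probabilities (D: 0.9, G: 0.1 by default, both
configurable; inverted-dropout scaling).

**Epoch budget.** The epoch count is the one knob with no principled
default from theory; at full-batch learning rate 0.01 the game needs on
the order of a few thousand steps to move the generator onto the data on
the fixtures used here, so the default is 2000 epochs. Convergence is
monitored through the mean discriminator output on a mixed real+generated
batch: at the optimum `D*(x) = p_data/(p_data + p_g) = 1/2`. Because an
*untrained* discriminator also outputs ≈ 1/2, the early stop only engages
once the mean output has left the 0.5 ± 0.05 band at least once, then
returned and stayed inside it for 10 consecutive epochs (and at least
`min_epochs` = 50 have run). A non-finite loss raises a divergence error
carrying the epoch index.

**Accounting.** The execution count is `num = ⌊N⁻/N⁺⌋`. The balanced set
holds the `N⁺` original minority rows plus `(num−1)·N⁺` generated rows —
one GAN is trained on the minority chunk and sampled for the whole
synthetic budget — so `N′ = num·N⁺ + N⁻` exactly, and the majority rows
pass through bit-identical. With `num = 1` the data is already as close
to parity as the rule can get and is returned unchanged with `ΔIR = 0`.
`IR′ = num·N⁺/N⁻` never overshoots 1 and never decreases.

SMOTE (k = 5 nearest minority neighbours, uniform interpolation on the
connecting segment, default target = parity) is provided as the
comparison oversampler.

## ELM family

`elm_solve` computes the ridge output weights in whichever of the
dual/primal forms inverts the smaller matrix; the two are algebraically
identical (push-through identity) and the equivalence is tested to 1e−8.
Random input weights and biases are Gaussian draws orthonormalized by QR
(columns when nodes ≤ input dimension, rows otherwise); the sigmoid slope
is fixed at 1 since the random weights already set the input scale.

ELM-AE layers solve `min ‖Hβ − X‖² + l1‖β‖₁` by FISTA with step
`1/(2σ_max(H)²)` (the Lipschitz constant of the smooth gradient),
defaults l1 = 1e−3 and 50 iterations. Plain FISTA is not strictly
monotone; the objective is checked to decrease over a 100-iteration
horizon, not per step. The layer's forward map is the transposed
reconstruction weight, `H_k = g(H_{k−1} βᵀ)`.

The multilayer classifier stacks `Q` such layers of `P` nodes and one
supervised decision layer, with

    P = ⌈(1−ΔIR)·N/M + ΔIR·N′/M′⌉,   Q = max(1, ⌈ΔIR·M′⌉).

`Q` is clamped to ≥ 1 because the formula yields 0 for already balanced
data and a model must still exist; in that limit the method degenerates
to a single ELM-AE + ELM pipeline (regression-tested). Ceilings are
evaluated with a 1e−9 guard against floating-point fuzz. The
regularization coefficient `C` defaults to 1 and is exposed everywhere.

W-ELM uses per-sample weights `wᵢ = 1/n_class(i)` (each class receives
equal total weight; the diagonal sums to the number of classes) in the
weighted ridge system. With perfectly balanced classes the uniform weight
`c` simply rescales the effective regularizer — the weighted solution at
`C` equals the unweighted one at `cC` — which is the equivalence the
tests assert. The H-ELM baseline uses 2 feature layers with the
`ΔIR = 0` node count `⌈N/M⌉`, which is also the width given to the
single-layer baselines.

Models serialize to a single JSON file (full-precision floats), and a
round-trip reproduces predictions bit-exactly.

## Metrics and statistics

Confusion counts follow the standard two-class layout with class 1
positive. Metrics with zero denominators are reported as explicit
`None`, never silently 0. ROC is a threshold sweep over distinct scores
(stable sort), AUC the trapezoid integral, which equals the
pair-counting statistic with ties at ½ (tested to 1e−12). Kernel MMD
uses a Gaussian kernel with the median pairwise-distance bandwidth over
the pooled sample by default and the biased V-statistic estimator, so
MMD(X, X) = 0 exactly and the estimate is nonnegative.

The Friedman statistic is the chi-square form
`12N/(k(k+1))·Σⱼ(Rⱼ−(k+1)/2)²` with tie-averaged ranks, referred to
χ²(k−1). Note the chi-square reference is a large-sample approximation:
against the exact permutation null at k = N = 3 its mid-range tail is
off by up to ≈ 0.2, tightening in the far tail — with a handful of
datasets, treat borderline p-values with care (the Nemenyi CD comparison
of average ranks is the decision tool here). Nemenyi critical difference
`CD = q_α√(k(k+1)/(6N))` uses the embedded studentized-range-based table
for k = 2..10, α ∈ {0.05, 0.10}.

## Synthetic benchmark

`make_imbalanced` draws two Gaussian classes in the informative subspace
(equicorrelated within class, default ρ = 0.3), separated by a Euclidean
distance `class_separation` between means; redundant features are
unit-norm random mixes of informative ones plus noise at σ = 0.1
(structure for PCA to find), and noise features are pure N(0, 1).
Defaults — 40 minority vs 160 majority (IR 0.25), 6+3+1 features,
separation 3.0 — emulate the realistic overlapping regime: with the
correlated block the Mahalanobis gap at separation 3.0 caps the Bayes
G-mean near 0.83, so no classifier can look perfect there. The
strongly separated fixture (separation 6.0, Bayes G-mean ≈ 0.97) is used
for end-to-end sanity bounds. Splits are random and stratified by
default (class ratio preserved within one sample; both splits must
contain both classes); a plain-random mode is available.

What the generator does **not** emulate: heavy-tailed or skewed marginal
distributions, discrete/ordinal clinical codes, label noise, missing
values, and batch effects. Passing tests therefore demonstrate the
pipeline's mechanics and its behaviour under controlled Gaussian
imbalance, not performance on any particular clinical dataset.

## Experiment driver and problem sizes

Each Monte-Carlo trial derives its seed from the master seed by a fixed
integer hash, re-splits the data, and refits preprocessing, GAN and
models on the training split only. Averages exclude (and count) trials
where a metric is undefined. The shipped experiments use 20 trials on
200-sample tables — small enough that the full suite and the acceptance
run each complete in well under a minute on one CPU, while the
Monte-Carlo average stabilizes to ±0.01–0.02 in G-mean across master
seeds.

## Known limitations

- The GAN is a minimal fully-connected pair; on very small minority
  chunks (< ~10 rows) its samples are close to smoothed resampling, and
  mode coverage is not guaranteed.
- The 0.5 decision threshold is calibrated by the balanced training
  targets; for unbalanced fits (plain ELM/H-ELM on skewed data) it can
  sit far from the G-mean-optimal operating point — visible in the
  baselines' results, and intrinsic to threshold-at-½ evaluation.
- Binary problems only; multi-class extension is out of scope.
- The Friedman test's chi-square approximation is coarse below ~5
  datasets (see above).
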