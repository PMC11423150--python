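# Methods

## The prediction task

Transcription-factor (TF) ChIP-seq experiments yield, per TF and cell type, a
set of reproducible binding intervals (IDR peaks) and a per-base signal track
(−log10 p-value style coverage). This package treats TF-binding prediction as
*nucleotide-level regression*: a network maps a 600-bp one-hot DNA window
directly to its 600 per-base coverage values. A window's predicted binding
strength is then the *maximum* of its predicted track — the "max-coverage
bridge" that lets a per-base regressor be scored with the same PR-AUC /
Pearson protocol as scalar-output (sequence-level) models.

## Data pipeline

Genomes are tiled into 600-bp windows offset by 100 bp. Windows overlapping an
exclusion list are dropped. A window is *positive* when the fraction of its
bases covered by the peak union strictly exceeds 0.2, *negative* when the
overlap is exactly zero; windows in between are discarded. Negatives are
sampled to match the positives' GC histogram (20 equal-width bins on [0, 1],
per-bin quotas by largest-remainder rounding, deficits spilling to the nearest
bins). Positive targets are `log10(1 + coverage)` per base — the offset keeps
zero-coverage bases at exactly 0 and targets finite — and negatives carry
all-zero targets. Coordinates are 0-based half-open (BED convention)
throughout.

Splits are by chromosome, so test windows never share a chromosome with
training windows. At the desk scale used here (two 100-kb chromosomes per
species), the validation set is a random 15% of the *training-chromosome*
windows rather than a third held-out chromosome: with 30 peaks per
chromosome, a dedicated validation chromosome would leave too few peaks per
split to be useful. The test chromosome remains fully held out, which is the
scientifically load-bearing part of the protocol.

## Architecture

The network is U-shaped:

- **Encoder (= generator)** — three convolutional blocks
  (conv → ELU → max-pool → dropout) with default desk-scale widths
  (24, 24, 32), kernels (15, 5, 3) and pools (5, 2, 2), so a 600-bp window
  maps to a 30-step bottleneck; a bidirectional GRU over the bottleneck
  (re-projected to the bottleneck width by a width-1 convolution) captures
  long-range dependencies; a simple pyramid pooling module (SPPM) mean-pools
  the bottleneck at scales (1, 2, 4), projects each scale with a width-1
  convolution, nearest-upsamples back, and sum-fuses.
- **Connection + decoder (= predictor)** — three up-sample blocks
  (nearest-neighbour upsample by the matching pool factor → batch-norm →
  ReLU → conv), each fused with the same-level encoder feature (the pre-pool
  conv activation) through a refinement residual block (RRB): the skip is
  projected to the common width by a width-1 convolution, added to the
  upsampled decoder feature, then refined by a conv–BN–ReLU–conv residual.
  The output head is a width-1 linear convolution (no final nonlinearity);
  negative predictions are clipped to zero only where a nonnegative track is
  needed (localization scans).

The generator/predictor partition is exact: composing the two reproduces the
full forward pass bit-for-bit, and their parameter sets tile the model's.
Inputs whose length is not divisible by the pool product are right-padded
with zero columns and the prediction trimmed, so any window length is
accepted. An optional fifth input channel carries a log-scaled chromatin
accessibility track.

Published layer widths for this architecture are not fully specified in the
source material; all sizes here are config-exposed, and the desk defaults
were chosen to train in minutes on one CPU while keeping every architectural
element (GRU, SPPM, RRB).

## Training

Per-nucleotide MSE with an L2 penalty on weight tensors (biases exempt;
α defaults to 1e-6, 1e-5 at desk scale). Each epoch uses all positive windows
plus three times as many negatives drawn *without replacement* from a rolling
shuffled pool, so successive epochs cycle through the whole negative set.
ADAM with the learning rate decayed by a fixed factor on a fixed epoch
schedule; the documented full-scale defaults are batch 500, 60 epochs,
lr 1e-3 decayed ×0.9 every 10 epochs, while the desk-scale toy runs use
batch 32, 16 epochs, lr 3e-3 decayed ×0.75 every 6 epochs so the regression
settles. A warm-up stage can train several fresh initializations briefly and
keep the best by validation PR-AUC. The retained checkpoint maximizes
validation PR-AUC + 0.5·Pearson(max) — the two quantities the method is
evaluated on, with classification weighted higher. A Poisson
negative-log-likelihood loss (exp-linked) is available for count-scale
targets. Optional reverse-complement augmentation doubles each batch with
the complemented windows and mirrored targets; it is off by default in the
library and on in the desk-scale recipe — with only 30 training peaks per
world, the un-augmented network memorizes peak contexts instead of the
motif, which shows up as held-out-chromosome fitting performance decaying
while training-chromosome validation keeps improving.

The deep-learning stack itself (reverse-mode autodiff over numpy, conv/GRU/
batch-norm/pooling layers, ADAM) is part of this package (`nldnn.nn`); all
gradients are verified against central finite differences in the test suite.

## Cross-species adaptation

Given a source-species model, the dual-path adversarial stage freezes the
source generator G_s and the predictor, initializes a target generator G_t
from G_s, and trains a species discriminator D against G_t:

- D minimizes −E[log D(G_s(X_s))] − E[log(1 − D(G_t(X_t)))] (source
  features labeled 1, target features labeled 0);
- G_t minimizes the inverted-label loss −E[log D(G_t(X_t))].

X_s are source binding (positive) windows; X_t mixes arbitrary target-species
training windows with a proportion p ∈ {0, 0.001, 0.1, 0.5, 1} of target
binding windows (desk default p = 0.1). Per round, the discriminator takes
`d_steps` updates on feature maps cached once per round (both generators are
frozen while D trains, so features need computing only once), then G_t takes
`g_steps` updates with D frozen. ADAM uses betas (0.5, 0.9), weight decay
1e-5; gradients are value-clipped (default 0.05). The documented full-scale
update ratio is 1400:1; the ratio is data-scale-dependent, so desk runs use
100:1 with up to ~10 rounds. Training stops when the target-validation PR-AUC
(through the frozen predictor) fails to improve on the previous round, after
a configurable burn-in (`min_rounds`, desk default 6): a desk-scale round is
a single generator update, so judging the stopping rule from round one would
abort before the generator has moved at all. The best-round G_t is returned
(the unadapted generator if no round beats the starting point), and a hash
check guarantees G_s is untouched.
Early stopping here uses a small labeled target validation split — the
synthetic truth makes one available; an unsupervised alternative
(discriminator-loss plateau) can be substituted via config when no target
labels exist.

The discriminator sees only the bottleneck feature map (not the skip
features) — the minimal reading of a single feature stream entering it; this
is config-overridable in principle and noted as an open modeling choice.

A transfer-learning baseline (global-average-pool → FC → ReLU → FC → sigmoid
species classifier on the generator bottleneck; generator at lr 1e-5, head at
1e-3) provides the non-adversarial comparison.

## Synthetic study conditions

The synthetic module generates everything the pipeline consumes. Defaults —
the conditions under which all self-tests run:

- Two species, two chromosomes × 100 kb each, 60 peaks total.
- Background: order-2 Markov chains from species-specific 3-mer tables
  (species A GC-rich ~0.60, species B AT-rich ~0.38), plus a species-private
  repeat element (31–32 bp) inserted at rates 0.03 (A) / 0.08 (B) outside
  peaks.
- Motif: one shared 12-bp PWM (0.92-sharp random consensus). Each peak holds
  a homotypic cluster of 4–12 instances sampled from the PWM (strand uniform,
  reverse complement planted on minus), two of them anchored in the peak-edge
  strips so that *every* window passing the 0.2-overlap labeling rule
  contains at least one complete motif — without this guarantee, edge-overlap
  positives carry no sequence signal and cap attainable PR-AUC well below 1.
- Coverage: per peak a Gaussian bump (σ = halfwidth = 120 bp, truncated at
  ±3σ) with amplitude interpolating (4, 30) in the cluster copy number —
  binding strength is motif multiplicity, so the regression target is
  genuinely sequence-predictable — plus N(0, 0.4) noise truncated at zero.
- The species-B repeat embeds a *one-mismatch decoy* of the motif consensus.
  Within species B the decoy is abundant, fixed-context background the model
  learns to discount; a model trained on species A has never seen it labeled
  negative and scores it like a true site. This is the mechanism that makes
  cross-species transfer measurably worse than within-species performance —
  the species-specific context feature the adversarial stage must overcome.
  (A two-mismatch decoy proved too weak: whether it fooled the source model
  depended on that model's calibration, making the cross-species gap
  unreliable across seeds.)
- Variant sets: positives substitute one base inside a planted motif
  instance; each defines an LD group with negatives substituted at
  non-motif bases within an LD radius (default 500 bp).

What the generator does *not* emulate: read-level noise (no FASTQ/BAM),
population LD structure beyond positional proximity, chromatin-state
heterogeneity, cell-type-specific binding, or the long-tailed peak-strength
distributions of real ChIP-seq. Passing the self-tests therefore shows the
machinery is correct and the adaptation mechanism behaves as designed under a
controlled domain gap — not that the desk-scale model matches ENCODE-scale
performance on real genomes.

## Evaluation protocols

- **Classification**: per-window maxima of predicted and true coverage,
  PR-AUC by step interpolation of the precision–recall curve (equivalently,
  the average-precision sum) and ROC-AUC (Mann–Whitney U normalization).
- **Fitting**: Pearson of per-window maxima over positive windows, and of
  concatenated per-base values over positive windows ("all nucleotides" is
  scoped to positive windows, consistent with the positive-sequence fitting
  protocol).
- **Binding strength**: per-peak read counts (≥1-base overlap counts a
  read; duplicate reads are distinct), log10(1+count), correlated with
  per-peak coverage maxima.
- **Variant effects**: windows centered on the variant (shifted at
  chromosome edges, neighbourhood following the variant); effect =
  Σ|v_alt − v_ref| over ±100 bp (abs mode) or the signed sum (MPRA-style).
  The neighbourhood size is not fixed by the source description; 100 bp is
  the default and config-exposed. ISSM scores all 3L substitutions of a
  window into a 4×L matrix with zeros at the reference base.
- **Localization**: non-overlapping 600-bp tiling, top-1% windows by
  predicted maximum (ties to the leftmost start), intersection ratio against
  peaks, and motif-instance ratio via a PWM scanner whose p-values come from
  an exact dynamic program over the discretized log-odds null (granularity
  1e-3, 0-order background, both strands). The full 600-bp window (not the
  argmax point) is what intersects peaks.
- **Categorization**: tracks are min–max scaled to [−1, 1] then passed
  through a sigmoid; window maxima P (prediction) and T (truth) are
  classified TP (P>0.7 ∧ T>0.7), FP (P>0.5 ∧ T<0.5 ∧ |P−T|>0.5),
  FN (P<0.5 ∧ T>0.5 ∧ |P−T|>0.5), else "other". A constant vector scales to
  0.5. Scaling scope is per scanned vector.

## Interpretation

Kernel-based motif discovery: for each positive test window, the 60-bp
region centered on the predicted-coverage argmax is extracted; each
first-layer kernel scores every stride-1 sub-region and keeps its argmax
sub-region when the activation exceeds 0.5× that kernel's global maximum
over the set; aligned sub-regions form count matrices → PWMs (pseudocount
0.25), dropped below a support threshold. Attribution is
gradient-times-input of the window-maximum scalar — a lightweight
first-order attribution, not a reimplementation of reference-based methods.

## Numerical choices and degenerate inputs

- GAN losses clamp probabilities to [1e-7, 1 − 1e-7] before the log.
- Division-free PR-AUC step handling groups tied thresholds.
- Single-class metric inputs, zero-variance correlations, empty negative
  pools, and chromosomes shorter than one window raise explicit errors (or
  log and degrade where the contract says so).
- PWM columns containing zeros receive a 1e-3 pseudocount before log-odds.
- All randomness flows from named sub-seeds of one master seed; worlds,
  batches, initializations and adaptation runs are bit-reproducible.

## Known limitations

- Desk-scale only: layer widths, epochs, d_steps and genome sizes are far
  below the published experiment scale; absolute metric values are not
  comparable to ENCODE-scale results.
- The numpy engine is single-threaded f64; it favors correctness and
  determinism over speed.
- The adversarial stage's early stopping uses labeled target validation
  data, which real "unobserved species" settings would not have (see above).
- Sequence-level competitor models are represented by one minimal conv
  baseline, sufficient for exercising the bridge protocol only.
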