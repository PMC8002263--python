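# Methods

## Problem and data model

The classifier decides, from a fixed-length window of RR intervals (the
times between successive ECG R-peaks, in seconds), whether the subject is
in congestive heart failure. Input data are per-subject tachograms with a
beat-type annotation per interval: `'N'` for a normal sinus beat, anything
else for ectopic/abnormal beats. The package never touches raw ECG
waveforms; R-peak detection and beat typing are assumed done upstream
(as in the PhysioNet RR-interval databases).

## Preprocessing

Two pointwise filters are applied per subject, in either order (they
commute, and a property test asserts this):

1. drop every interval whose terminating beat is annotated non-`'N'`;
2. drop every interval strictly longer than 2.0 s (peak-detection
   artefacts); the boundary value 2.0 s is kept.

An interval is attributed the annotation of its *terminating* beat — the
simplest consistent beat-to-interval mapping; the alternative of removing
both intervals flanking an ectopic beat would shrink segment counts
slightly but not change the pipeline's structure. Survivors are simply
concatenated (no gap markers or resampling), cut into consecutive
non-overlapping windows of N ∈ {500, 1000, 2000} intervals (trailing
remainder dropped, so a subject yields ⌊len/N⌋ segments), and right-padded
with zeros to M = the smallest multiple of 2^L ≥ N, where L is the encoder
depth. For L = 4 this gives M = 512, 1008 and 2000 — the only rule that
reproduces all three values. Tail padding keeps the physiological sequence
causally intact. RR values are fed in raw seconds;
`segments_to_arrays(..., zscore=True)` offers per-segment standardisation,
but amplitude normalisation is off by default.

`build_dataset` also reports per-class segment counts at three cascade
stages (no filtering / long-interval filter only / both filters), the
bookkeeping used to document preprocessing attrition.

## Architecture

`build_topology(L)` constructs the UNet++ lattice {X(i,j) : 0 ≤ i ≤ L,
0 ≤ j ≤ L−i}: encoder nodes X(i,0) receive the max-pooled (kernel 2,
stride 2 — the choice that actually halves the map and yields the 1/16
bottleneck) output of X(i−1,0); nodes X(i,j>0) receive the channel
concatenation of X(i,0..j−1) and the up-sampled X(i+1,j−1), i.e. j+1
inputs. Up-sampling is parameter-free nearest-neighbour repetition by
default; a learned variant (zero-interleave + convolution) is available as
`upsample_mode="conv"`.

Convolution blocks come in three kinds (`block_kind`):

- `residual` — Conv1D→BN→ReLU→Conv1D→BN, additive shortcut from the first
  convolution's output, final ReLU. Because the shortcut is the first
  convolution's output it always has the block's output width, so no
  projection is needed.
- `se_residual` (default) — the same block with a squeeze-and-excitation
  gate on the residual branch: global average over time, a bottleneck of
  width max(c/r, 1) with ReLU, expansion back to c, logistic squashing;
  the (0,1) gate rescales the branch per channel before the shortcut
  addition. Setting the gate identically to 1 reduces the block bit-for-bit
  to `residual` (tested).
- `inception` — parallel convolutions of widths {1, 3, 5} plus a
  length-preserving max-pool branch, concatenated and projected 1×1, then
  BN and ReLU.

Defaults: depth L = 4, channels (16, 32, 64, 128, 256), kernel width 3,
SE reduction r = 16. The activation inside blocks is the rectifier and the
order is Conv→BN→activation; neither is dictated by the architecture's
published description, both follow standard practice.

The head global-average-pools X(0,L) per channel, batch-normalises the
pooled feature vector, and applies a single zero-initialised logistic
unit. Two deliberate stabilisation choices live here:

- *Zero-initialised head*: the untrained network scores every input
  exactly 0.5, so early training moves the two classes symmetrically
  around the decision threshold instead of starting from an arbitrary
  offset.
- *BN on the pooled features*: ReLU'd GAP features are all-positive, so
  any head-weight step Δw shifts the mean logit by Δw·ḡ — a systematic
  drift that the scalar bias (whose Adam step is capped at the learning
  rate) cannot cancel in a short run. Centring the head input removes the
  drift term; in long runs it is a no-op for expressiveness.

Training mode uses batch statistics in BN and seeds the running averages
with the first batch seen (rather than (0, 1)), so evaluation mode is
sensible even after very few updates; evaluation mode is fully
deterministic.

## Optimisation protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), mean-squared-error loss between the
logistic score and the {0,1} label, batch size 16, 70 epochs, initial
learning rate 1e−4 multiplied by 0.1 whenever the inner-validation loss
fails to improve for 5 consecutive epochs (patience counter resets on each
cut; the rate is non-increasing). Shuffling, weight initialisation
(He/variance-scaling for convolutions, zeros for biases) and fold
assignment all derive from one documented seed; reruns are bit-identical.

## Evaluation

Subject-wise k-fold (default k = 10): subjects are permuted within each
class and dealt round-robin into k parts, so parts are class-balanced and
sizes differ by ≤ 1. Per fold, one part is the untouched test set; ~10% of
the remaining subjects (at least one per class where possible, never
starving the training side of a class) form an inner validation set that
drives the plateau schedule — using the test fold for scheduling would
leak. Leakage-freedom is asserted programmatically on every run. All folds
start from the identical seeded initialisation, which keeps the fold score
distributions commensurable when pooled.

Metrics from pooled and per-fold confusion counts (score ≥ 0.5 ⇒ CHF;
ties positive): accuracy (TP+TN)/n, recall TP/(TP+FN), precision
TP/(TP+FP), F1 = 2PR/(P+R), each defined as 0 when its denominator is 0.
ROC is a full threshold sweep and AUC its trapezoidal area (equal to the
positive-over-negative pairwise-win probability with ties counted half;
the test suite checks this against exhaustive pair counting). The ROC/AUC
computation is delegated to scikit-learn; the confusion-count formulas are
evaluated directly.

## Synthetic cohorts

`generate_subject` draws an AR(1) tachogram x_t = μ + φ(x_{t−1} − μ) + ε_t
with innovation variance σ²(1 − φ²), so the stationary SD equals the
configured SDNN; values are clipped below at 0.2 s. Ectopic annotations
and uniform (2, 3] s pauses are injected at per-beat rates 0.01 and 0.005
(both classes), so the cleaning filters always have work. Class profiles:

| class | mean RR (s) | SDNN (s) | φ (lag-1 AR) |
|---|---|---|---|
| NSR-like | 0.90 | 0.060 | 0.90 |
| CHF-like | 0.65 | 0.015 | 0.30 |
| AF-like | 0.75 | 0.120 | 0.05 |

These encode the clinical HRV contrast (CHF: faster, flatter tachogram;
AF: highly irregular, nearly uncorrelated) at the level of first/second
moments and lag-1 autocorrelation only. The classes are separable by
per-segment mean alone, by construction. Consequently, passing the
end-to-end recovery test demonstrates that the pipeline — filtering,
segmentation, subject-wise splitting, training, calibration, pooling — is
wired correctly; it says nothing about performance on real cohorts, where
class overlap, inter-subject variability and nonstationarity dominate.
AR(1) was chosen over point-process HRV models because its moments are
analytic, which makes the statistical test bounds exact.

Per-subject seeds spawn deterministically from the master seed; changing
the master seed changes every series.

## Problem sizes

The test suite and the acceptance script run the full-width network
(channels 16–256) only for the scaled-down recovery experiment — a
20-subject cohort of 1500 beats each, n = 500, 2-fold CV, 10 epochs
(≈ 30 s on one core) — and use a depth-2, few-channel configuration for
unit-level training tests. The numerical engine is float64 throughout,
and every operator's gradient is validated against central differences.

## Known limitations

- Training at the published scale (≈ 18k segments × 70 epochs × 10 folds)
  is possible but slow on the bundled numpy engine; the package targets
  correctness and desk-scale experiments, not GPU throughput.
- The synthetic generator does not model circadian trends, respiratory
  sinus arrhythmia spectra, or NYHA severity grades.
- Deep supervision (multi-output UNet++) is deliberately not implemented;
  only X(0,L) feeds the classification head.
- WFDB ingestion is out of the core contract; any tool that exports the
  two-column text format can feed the pipeline.
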