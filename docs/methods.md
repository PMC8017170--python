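# Methods

`ecgfb` implements a complete pipeline for multi-label classification of
12-lead ECG recordings of variable duration: frame-blocking length
unification, Butterworth denoising, binary-relevance task construction
with under-sampling, a residual CNN + attention-BiLSTM binary classifier,
and the matching evaluation suite.  A template-based synthetic generator
makes every stage exercisable without any external data.

## Frame blocking

Clinical ECG records have non-uniform duration, but convolutional
classifiers want a fixed input shape.  Rather than truncating or
zero-padding to a fixed length, each record of `S_l` samples is cut into a
fixed number `F_n` of frames of fixed length `F_l`, with the start-to-start
lag (frameshift) adapting to the record:

    F_s = (S_l - F_l) / (F_n - 1),        f_o = F_l - F_s

where `f_o` is the overlap shared by consecutive frames.  The defaults are
`F_l = 2000` samples (4 s at 500 Hz) and `F_n = 10`, so a 40-s record tiles
exactly (`F_s = F_l`, `f_o = 0`), shorter records overlap their frames and
retain every sample, and longer records sample uniformly with gaps.  Each
record becomes a tensor of shape `(F_n, F_l, n_leads)`.

Numerical choices:

* `F_s` is fractional for most `S_l`.  Frame starts are computed as
  `round(i * F_s)` for `i = 0 .. F_n-1`, which anchors the first frame at
  sample 0 and the last frame's end exactly at `S_l` while deviating at
  most half a sample from the ideal grid.  Flooring instead would shave
  off the record tail, defeating the point of the method.
* Records shorter than one frame (`S_l < F_l`, impossible in a CPSC-like
  corpus where the minimum is 6 s = 3000 samples, but legal input) are
  right-padded with zeros to `F_l` and emit `F_n` identical frames
  (`F_s = 0`).
* Records longer than `F_n * F_l` give `F_s > F_l`, i.e. negative
  overlap; this is allowed — the frames then uniformly subsample the
  record.

The comparison baseline (`pad_or_truncate`) unifies to a fixed 20,000
samples (40 s): keep the first 20,000 or append zeros.  For a like-for-like
model input, the baseline tensor is the exact non-overlapping tiling of the
padded/truncated record into the same `(10, 2000, leads)` shape.

## Denoising

Diagnostic ECG energy lies roughly between 0.1 and 35 Hz; powerline
interference, muscle artefact and much of the baseline-wander spectrum lie
outside it.  Each lead is filtered independently with an 8th-order
Butterworth lowpass at 35 Hz.  Whether the original protocol applied the
filter causally or zero-phase is not derivable from its description; the
default here is zero-phase forward–backward application (no phase
distortion of QRS morphology; the effective magnitude response is |H|²),
with a causal single-pass option.  An optional 0.1-Hz highpass (default
off) is available for explicit baseline-wander removal.

## Class balancing and splitting

Each abnormality is treated as an independent binary problem (binary
relevance): a record is a positive example for every label it carries, and
a multi-label prediction is the union of the per-class positive calls.
Because abnormal classes are rare, each binary task is balanced by random
under-sampling of the majority class to a 2:1 majority:minority ratio —
all minority records are kept, `floor(2 * n_minority)` majority records
are drawn without replacement.

Balanced tasks are partitioned 64 % / 16 % / 20 % into train / validation
/ test.  Fractional sizes are resolved by largest-remainder rounding
(preserves the total, minimises deviation).  Splitting is stratified by
default so the 2:1 ratio survives into each partition within one record
per class — without this, tiny minority classes can produce positive-free
test sets.  Splitting is record-level: all frames of one record share its
partition, so no signal leaks between train and test.  5-fold
cross-validation follows the same policy: balance once globally, then fold.

## The classifier

One binary classifier per class.  The CNN trunk is applied to each of the
`F_n` frames with shared weights:

    Conv1D(32, k=16, s=2) -> BN -> ReLU -> max-pool(3)
    -> residual block 1: Conv1D(32, k=7) -> BN -> ReLU -> Conv1D -> BN,
       identity shortcut added before the output ReLU
    -> residual block 2: Conv1D(64, k=5, s=2) -> BN -> ReLU -> Conv1D -> BN,
       with Conv1D(k=1, s=2) + BN on the shortcut to match channels/stride
    -> global average pooling  (one 64-dim embedding per frame)

The trunk has 13 layers under the convention used throughout this package:
6 convolutions + 6 batch-norms + 1 max-pool; global average pooling is
counted as the interface to the sequence model.  The `F_n` embeddings form
a length-10 sequence consumed by a bidirectional LSTM (64 units per
direction); additive attention (`e_t = v·tanh(W h_t + b)`, softmax
weights) pools the BiLSTM outputs into a context vector; a single sigmoid
unit yields the class probability, trained with binary cross-entropy.
A probability equal to the decision threshold (default 0.5) is called
positive.

The per-layer sizes, optimizer and schedule are this package's own
defaults, declared in `ModelConfig` and fully overridable: Adam at 1e-3,
batch 32, early stopping on validation loss with patience 5 after a
warm-up floor of 8 epochs.  The warm-up exists because eval-mode
validation loss is computed with batch-norm running statistics, which are
unreliable during the first epochs; stopping on that signal too early can
leave a model that ranks perfectly but is miscalibrated around the 0.5
threshold.

The network is implemented as a compact NumPy layer library with
hand-written forward/backward passes (`ecgfb.nn.layers`), verified by
finite-difference gradient checks in the test suite.  All arithmetic is
float32; initialisation, shuffling and under-sampling are seeded, so runs
are bit-reproducible on one thread.  Attention form is additive with a
learned query; dot-product attention would be a drop-in alternative but is
not needed at sequence length 10.

## Evaluation

Per class: precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1 (harmonic
mean).  Any 0/0 is defined as 0 and flagged, keeping macro averages
defined when a rare class gets no positive calls.  Macro averages are
unweighted means over classes.  ROC curves sweep the threshold over unique
scores; AUC is trapezoidal and, with ties given half credit, equals the
probability-of-correct-ranking statistic (verified against an exhaustive
pairwise oracle in the tests).

Preprocessing arms are compared with the two-sided Wilcoxon signed-rank
test on paired per-class F1 scores.  Zero differences are dropped,
absolute differences midranked; for up to 25 retained pairs the exact
tie-aware null distribution is enumerated by dynamic programming over all
2^n sign assignments, above that a tie-corrected normal approximation with
continuity correction is used.

## The synthetic generator

Records are sums of per-beat templates (Gaussian P wave, triangular QRS
with small Q/S dips, Gaussian T wave) repeated at stochastic RR intervals
and projected onto 12 leads by fixed gain/polarity vectors.  Each class
perturbs its defining feature: AF — RR coefficient of variation 0.30 and
absent P waves (normal: 0.02); I-AVB — PR 0.30 s (normal 0.16 s);
LBBB/RBBB — QRS width 0.15/0.14 s (normal 0.08 s) with polarity flips on
lateral/right-precordial leads; PAC/PVC — 18 % premature narrow/wide
beats; STD/STE — ST offsets −0.18/+0.22 mV.  Noise adds baseline wander
(0.10 mV at 0.25 Hz), powerline (0.05 mV at 50 Hz, the mains frequency of
the corpus the defaults emulate) and white noise (0.02 mV).  Corpus-level
defaults mirror the emulated corpus: 500 Hz, 12 leads, durations uniform
over 6–60 s, imbalanced class mix with Normal as the remainder, and a
compatibility table restricting second labels to clinically co-occurring
pairs (Normal never co-occurs).

This is a template synthesiser, not a biophysical simulator.  Classes are
separable by their defining statistic essentially without error, noise is
stationary and additive, leads are perfectly correlated up to gain, and no
electrode artefacts, drift nonstationarity or inter-patient variability
exist.  Passing smoke experiments therefore demonstrates that the pipeline
is wired correctly and can learn constructed class structure — not that it
reaches any particular accuracy on clinical recordings.

## Problem sizes of the shipped experiments

The package's own experiments are sized for a single CPU: the
separability smoke run uses 200 records (AF vs Normal, 1:1), the
reduced-width model preset (12/12/24 filters, 16 LSTM units) and 12
epochs, reaching held-out F1 of 1.0 in about a minute; the
preprocessing-comparison demonstration uses 24–36 records and 2–3 epochs,
since its contract (identical splits between arms, a finished paired
report) is structural rather than score-based.  The full-width defaults in
`ModelConfig` remain available for larger runs.

## Known limitations

* The NumPy training loop is single-process and unsuited to corpus-scale
  training; it exists to make the full method executable and testable
  end-to-end.
* Exact per-layer hyperparameters of the original architecture are not
  public; the defaults here are reasonable placeholders, not a claim of
  equivalence.
* The MAT+header reader implements a minimal CPSC-style dialect (variable
  `val`, `#Dx:` label line), not full WFDB header parsing.
* `paired_wilcoxon` requires at least five pairs and rejects all-zero
  difference vectors rather than returning p = 1.
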