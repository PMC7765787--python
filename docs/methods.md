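# Methods

## Problem setting

The package classifies *records* — long multi-channel monitoring time series
(minutes of single-lead ECG, structural vibration data, and the like) that
carry a single reference health-condition label — under three difficulties
that are typical of real monitoring data:

1. **Class skewness.** Unhealthy conditions are rare, so record labels are
   heavily imbalanced.
2. **Noisy segments.** A record-level label does not hold uniformly over the
   record: stretches may be dominated by signal noise, or show another
   condition's morphology (label noise at the segment level).
3. **Interpretability.** A bare class prediction is not a decision basis; the
   clinically meaningful quantities behind it (presence of a secondary
   waveform deflection, inter-beat regularity, pulse amplitude, ...) should be
   predicted alongside.

## Pipeline

### Skewness-aware augmentation

Records are cut into segments of width `W` by a sliding window whose stride
depends on the class frequency of the record's label:

    S_c = ceil(M * n_c / max_c' n_c')

where `M` is the maximum stride threshold and `n_c` the number of training
records of class `c`.  The most frequent class slides by exactly `M`; rare
classes slide proportionally less and therefore yield proportionally more
segments, rebalancing the augmented training set without resampling or
reweighting.  Records shorter than `W` are zero-padded at the end; windows
never overhang the record end.  A class with zero training records keeps the
maximum stride (the formula is otherwise undefined; such a class generates
nothing but keeps the output simplex dimension fixed).  At prediction time the
stride is a fixed `test_stride` because labels are unknown.

Each segment is further sliced into `ceil(W/N)` fragments of width `N` (the
last one zero-padded when `N` does not divide `W`), which form the sequence
steps of the recurrent layer and the unit of knowledge regression.

### Segment classifier

A residual convolutional-recurrent network: each fragment passes through a
shared 1-D convolutional trunk (stem convolution plus `n_residual_blocks`
two-convolution residual blocks with identity shortcuts; max-pooling by
`pool_factor` after the stem and the first two blocks widens the receptive
field past one beat period) and is summarised by per-channel (mean, max, sd)
pooling statistics.  The fragment-feature sequence, in temporal order, feeds a
bidirectional LSTM; the concatenated final states of both directions go
through a dense softmax layer.  Training minimises the softmax cross-entropy
with Adam.

The network is implemented directly on numpy via a small in-package
reverse-mode autodiff engine (`kmargin._autodiff`) providing exactly the
operations the model needs; all gradients are verified against central finite
differences in the test suite.  Depth and width are configurable; the
defaults are deliberately small (4 residual blocks, 8 channels) so that
desk-scale experiments train in seconds per epoch on one CPU — the framework's
correctness does not depend on full-scale depth.

### Margin filtering

For a segment with class probabilities `p`, the *uncertainty margin* is
`second_max(p) − max(p) ∈ [−1, 0]`; more negative means the model separates
its top two hypotheses more decisively.  The top-K selection iteratively
removes the current minimum-margin segment K times, which is equivalent to a
stable sort by `(margin, index)` — the tie-break toward the lower segment
index makes the procedure deterministic.  `K` larger than the number of
segments clamps rather than errors, since short records legitimately produce
few segments.

During training the selection is gated: with `α` the mean top-1 probability
over all of a record's segments, the loss is restricted to the record's top-K
segments only when `α > 0.5` (strictly); otherwise all segments are used,
because an unconfident model's selection is not yet trustworthy.  The gate
and selection are recomputed from the current model state at the start of
every epoch.  The classification loss is the mean negative log-likelihood
pooled over all selected segments (per-segment probabilities clipped at
1e-12); pooling the mean over segments rather than nesting per-record means
keeps the loss well defined when records contribute different selection
sizes.

### Record-level diagnosis

At prediction time the record label is the majority class of the one-hot
votes of its top-K most confident segments.  A vote tie breaks toward the
tied class holding the single most confident segment, then toward catalog
order.  The margins can optionally weight the votes, but the default is
unweighted counting with margin tie-breaking.  The per-record *extra*
inference cost of the interpretable variant is exactly `ceil(W/N) × K`
fragment passes through the knowledge head (60 at the full-scale defaults
W=6000, N=300, K=3), verified by instrumentation.

### Knowledge-level interpretation

A regression head shares the convolutional trunk tensors with the classifier
(the same objects, not copies) and maps each fragment's pooled trunk features
through a small dense stack to `F` domain attributes under mean-squared
error.  Fragment predictions pool column-wise into segment features and —
over the top-K confident segments only, so noisy segments do not leak into
the record-level account — into one record vector.  Three aggregators are
provided, matched to an attribute's nature: `max` for presence-style flags,
`mean` for levels, and `cv` (population sd / |mean|, the dispersion
coefficient; 0 for constant input, NaN sentinel with a log entry when the
mean is zero with unequal values).  The joint objective is the plain sum of
the classification and interpretation terms (a config weight `λ`, default 1,
is exposed for real tasks that need balancing).

Reference knowledge values are z-scored per feature before the MSE so that
attributes of different units contribute comparably; the means and scales are
stored with the checkpoint and inverted at prediction time.

## Synthetic data

The generator emulates exactly the structure the method assumes, no more:

* Three classes: `regular` (fixed inter-beat interval, Gaussian main pulse of
  amplitude ~N(1, 0.1), and a smaller secondary deflection 0.12 s before each
  pulse — the "P-wave" analog), `irregular` (strongly jittered intervals,
  sd 0.2 s on a 0.5 s period, no deflection), `noise` (broadband noise,
  no beats).  Default skew 0.6/0.3/0.1.
* Baseline noise (sd 0.05) everywhere plus sporadic 0.3 s noise bursts.
* **Injected noisy spans**: with fraction `ρ > 0`, one contiguous span of
  `ρ × length` is rewritten with a different class's morphology while the
  record label is unchanged.  Spans are contiguous, not i.i.d. per sample,
  to reproduce the consecutive-segment label-noise phenomenon seen in real
  monitoring records.
* Knowledge ground truth per fragment — deflection presence (0/1),
  inter-beat-interval cv, mean pulse amplitude — is computed analytically
  from the generation parameters (beat times, amplitudes, placed
  deflections), never estimated from the waveform, so interpretation tests
  have exact references.

A rule-based morphology oracle (roughness threshold for broadband noise,
matched peak detection plus a pre-beat deflection test) classifies clean
segments with ≥ 95 % accuracy, certifying that the learning task is solvable
and that filtering effects measured on it are meaningful.  What the generator
does **not** model: real ECG morphology beyond one pulse family, baseline
wander, sensor artefacts, inter-patient variability, multi-channel
correlation structure.  Passing tests show the method behaves as designed
under its own assumptions, not clinical performance.

## Desk-scale profile and experiment sizes

Self-contained experiments run on a proportionally scaled profile chosen so
that the full multi-seed suite trains on one CPU in minutes: 100 Hz records
of 30–45 s, window W = 1500 (15 s), fragment N = 300 (five fragments per
segment), maximum stride threshold 500 and test stride 300, a 2-block
8-channel trunk with 12 recurrent units, Adam at 3e-3, batch 64, 8 epochs.
The full-scale defaults (W = 6000, M = 500, N = 300, test stride 300, K = 3)
remain the package defaults and are used as-is for the inference-cost check.

* **Noise robustness**: 200 training / 100 held-out records, ρ = 0.3, K = 3,
  five seeds; the comparison is the median record-level macro F1 of
  margin-filtered training + top-K voting versus training on all segments +
  voting over all segments.  Both arms train with Adam 1e-3 for 14 epochs:
  the α gate is confidence-driven, so the learning rate must be slow enough
  that the gate opens only once the model is mature — with aggressive
  optimization the gate can open after a single epoch and freeze training
  onto a tiny confidently-selected subset, collapsing the filtered arm.
  Because the injected spans are *clean* other-class morphology (the hardest
  case for confidence-based filtering — such segments are selected
  confidently, not rejected), the training-side gain is modest and the bulk
  of the filtered arm's advantage comes from top-K voting at prediction
  time.
* **Knowledge recovery**: 100 training / 40 held-out records, joint loss,
  three seeds, 30 epochs, with a wider trunk (16 channels, 32 hidden units in
  the head, Adam 5e-3) because the regression needs more capacity than the
  plain classifier; measured as held-out fragment-level MAE in standardized
  units, compared after one epoch versus at the budget.

## Numerical choices

* Margin ties → lowest segment index; vote ties → most confident tied class,
  then catalog order; `argmax` ties inside one-hot conversion → first class.
* α threshold is strict (`> 0.5`); a record at exactly 0.5 trains on all its
  segments.
* Per-class F1 is `2·diag / (row sum + col sum)`, with 0/0 defined as 0 and
  still averaged; precision uses predicted-class denominators and recall
  reference-class denominators (the conventional assignment).  Macro F1 — the
  headline metric — is unaffected by that convention.
* The cross-entropy clips target probabilities at 1e-12 and logs when it does.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; training traces are bit-reproducible on one
  machine because the epoch loss is the sample-weighted mean (invariant to
  batch order) and numpy kernels are deterministic.

## Known limitations

* The classifier is deliberately small; it demonstrates the framework, not
  state-of-the-art accuracy at full scale.
* The margin filter assumes most of a record matches its label (ρ ≤ 0.5);
  with majority-corrupted records the consistency argument inverts.
* Knowledge attributes are inputs (or synthetic ground truth); the package
  does not extract clinical features from raw physiology.
* The `cv` aggregator is undefined at zero mean with varying input and
  returns a logged NaN sentinel rather than guessing.
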