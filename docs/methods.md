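# Methods

This note records the model, the synthetic data it is exercised on, the
numerical choices, and the limits of what the tests demonstrate.

## Signal model and data contract

A recording is `T × 8` signed 8-bit integers at 200 Hz: the native output
of an 8-electrode consumer forearm armband, zero-centered by the
hardware. The pipeline deliberately performs **no filtering, rescaling or
centering** anywhere — the classifier's input is the raw integer signal
cast to float. Loaders reject (rather than clip) out-of-range or
non-integer values, since silent coercion would mask acquisition faults.

Two canonical on-disk formats exist: a flat CSV (`subject_id, gesture,
recording_ordinal, sample_index, ch1..ch8`) chosen for transparency and
diffability, and a column-binary container (one channel-major int8 file
per recording plus a JSON manifest) for fast loading. Round-trips are
bit-exact in both. The originally published recordings use an
undocumented layout; `read_authors_dataset` is a stub that directs users
to convert to the canonical CSV.

## Windowing and targets

Windows of `look_back = 188` samples advance by `offset = 20` within each
recording; the trailing segment shorter than a window is discarded, and
windows never span recordings (recordings are the unit of subject and
label provenance, so cross-recording windows would leak labels).
The window count `⌊(T − look_back)/offset⌋ + 1` is property-tested
against brute-force start-index enumeration.

Smoothed targets put `ε = 0.01` on each of the 6 incorrect classes and
`1 − 6ε = 0.94` on the correct class. Defining the correct-class mass by
normalization (rather than `1 − ε`) makes every target an exact
distribution, which categorical cross-entropy assumes. Schemes with
`(K−1)ε ≥ 1` are rejected.

## Architecture and numerics

The default stack is two Conv1D layers of 64 filters (kernel 3), max
pooling (window 3), two Conv1D layers of 128 filters, dropout 0.5, two
GRU layers of 150 units with dropout 0.5 after each, and a 7-way softmax
head. Choices where convention had to fill gaps:

- **Padding 'valid', pool stride = pool window (3).** This makes the
  temporal trace explicit (188 → 186 → 184 → 61 → 59 → 57) and is
  asserted in tests; 'same' padding is available in `ModelSpec`.
- **ReLU** for conv layers (standard for Conv1D stacks), configurable.
- **Dropout placement**: once after the second conv block, once after
  each GRU layer; rates are drop probabilities.
- **GRU form**: classic reset-before-matmul candidate,
  `g = tanh(xW + (r∘h)U + b)`, `h' = z∘h + (1−z)∘g`. The first GRU
  returns its full sequence (feeding the second); the second returns its
  final state (feeding the head). The final GRU state is also the
  "penultimate representation" used for embedding export.
- **Initialization**: Glorot-uniform for all weight matrices, zero
  biases, seeded; an untrained model therefore predicts near-uniform
  probabilities, and its cross-entropy on balanced data is ≈ ln 7.

All layers and backpropagation (including BPTT) are implemented on numpy
arrays. Gradients of every parameter tensor are verified against central
finite differences in float64 on a small configuration; the test guards
against ReLU-kink artifacts by asserting a margin between pre-activations
and zero. Forward passes are per-sample, so predictions are invariant to
batch partitioning (checked to 1e−6, the float32 accumulation level);
softmax is computed with max-subtraction for stability.

Training is full backprop with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8),
constant learning rate. The default recipe is learning rate 1e−4, batch
500, 300 epochs. `TrainConfig.reduced()` (learning rate 2e−3, batch 256,
30 epochs) pairs with `ModelSpec.reduced()` (16/16–32/32 conv filters,
two 32-unit GRUs, dropout 0.25) for CPU-scale runs: the higher rate
compensates for the ~10× shorter schedule, and the lighter dropout
matches the much smaller capacity. Non-finite loss aborts with a
diagnostic rather than training onward.

The train/validation split is **temporal within each recording**: the
earliest 75% of each recording's windows train, the latest 25% validate.
Validation therefore shares subjects with training but not moments,
which is the protocol the leave-group-out evaluation assumes;
held-out-subject testing is the only subject-independent measure.

## Cross-validation and metrics

`make_fold_plan` partitions subjects into seeded-random near-equal groups
(sizes differ by at most one; 15 subjects / 5 groups → 3 each). Every
fold asserts train/test subject disjointness at both the subject and the
window level before any window reaches the model. Per-fold model seeds
derive from the train seed and fold id only, so the paired label-scheme
comparison shares folds, windows, initial weights and batch order between
schemes — the encoding is the only varying factor.

Accuracy is window-level (each window one vote), matching per-sample
classification; recording-level majority voting is available but off by
default. Confusion matrices are raw counts plus row-normalized rows
(rows sum to 1 up to one float division per entry, asserted at 1e−12;
empty rows stay zero). t-SNE delegates to scikit-learn on the final GRU
state; it is an export for visual inspection, not part of the method.

## Synthetic generator

The generator emulates the *structure* of the recorded corpus — 8
channels, 200 Hz, int8, one ~10 s recording per (subject, gesture), 15
subjects by default — with a first-order surface-EMG model: zero-mean
Gaussian noise per channel whose standard deviation is

    σ_c(t) = noise_floor + gain · w[(c − rotation) mod 8] · (1 + depth·sin(2πt/period + φ))

The sinusoidal envelope (period 2.5 s, depth 0.3, random phase per
recording) models the instructed arm movement during the hold. Gesture
signatures `w` are fixed random directions around a common mean, scaled
by a **separability** dial; they depend only on the gesture and the dial
(a constant internal seed), never on the dataset seed, so class structure
transfers across independently generated datasets. Random directions
rather than single-channel bumps keep signatures distinguishable under
electrode rotation. Inter-subject variation is a circular electrode
rotation (the electrodes form a ring; default jitter ≤ 1 slot, modelling
roughly consistent donning — wider rotations are supported but make
cross-subject transfer intentionally harder), a log-normal gain
(σ = 0.15), and a uniform noise floor. Scaling uses 24 counts per unit
amplitude, putting ~3σ of the strongest channels near the int8 edge;
quantization clips with logged rate, well under 1% at defaults.

What this emulates: amplitude-coded, spatially patterned, envelope-
modulated multichannel activity with subject-level nuisance variation.
What it does **not** emulate: motor-unit action-potential waveforms and
their spectral content, electrode-skin impedance drift, crosstalk,
fatigue, or gesture transients. Passing tests therefore demonstrate that
the pipeline recovers amplitude-pattern structure across unseen subjects
under controlled nuisance variation — not performance on physiological
recordings.

Streams draw each schedule segment from an RNG keyed by the segment's
absolute index, so a multi-segment stream is bitwise equal to
back-to-back single segments generated with matching indices — the
property that makes end-to-end replay tests exact.

## Real-time path

A circular buffer holds the latest 188 samples; classification happens
only when the buffer is full **and** the debounce interval (default 1 s)
has elapsed since the last emission — the debounce suppresses, rather
than queues, intermediate predictions, and the first event may fire as
soon as the buffer fills. The debounce clock is stream time (sample
timestamps), which makes replayed streams deterministic; a live source
would supply monotonic wall-clock timestamps. The TCP protocol is
one-way, newline-delimited text; the gesture→action assignment
(closed hand→grow, tap→shrink, wrist flexion→backward, wrist
extension→accelerate, neutral→jump) is a configurable default — the
five control gestures and five game actions are fixed, their pairing is
an open choice. No confidence threshold is applied by default (argmax
rules); a minimum-confidence gate is available.

## Problem sizes in the checked experiments

The end-to-end experiments run the reduced model on 8 synthetic subjects
(7 gestures × 10 s each, separability 1.5, ≈ 5,100 windows), training on
6 subjects and testing on 2 entirely held out, 30 epochs — a few minutes
on one CPU. The full-scale default recipe (64/128-filter model, 300
epochs) is intended for real recorded corpora on accelerated hardware.

## Known limitations

- The numpy implementation is single-threaded and CPU-bound; it is built
  for correctness and moderate scale, not GPU throughput.
- Bit-level training reproducibility holds for a fixed BLAS/numpy build;
  across builds, expect agreement only to float precision.
- Accuracy figures on synthetic data characterize the pipeline, not
  human sEMG; the generator's separability dial directly controls task
  difficulty.
- The adapter for the originally published recordings is a stub pending
  a documented layout.
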