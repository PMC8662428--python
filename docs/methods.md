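# Methods

## Problem and model

The task is closed-set user identification: given a fragment of a walking
recording from bilateral smart insoles (6 accelerometer channels at 30 Hz),
decide which of n enrolled users produced it. The defining constraint is
that fragments may be *partial* — shorter than a single step — so no
step-segmentation stage is possible.

The classifier is a stacked LSTM: the first 64-unit layer maps a `T × 6`
window to its full `T × 64` output sequence, the second 64-unit layer
consumes that sequence and emits its final 64-dimensional hidden state,
and one dense layer with softmax maps those 64 features to n class
probabilities. Recurrent (variational) dropout of 0.2 is applied inside
both LSTM layers and ordinary dropout of 0.5 to the 64-vector, during
training only. Ties in the argmax are broken toward the lowest class
index. Because an LSTM consumes sequences step by step, the same weights
score windows of any length; variable-length robustness comes entirely
from the *training distribution*: windows of size `T ~ U{20..200}` at
uniformly random positions within uniformly chosen training recordings.

Training minimizes mean categorical cross-entropy with Adam. Each
mini-batch shares a single window size (drawn per batch), which keeps
tensors rectangular without padding or masking while still exposing the
network to the full size range across batches.

## Implementation and numerical choices

- The network is pure NumPy (`insolegait.nn`): packed-gate LSTM forward and
  backpropagation through time, inverted dropout, Adam. Analytic gradients
  are verified against central finite differences on float64 layers in the
  test suite; training uses float32.
- Weight init: uniform `[-1/√h, 1/√h]`; the forget-gate bias starts at 1
  (standard stabilizer). Initialization, window sampling and dropout draw
  from RNG streams spawned separately from one seed, so changing the
  training length never changes the initial weights.
- Optimizer defaults: Adam, lr 1e-3, β = (0.9, 0.999). Softmax and the
  cross-entropy are computed in float64 with max-subtraction for stability.
- Normalization is a per-channel, per-recording z-score (population SD),
  applied before any windowing. Per-recording scope keeps inference
  self-contained (no training-set statistics leak into a new walk); a
  pooled-statistics mode was considered and rejected for that reason.
  Constant channels raise a degenerate-input error naming the channel.
- Window indexing is 0-based and half-open, `[start, start + T)`; for a
  recording of length L the training size is uniform on
  `[20, min(200, L)]` and the start uniform on `[0, L − T]`.
- Evaluation extracts k = 10 windows of exact size T per test recording at
  uniform random starts (with replacement). Accuracy is per-window — each
  window is one identification attempt — with an optional
  majority-vote-per-recording mode (off by default). Recordings shorter
  than a requested T are excluded from that cell rather than padded;
  padding would fabricate signal. A size with no eligible recording
  reports NaN instead of raising.
- Rendered window durations are T/30 rounded *up* at two decimals, so the
  six test sizes read 0.67, 1.00, 1.67, 3.34, 5.00, 6.67 s.
- Cross-validation is stratified by user at the recording level: each
  user's trials are permuted and dealt into five equal blocks, so a
  16 × 10 study always splits 128 train / 32 test with exactly 2 held-out
  trials per user. Repeats reshuffle with independent seeded permutations.
  Trial counts not divisible by the fold count are rejected rather than
  approximately balanced.

## Synthetic data generator

Real insole data for this task are not distributable, so the package ships
a generator that reproduces the *statistical premises* the method relies
on, not insole biomechanics:

- Each user is a `GaitProfile`: stride frequency (default draw
  U[0.85, 1.05] Hz), walking speed, a per-channel signature of H = 4
  harmonic amplitudes (decaying ~1/k) and phases, a left/right offset in
  [0.45, 0.55] of the stride period, and a noise SD (default 0.2 in units
  of the O(1) harmonic amplitudes).
- A 10 m walk lasts between 7.2 s (216 samples) and 9.6 s (290 samples),
  so admissible speeds span [10/9.6, 10/7.2] m/s. Default profile speeds
  are drawn from the narrowed band [10/9.024, 10/7.632] m/s so that trial
  cadence jitter (Normal(1, 0.02) truncated to [0.94, 1.06]) can never
  push a trial outside the 216–290 sample envelope. Recording length obeys
  L = round(30 · distance / (speed · cadence_scale)) exactly.
- Right-foot channels reuse the left-foot harmonic signature (scaled by a
  per-user asymmetry factor in [0.9, 1.1]) delayed by the left/right
  offset, giving the anti-phase structure of alternating feet; with zero
  noise the zL/zR circular cross-correlation peaks at exactly
  offset × stride period.
- Per-trial variability: multiplicative cadence and amplitude jitter plus
  a uniform stride-phase shift, then white Gaussian noise. The jitter
  magnitudes are a modeling choice (real within-user variability beyond
  length differences is not characterized anywhere we could anchor to) and
  are exposed as tunables.
- The `separation` dial: `"low"` gives all users one shared parameter
  point (labels carry no information — a chance-level control), `"high"`
  spaces cadences on an even grid with independent signatures (a
  separability upper bound), `"default"` draws independently from the
  documented ranges.

What passing tests on this generator do **not** show: robustness to
sensor placement, walking-speed changes, surfaces, footwear, or
session-to-session drift in real populations. The generator's users are
stationary harmonic processes; real gait is not.

## Desk-scale defaults

The full-scale experiment (1000 epochs; five repeats of five-fold
cross-validation) is available as the `full` run profile. The default
`desk` profile — 16 users × 10 trials, 40 epochs × 2048 windows (batch 32),
one fold per analysis in the acceptance script — was sized to train in a
few minutes on a single CPU while leaving every protocol choice (window
range, fold structure, test sizes, dropout rates, layer sizes) untouched.
On default-separation synthetic data it reaches ≈97 % held-out window
accuracy at T = 20 and ≈100 % at T ≥ 30, reproducing the qualitative
accuracy-vs-window-size trend; absolute accuracies on the synthetic study
are higher than on real gait data, because harmonic signatures plus white
noise are easier to separate than real inter-subject variability.

## Known limitations

- No padding/masking path: a forward pass requires T ≥ 1 and one size per
  batch.
- The NumPy training loop is single-threaded per GEMM call and desk-scale
  by design; it is not a GPU-scale trainer.
- Per-window accuracy treats the k windows of one recording as
  independent attempts, which overweights long recordings slightly when
  recording lengths differ (they differ by ≤ 34 % here).
- The chance-level control trains briefly (10 epochs); longer training on
  inseparable data cannot raise expected held-out accuracy but does add
  variance across seeds.
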