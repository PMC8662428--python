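# insolegait

Gait-based user identification from bilateral smart-insole accelerometer
data, **without step detection or gait segmentation**.

Most gait-biometric pipelines first slice a walking signal into individual
steps and then classify the step templates. That pre-processing fails
whenever only *partial* data is available — a fragment shorter than one
complete step. `insolegait` implements an alternative: a two-layer stacked
LSTM is trained directly on raw accelerometer windows of **random size
(20–200 samples, i.e. 0.67–6.67 s at 30 Hz) and random location** within
each walk. A single trained network then scores a window of *any* length in
that range, so identification works on arbitrary signal fragments.

The package is aimed at researchers in wearable biosignal analysis who want
a reproducible, dependency-light (pure NumPy) reference implementation of
this training scheme, together with a synthetic smart-insole data generator
so the whole pipeline is testable without access to private gait recordings.

## Model

Input is a `T × 6` window of z-scored accelerometer channels
(`xL, yL, zL, xR, yR, zR`, 30 Hz). The network is

```
LSTM(64, full sequence, recurrent dropout 0.2)
→ LSTM(64, last output, recurrent dropout 0.2)
→ dropout 0.5
→ dense(64 → n) → softmax over the n users
```

trained with Adam (lr 10⁻³) on categorical cross-entropy. Per training
mini-batch one window size `T ~ U{20, …, 200}` is drawn, then each window a
uniformly random training recording and a uniformly random start — the
random-window scheme is the whole trick; there is no other feature
engineering. The LSTM forward pass, backpropagation through time, dropout
and Adam are implemented in NumPy (`insolegait.nn`) and validated against
finite-difference gradients in the test suite.

Evaluation follows a stratified five-fold protocol over recordings (each
fold holds out an equal number of trials per user), repeated with
reshuffling; accuracy is reported per test window size
`T ∈ {20, 30, 50, 100, 150, 200}` and at the partial-data sizes
`{42, 63, 84}` labeled by their nominal data rates `{26, 39, 52} %`.

## Synthetic data

`insolegait.synth` simulates a 16-user × 10-trial study of 10 m walks: each
user is a latent `GaitProfile` (stride frequency, walking speed, per-channel
harmonic amplitude/phase signature, left/right offset), each trial a sum of
4 harmonics of the stride frequency plus trial jitter and white noise, with
the right-foot channels delayed by half a stride period. Recording lengths
land in the 216–290 sample range of a normal-paced 10 m walk. A
`separation` dial provides a chance-level control (`"low"`: all users share
one parameter point) and a separability upper bound (`"high"`).

## Worked example

```python
import numpy as np
from insolegait import synth, normalize, ModelConfig, build_model
from insolegait.evaluate import make_folds, evaluate_by_window_size

profiles = synth.sample_profiles(16, rng_seed=1)
recordings = [normalize(r) for r in synth.generate_dataset(profiles, n_trials=10, rng_seed=2)]
folds = make_folds(recordings, n_folds=5, rng_seed=3)
by_id = {r.recording_id: r for r in recordings}
train = [by_id[i] for i in sorted(folds[0].train_ids)]
test = [by_id[i] for i in sorted(folds[0].test_ids)]

model = build_model(ModelConfig(n_classes=16, epochs=40, rng_seed=7)).fit(train)
print(evaluate_by_window_size(model, test, rng_seed=5))
```

prints (a few minutes of training on one CPU):

```
{20: 97.1875, 30: 100.0, 50: 100.0, 100: 100.0, 150: 100.0, 200: 100.0}
```

i.e. the identification rate in percent per test window size: with windows
of only 20 samples (0.67 s — less than one step) 97.2 % of the held-out
windows are attributed to the correct user, and from 30 samples (1 s)
upward identification on this synthetic study is essentially perfect. The
one model scores every window size; nothing is retrained per length.

The same pipeline is scriptable from the shell:

```
insolegait simulate --n-users 16 --n-trials 10 --seed 1 --out data/
insolegait run --profile desk --seed 3 --dataset data/ --out results/
insolegait report --report results/report.json
```

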