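"""Stacked-LSTM user-identification network and its training loop.

Architecture: two LSTM layers in series -- the first consumes a T x 6 window
and emits the full T x 64 output sequence, the second reduces it to a single
64-feature vector -- followed by one fully connected layer with softmax over
the n users.  Both recurrent layers use recurrent dropout 0.2 and the final
64-vector dropout 0.5 during training; dropout is disabled at inference.

The network is trained on windows of random size (20-200 samples) cut at
random locations from the training recordings, so a single trained model
scores windows of any length in that range without retraining -- no step
detection or gait segmentation is ever performed.  Each mini-batch shares one
window size (drawn per batch) so tensors stay rectangular; the size varies
across batches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .data import AccelRecording, N_CHANNELS, T_MAX_DEFAULT, T_MIN_DEFAULT, Window


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the desk-scale profile; the experiment described at full
    scale uses ``epochs=1000``.  ``windows_per_epoch`` controls how many
    random windows are drawn per epoch (the full-scale batch count per epoch
    is not reconstructible, so it is an explicit knob here).
    """

    n_classes: int = 16
    hidden1: int = 64
    hidden2: int = 64
    recurrent_dropout: float = 0.2
    final_dropout: float = 0.5
    epochs: int = 50
    windows_per_epoch: int = 2048
    batch_size: int = 32
    learning_rate: float = 1e-3
    t_min: int = T_MIN_DEFAULT
    t_max: int = T_MAX_DEFAULT
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name in ("hidden1", "hidden2", "windows_per_epoch", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        for name in ("recurrent_dropout", "final_dropout"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (1 <= self.t_min <= self.t_max):
            raise ValueError("need 1 <= t_min <= t_max")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class StackedLSTMClassifier:
    """Two stacked LSTM layers plus a softmax head, in NumPy.

    Accepts input windows of any length T >= 1 with 6 channels; the
    variable-length contract is the point of the architecture.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        # weight init and window sampling use separated RNG streams so that
        # e.g. changing epochs never perturbs the initial weights
        ss = np.random.SeedSequence(config.rng_seed)
        init_ss, self._train_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        self.lstm1 = nn.LSTMLayer(
            N_CHANNELS, config.hidden1, rng, recurrent_dropout=config.recurrent_dropout
        )
        self.lstm2 = nn.LSTMLayer(
            config.hidden1, config.hidden2, rng, recurrent_dropout=config.recurrent_dropout
        )
        self.head = nn.Dense(config.hidden2, config.n_classes, rng)
        self.history: list[dict] = []
        self.classes_: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.lstm1.params + self.lstm2.params + self.head.params

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None):
        """Score a (T, B, 6) batch; returns (scores, caches)."""
        H1, c1 = self.lstm1.forward(x, training=training, rng=rng)
        H2, c2 = self.lstm2.forward(H1, training=training, rng=rng)
        feat = H2[-1]  # (B, hidden2): last step of the second layer
        if training and self.config.final_dropout > 0:
            mask = nn.dropout_mask(feat.shape, self.config.final_dropout, rng, feat.dtype)
            feat = feat * mask
        else:
            mask = None
        scores, c3 = self.head.forward(feat)
        return scores, (c1, c2, c3, mask, H2.shape)

    def _backward(self, dscores: np.ndarray, caches):
        c1, c2, c3, mask, h2_shape = caches
        dfeat, g3 = self.head.backward(dscores, c3)
        if mask is not None:
            dfeat = dfeat * mask
        dH2 = np.zeros(h2_shape, dtype=dfeat.dtype)
        dH2[-1] = dfeat
        dH1, g2 = self.lstm2.backward(dH2, c2)
        _, g1 = self.lstm1.backward(dH1, c1)
        return g1 + g2 + g3

    # -- public API -------------------------------------------------------

    def predict_proba_batch(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a (T, B, 6) batch of equal-size windows."""
        if x.ndim != 3 or x.shape[2] != N_CHANNELS:
            raise ValueError(f"expected (T, B, {N_CHANNELS}) input, got {x.shape}")
        scores, _ = self._forward(x, training=False)
        return nn.softmax(scores.astype(np.float64))

    def predict_proba(self, window: Window | np.ndarray) -> np.ndarray:
        """Probability vector of length n for one window (T x 6)."""
        data = window.data if isinstance(window, Window) else np.asarray(window)
        if data.ndim != 2 or data.shape[1] != N_CHANNELS:
            raise ValueError(f"expected (T, {N_CHANNELS}) window, got {data.shape}")
        return self.predict_proba_batch(data[:, None, :])[0]

    def predict_label(self, window: Window | np.ndarray) -> int:
        """Most probable class index; ties broken toward the lowest index."""
        return int(np.argmax(self.predict_proba(window)))

    def fit(self, recordings: list[AccelRecording]) -> "StackedLSTMClassifier":
        """Train on random windows of the given (normalized) recordings.

        Every epoch draws ``windows_per_epoch`` windows: per mini-batch one
        window size T uniform on [t_min, min(t_max, max L)], then for each
        window a recording (uniform among those with L >= T) and a uniform
        start.  Minimizes mean categorical cross-entropy with Adam.
        """
        cfg = self.config
        labels = sorted({r.user_id for r in recordings})
        if len(labels) != cfg.n_classes:
            raise ValueError(
                f"training data has {len(labels)} distinct user labels, "
                f"config expects {cfg.n_classes}"
            )
        self.classes_ = np.asarray(labels)
        label_index = {u: i for i, u in enumerate(labels)}
        lengths = np.array([r.n_samples for r in recordings])
        if lengths.min() < cfg.t_min:
            raise ValueError("all recordings must be at least t_min samples long")
        t_high = int(min(cfg.t_max, lengths.max()))

        rng = np.random.default_rng(self._train_ss)
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        y_all = np.array([label_index[r.user_id] for r in recordings])
        order = np.argsort(lengths)  # recordings sorted by length for eligibility
        sorted_lengths = lengths[order]

        n_batches = max(1, cfg.windows_per_epoch // cfg.batch_size)
        for epoch in range(cfg.epochs):
            losses = []
            correct = 0
            seen = 0
            for _ in range(n_batches):
                T = int(rng.integers(cfg.t_min, t_high + 1))
                # recordings long enough for this T
                first = np.searchsorted(sorted_lengths, T)
                eligible = order[first:]
                idx = eligible[rng.integers(0, eligible.size, size=cfg.batch_size)]
                x = np.empty((T, cfg.batch_size, N_CHANNELS), dtype=np.float32)
                for j, ri in enumerate(idx):
                    rec = recordings[ri]
                    s = int(rng.integers(0, rec.n_samples - T + 1))
                    x[:, j, :] = rec.samples[s : s + T]
                y = y_all[idx]
                scores, caches = self._forward(x, training=True, rng=rng)
                loss, probs, dscores = nn.softmax_cross_entropy(scores, y)
                grads = self._backward(dscores, caches)
                opt.step(grads)
                losses.append(loss)
                correct += int((probs.argmax(axis=1) == y).sum())
                seen += cfg.batch_size
            self.history.append(
                {
                    "epoch": epoch,
                    "loss": float(np.mean(losses)),
                    "accuracy": correct / seen,
                }
            )
        return self

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write weights + config + class labels to one .npz archive."""
        path = Path(path)
        names = ["lstm1_W", "lstm1_b", "lstm2_W", "lstm2_b", "head_W", "head_b"]
        arrays = dict(zip(names, self.params))
        meta = {
            "config": asdict(self.config),
            "config_digest": self.config.digest(),
            "classes": (self.classes_.tolist() if self.classes_ is not None else None),
            "history": self.history,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "StackedLSTMClassifier":
        """Load a checkpoint; refuses archives whose config hash mismatches."""
        with np.load(Path(path)) as npz:
            meta = json.loads(bytes(npz["_meta"].tobytes()).decode())
            cfg = ModelConfig(**meta["config"])
            if cfg.digest() != meta["config_digest"]:
                raise ValueError("checkpoint config hash mismatch: archive corrupted")
            model = cls(cfg)
            for p, name in zip(
                model.params,
                ["lstm1_W", "lstm1_b", "lstm2_W", "lstm2_b", "head_W", "head_b"],
            ):
                p[...] = npz[name]
        if meta["classes"] is not None:
            model.classes_ = np.asarray(meta["classes"])
        model.history = meta["history"]
        return model


# functional aliases mirroring the pipeline vocabulary --------------------

def build_model(config: ModelConfig) -> StackedLSTMClassifier:
    """Construct an untrained network with seed-deterministic weights."""
    return StackedLSTMClassifier(config)


def train(model: StackedLSTMClassifier, recordings: list[AccelRecording]) -> StackedLSTMClassifier:
    """Train ``model`` in place on normalized recordings; returns it."""
    return model.fit(recordings)


def predict(model: StackedLSTMClassifier, window: Window | np.ndarray) -> np.ndarray:
    """Softmax probability vector over users for one window."""
    return model.predict_proba(window)
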