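"""Minimal NumPy neural-network primitives for the stacked-LSTM classifier.

Implements an LSTM layer (forward and full backpropagation through time),
a dense softmax head with categorical cross-entropy, inverted dropout, and
the Adam optimizer.  Everything is plain NumPy so the package has no deep
learning framework dependency; gradients are validated against central
finite differences in the test suite.

Conventions
-----------
Sequences are (T, B, F) arrays: time-major, batch second, features last.
LSTM gate order in the packed weight matrix is i, f, g, o (input, forget,
cell candidate, output).  Recurrent dropout uses a single mask per forward
call applied to the hidden state entering the recurrence, the "variational"
scheme, scaled by 1/(1-p) so inference needs no rescaling.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a (B, C) score matrix."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMLayer:
    """One LSTM layer with packed input+recurrent weights.

    Parameters are ``W`` of shape (input_size + hidden, 4*hidden) acting on
    the concatenation [x_t, h_{t-1}], and bias ``b`` of shape (4*hidden,).
    The forget-gate bias is initialized to 1, a standard stabilizer for
    gradient flow early in training; other weights are uniform in
    [-k, k] with k = 1/sqrt(hidden).
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        rng: np.random.Generator,
        recurrent_dropout: float = 0.0,
        dtype=np.float32,
    ):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.recurrent_dropout = float(recurrent_dropout)
        self.dtype = dtype
        k = 1.0 / np.sqrt(hidden_size)
        self.W = rng.uniform(-k, k, size=(input_size + hidden_size, 4 * hidden_size)).astype(dtype)
        self.b = np.zeros(4 * hidden_size, dtype=dtype)
        self.b[hidden_size : 2 * hidden_size] = 1.0  # forget gate

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Run the layer over a (T, B, input_size) sequence.

        Returns ``(H, cache)`` where H is the (T, B, hidden) full output
        sequence.  ``cache`` holds what :meth:`backward` needs; pass
        ``training=True`` (with an rng) to enable recurrent dropout.
        """
        T, B, _ = x.shape
        hid = self.hidden_size
        dt = self.dtype
        x = x.astype(dt, copy=False)
        if training and self.recurrent_dropout > 0:
            if rng is None:
                raise ValueError("recurrent dropout requires an rng in training mode")
            keep = 1.0 - self.recurrent_dropout
            mask = ((rng.random((B, hid)) < keep) / keep).astype(dt)
        else:
            mask = None

        h = np.zeros((B, hid), dtype=dt)
        c = np.zeros((B, hid), dtype=dt)
        H = np.empty((T, B, hid), dtype=dt)
        gates = np.empty((T, B, 4 * hid), dtype=dt)
        cells = np.empty((T, B, hid), dtype=dt)
        h_prevs = np.empty((T, B, hid), dtype=dt)
        for t in range(T):
            h_prevs[t] = h
            h_in = h * mask if mask is not None else h
            z = np.concatenate([x[t], h_in], axis=1) @ self.W + self.b
            i = sigmoid(z[:, :hid])
            f = sigmoid(z[:, hid : 2 * hid])
            g = np.tanh(z[:, 2 * hid : 3 * hid])
            o = sigmoid(z[:, 3 * hid :])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t, :, :hid] = i
            gates[t, :, hid : 2 * hid] = f
            gates[t, :, 2 * hid : 3 * hid] = g
            gates[t, :, 3 * hid :] = o
            cells[t] = c
            H[t] = h
        cache = (x, H, gates, cells, h_prevs, mask)
        return H, cache

    def backward(self, dH: np.ndarray, cache):
        """Backpropagate through time.

        ``dH`` is the gradient of the loss w.r.t. the full output sequence
        (zero-filled rows for unused outputs).  Returns ``(dx, [dW, db])``.
        """
        x, H, gates, cells, h_prevs, mask = cache
        T, B, hid = H.shape
        dt = self.dtype
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, hid), dtype=dt)
        dc_next = np.zeros((B, hid), dtype=dt)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :hid]
            f = gates[t, :, hid : 2 * hid]
            g = gates[t, :, 2 * hid : 3 * hid]
            o = gates[t, :, 3 * hid :]
            c = cells[t]
            c_prev = cells[t - 1] if t > 0 else np.zeros((B, hid), dtype=dt)
            tanh_c = np.tanh(c)

            dh = dH[t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f

            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            h_in = h_prevs[t] * mask if mask is not None else h_prevs[t]
            inp = np.concatenate([x[t], h_in], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ self.W.T
            dx[t] = dinp[:, : self.input_size]
            dh_prev = dinp[:, self.input_size :]
            if mask is not None:
                dh_prev = dh_prev * mask
            dh_next = dh_prev
        return dx, [dW, db]


class Dense:
    """Affine map (B, in) -> (B, out)."""

    def __init__(self, input_size: int, output_size: int, rng: np.random.Generator, dtype=np.float32):
        k = 1.0 / np.sqrt(input_size)
        self.W = rng.uniform(-k, k, size=(input_size, output_size)).astype(dtype)
        self.b = np.zeros(output_size, dtype=dtype)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, dout: np.ndarray, cache):
        x = cache
        dW = x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.W.T
        return dx, [dW, db]


def dropout_mask(shape, rate: float, rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability ``rate``, else 1/(1-rate)."""
    keep = 1.0 - rate
    return ((rng.random(shape) < keep) / keep).astype(dtype)


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of (B, C) scores against integer labels.

    Returns ``(loss, probs, dscores)`` with ``dscores`` already averaged
    over the batch.
    """
    probs = softmax(scores.astype(np.float64))
    B = scores.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(B), labels] + eps))
    dscores = probs.copy()
    dscores[np.arange(B), labels] -= 1.0
    dscores /= B
    return float(loss), probs, dscores.astype(scores.dtype)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
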