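"""Minimal numpy neural-network engine for the conv-LSTM window classifier.

Implements exactly the pieces the motion detector needs: a 1-D valid
convolution over time, a unidirectional LSTM (last hidden state), linear
dense layers with a terminal softmax, soft-target cross-entropy, reverse-
mode gradients for all of it, and an Adam loop with patience-based early
stopping.  Everything is seeded through ``numpy.random.Generator``; no
threading, so identical seeds give identical runs.

Gradients are verified against central finite differences in the test
suite; keep any change here behind that check.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvLstmNet", "EarlyStopping", "softmax", "soft_cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean cross-entropy of predicted probabilities vs fractional targets."""
    p = np.clip(probs, 1e-12, 1.0)
    return float(-(targets * np.log(p)).sum(axis=-1).mean())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement.

    ``update`` returns True once the monitored loss has failed to improve
    on the best value for ``patience`` epochs in a row.
    """

    def __init__(self, patience: int, min_delta: float = 0.0) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = -1
        self.bad_epochs = 0
        self._epoch = -1

    def update(self, loss: float) -> bool:
        self._epoch += 1
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.best_epoch = self._epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


class ConvLstmNet:
    """Conv(1-D, valid) -> LSTM -> dense stack ending in 2-way softmax.

    Input windows are ``(batch, W, n_channels)``.  The first dense layers
    are linear (no activation); only the final layer applies softmax.
    """

    def __init__(
        self,
        n_channels: int,
        window_len: int,
        conv_filters: int = 32,
        kernel_size: int = 3,
        lstm_units: int = 32,
        dense_sizes: tuple[int, ...] = (64, 32, 2),
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if window_len < kernel_size:
            raise ValueError("window shorter than convolution kernel")
        self.n_channels = n_channels
        self.window_len = window_len
        self.kernel_size = kernel_size
        self.conv_filters = conv_filters
        self.lstm_units = lstm_units
        self.dense_sizes = tuple(dense_sizes)
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        def glorot(*shape):
            fan_in, fan_out = shape[-2], shape[-1]
            if len(shape) == 3:  # conv kernel (K, Cin, F)
                fan_in = shape[0] * shape[1]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape).astype(dtype)

        u = lstm_units
        self.params: dict[str, np.ndarray] = {
            "conv_W": glorot(kernel_size, n_channels, conv_filters),
            "conv_b": np.zeros(conv_filters, dtype=dtype),
            "lstm_Wx": glorot(conv_filters, 4 * u),
            "lstm_Wh": glorot(u, 4 * u),
            "lstm_b": np.zeros(4 * u, dtype=dtype),
        }
        # forget-gate bias starts at 1 for stable early training
        self.params["lstm_b"][u : 2 * u] = 1.0
        sizes = (u,) + self.dense_sizes
        for i in range(len(self.dense_sizes)):
            self.params[f"dense_W{i}"] = glorot(sizes[i], sizes[i + 1])
            self.params[f"dense_b{i}"] = np.zeros(sizes[i + 1], dtype=dtype)

    # ---- forward -----------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        x = np.asarray(x, dtype=self.dtype)
        k = self.kernel_size
        view = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # view: (B, T', C, K); conv_W: (K, C, F)
        pre_act = np.einsum("btck,kcf->btf", view, p["conv_W"]) + p["conv_b"]
        conv = np.maximum(pre_act, 0.0)

        b, t, _ = conv.shape
        u = self.lstm_units
        h = np.zeros((b, u), dtype=self.dtype)
        c = np.zeros((b, u), dtype=self.dtype)
        steps = []
        for ti in range(t):
            z = conv[:, ti, :] @ p["lstm_Wx"] + h @ p["lstm_Wh"] + p["lstm_b"]
            i_g = _sigmoid(z[:, :u])
            f_g = _sigmoid(z[:, u : 2 * u])
            g_g = np.tanh(z[:, 2 * u : 3 * u])
            o_g = _sigmoid(z[:, 3 * u :])
            c_new = f_g * c + i_g * g_g
            tanh_c = np.tanh(c_new)
            h_new = o_g * tanh_c
            if cache:
                steps.append((h, c, i_g, f_g, g_g, o_g, tanh_c))
            h, c = h_new, c_new

        a = h
        dense_inputs = []
        n_dense = len(self.dense_sizes)
        for i in range(n_dense):
            dense_inputs.append(a)
            a = a @ p[f"dense_W{i}"] + p[f"dense_b{i}"]
        probs = softmax(a)
        if not cache:
            return probs
        return probs, (x, view, pre_act, conv, steps, h, dense_inputs)

    def predict_proba(self, x: np.ndarray, batch: int = 2048) -> np.ndarray:
        out = [self.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(out, axis=0) if out else np.zeros((0, 2))

    # ---- backward ----------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Soft-target cross-entropy and gradients for one mini-batch."""
        p = self.params
        probs, (x, view, pre_act, conv, steps, h_last, dense_inputs) = self.forward(
            x, cache=True
        )
        y = np.asarray(y, dtype=self.dtype)
        b = x.shape[0]
        loss = soft_cross_entropy(probs, y)
        grads = {name: np.zeros_like(val) for name, val in p.items()}

        d_a = (probs - y) / b  # d loss / d logits
        n_dense = len(self.dense_sizes)
        for i in range(n_dense - 1, -1, -1):
            grads[f"dense_W{i}"] = dense_inputs[i].T @ d_a
            grads[f"dense_b{i}"] = d_a.sum(axis=0)
            d_a = d_a @ p[f"dense_W{i}"].T

        # BPTT through the LSTM
        u = self.lstm_units
        t = conv.shape[1]
        d_h = d_a.astype(self.dtype)
        d_c = np.zeros_like(d_h)
        d_conv = np.zeros_like(conv)
        wx, wh = p["lstm_Wx"], p["lstm_Wh"]
        for ti in range(t - 1, -1, -1):
            h_prev, c_prev, i_g, f_g, g_g, o_g, tanh_c = steps[ti]
            d_o = d_h * tanh_c
            d_c = d_c + d_h * o_g * (1.0 - tanh_c**2)
            d_f = d_c * c_prev
            d_i = d_c * g_g
            d_g = d_c * i_g
            d_z = np.concatenate(
                [
                    d_i * i_g * (1.0 - i_g),
                    d_f * f_g * (1.0 - f_g),
                    d_g * (1.0 - g_g**2),
                    d_o * o_g * (1.0 - o_g),
                ],
                axis=1,
            )
            grads["lstm_Wx"] += conv[:, ti, :].T @ d_z
            grads["lstm_Wh"] += h_prev.T @ d_z
            grads["lstm_b"] += d_z.sum(axis=0)
            d_conv[:, ti, :] = d_z @ wx.T
            d_h = d_z @ wh.T
            d_c = d_c * f_g

        # conv backward (through ReLU)
        d_pre = d_conv * (pre_act > 0)
        grads["conv_W"] = np.einsum("btck,btf->kcf", view, d_pre)
        grads["conv_b"] = d_pre.sum(axis=(0, 1))
        return loss, grads

    # ---- parameter helpers -------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params[k] = v.copy()


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            params[k] -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                params[k].dtype
            )
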