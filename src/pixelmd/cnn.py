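"""A small convolutional network implemented on numpy.

Layers: 3x3 same-padding convolutions (im2col + BLAS matmul), ReLU, 2x2
max-pooling, inverted dropout, dense layers and a softmax/cross-entropy
head, optimized with Adam.  Everything is float32 and seeded; there is no
GPU path.  The architecture wiring lives in :mod:`pixelmd.classifier`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet"]


class _Layer:
    params: list  # [(name, array, grad), ...] populated by subclasses

    def __init__(self):
        self.params = []

    def forward(self, x, train, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(_Layer):
    """3x3 convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, std, size=(c_out, 3, 3, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [("w", self.w, self.dw), ("b", self.b, self.db)]
        self.c_in, self.c_out = c_in, c_out

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        # x: (N, H, W, C) -> (N*H*W, 9*C), window order (kh, kw, c)
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        return col.reshape(n * h * w, 9 * c)

    def forward(self, x, train, rng):
        self._shape = x.shape
        self._col = self._im2col(x)
        n, h, w, _ = x.shape
        wf = self.w.reshape(self.c_out, -1)
        y = self._col @ wf.T + self.b
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy):
        n, h, w, _ = self._shape
        dyf = dy.reshape(n * h * w, self.c_out)
        self.dw[...] = (dyf.T @ self._col).reshape(self.w.shape)
        self.db[...] = dyf.sum(axis=0)
        # dx = "full" convolution of dy with spatially flipped, transposed kernels
        wrot = self.w[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (Cin,3,3,Cout)
        dycol = self._im2col(dy)
        dx = dycol @ wrot.reshape(self.c_in, -1).T
        self._col = None
        return dx.reshape(n, h, w, self.c_in)


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(_Layer):
    """2x2 non-overlapping max pooling; odd trailing rows/cols are dropped."""

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c)
        y = win.max(axis=(2, 4))
        self._win = win
        self._y = y
        return y

    def backward(self, dy):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._win == self._y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        grad = mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = grad.reshape(n, 2 * h2, 2 * w2, c)
        self._win = self._y = None
        return dx


class Dropout(_Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = []
        for layer in layers:
            for _, p, g in layer.params:
                self.state.append((p, g, np.zeros_like(p), np.zeros_like(p)))

    def step(self):
        self.t += 1
        bias1 = 1.0 - self.b1 ** self.t
        bias2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in self.state:
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class ConvNet:
    """Sequential CNN with a softmax / categorical cross-entropy head."""

    def __init__(self, layers: list[_Layer], n_classes: int, seed: int = 0):
        self.layers = layers
        self.n_classes = n_classes
        self.rng = np.random.default_rng(seed)
        # input standardization (fitted on the training images)
        self.input_mean: np.ndarray | float = 0.0
        self.input_scale: float = 255.0

    def _standardize(self, images: np.ndarray) -> np.ndarray:
        x = images.astype(np.float32)
        return (x - self.input_mean) / self.input_scale

    def fit_standardization(self, images: np.ndarray) -> None:
        """Per-pixel mean centering + global scale from training images."""
        self.input_mean = images.mean(axis=0, dtype=np.float64).astype(np.float32)
        self.input_scale = float(
            (images.astype(np.float32) - self.input_mean).std() + 1e-6
        )

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def predict_proba(self, images: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities for uint8 images (N, H, W, 3); rows sum to 1."""
        out = np.empty((images.shape[0], self.n_classes), dtype=np.float64)
        for start in range(0, images.shape[0], batch_size):
            x = self._standardize(images[start : start + batch_size])
            out[start : start + x.shape[0]] = softmax(self.forward(x, train=False))
        return out

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    # -- training ----------------------------------------------------------

    def _loss_grad(self, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        p = softmax(logits)
        n = logits.shape[0]
        loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
        grad = p
        grad[np.arange(n), y] -= 1.0
        return loss, (grad / n).astype(np.float32)

    def evaluate(self, images: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(cross-entropy loss, accuracy) without dropout."""
        p = self.predict_proba(images)
        loss = float(-np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean())
        acc = float((p.argmax(axis=1) == y).mean())
        return loss, acc

    def fit(
        self,
        images: np.ndarray,
        y: np.ndarray,
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.1,
        patience: int = 2,
        min_delta: float = 1e-4,
        convergence_loss: float = 1e-2,
        log=None,
    ) -> dict:
        """Train with Adam and early stopping on held-out validation loss.

        A seeded random ``validation_fraction`` of the training data is held
        out to monitor generalization; the parameters of the best epoch are
        restored.  Training also stops once the held-out loss stays below
        ``convergence_loss`` for two consecutive epochs; a single epoch is
        not enough because one small validation evaluation can be noisy.
        Returns a history dict.
        """
        y = np.asarray(y)
        n = images.shape[0]
        self.fit_standardization(images)
        perm = self.rng.permutation(n)
        n_val = max(1, int(round(validation_fraction * n))) if validation_fraction > 0 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        opt = _Adam(self.layers, lr=learning_rate)
        history = {"train_loss": [], "val_loss": [], "val_acc": []}
        best_loss, best_state, bad = np.inf, None, 0
        converged_epochs = 0
        for epoch in range(epochs):
            order = self.rng.permutation(len(tr_idx))
            losses = []
            for start in range(0, len(order), batch_size):
                idx = tr_idx[order[start : start + batch_size]]
                x = self._standardize(images[idx])
                logits = self.forward(x, train=True)
                loss, grad = self._loss_grad(logits, y[idx])
                losses.append(loss)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step()
            history["train_loss"].append(float(np.mean(losses)))
            if n_val:
                vloss, vacc = self.evaluate(images[val_idx], y[val_idx])
                history["val_loss"].append(vloss)
                history["val_acc"].append(vacc)
                if log:
                    log(f"epoch {epoch + 1}: train_loss={history['train_loss'][-1]:.4f} "
                        f"val_loss={vloss:.4f} val_acc={vacc:.4f}")
                if vloss < best_loss - min_delta:
                    best_loss, bad = vloss, 0
                    best_state = [p.copy() for p, _, _, _ in opt.state]
                else:
                    bad += 1
                    if bad > patience:
                        break
                converged_epochs = converged_epochs + 1 if vloss < convergence_loss else 0
                if converged_epochs >= 2:
                    break
        if best_state is not None:
            for (p, _, _, _), saved in zip(opt.state, best_state):
                p[...] = saved
        return history

    # -- persistence -------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for _, p, _ in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for _, p, _ in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def save(self, path) -> None:
        np.savez_compressed(
            path, *self.get_weights(),
            input_mean=np.asarray(self.input_mean),
            input_scale=np.asarray(self.input_scale),
        )

    def load(self, path) -> None:
        with np.load(path) as data:
            keys = [k for k in data.files if not k.startswith("input_")]
            self.set_weights([data[k] for k in keys])
            self.input_mean = data["input_mean"]
            self.input_scale = float(data["input_scale"])
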