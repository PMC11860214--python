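"""A small, seeded convolutional network implemented on numpy.

This backs the convolutional judge: five 3x3 convolution + ReLU + 2x2
max-pool stages followed by three fully connected layers (two hidden layers
with dropout, then the 2-way output).  Training is mini-batch Adam on the
softmax cross-entropy, with a held-out validation split and early stopping
that restores the best-validation-loss weights.

Everything is float32, NHWC layout, and deterministic given the Generator
passed in (weight init, batch shuffling and dropout masks all draw from it).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet"]


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv3x3:
    """3x3 convolution, zero padding 1, configurable stride (1 or 2)."""

    def __init__(self, rng, c_in, c_out, stride=1):
        self.W = _he_init(rng, (9 * c_in, c_out), 9 * c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out, self.stride = c_in, c_out, stride

    def forward(self, x, train):
        n, h, w, c = x.shape
        s = self.stride
        ho, wo = (h + s - 1) // s, (w + s - 1) // s
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # n,h,w,c,3,3
        if s > 1:
            cols = cols[:, ::s, ::s]
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n * ho * wo, 9 * c)
        out = cols @ self.W + self.b
        if train:
            self._cols, self._shape = cols, (n, h, w, c)
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dout):
        n, h, w, c = self._shape
        s = self.stride
        ho, wo = dout.shape[1], dout.shape[2]
        dflat = dout.reshape(n * ho * wo, self.c_out)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, ho, wo, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += dcols[:, :, :, ki, kj, :]
        self._cols = None
        return dxp[:, 1:-1, 1:-1, :]


class _ReLU:
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class _AvgPool2:
    """2x2 average pool, stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        if train:
            self._in_shape = (n, h, w, c)
        return x[:, :2 * h2, :2 * w2, :].reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, :2 * h2, :2 * w2, :] = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) / 4.0
        return dx


class _MaxPool2:
    """2x2 max pool, stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :2 * h2, :2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, (n, h, w, c)
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, :2 * h2, :2 * w2, :] = dxr.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class _BatchNorm:
    """Per-channel batch normalisation (NHWC, channels last)."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.W = np.ones(c, dtype=np.float32)   # scale (gamma)
        self.b = np.zeros(c, dtype=np.float32)  # shift (beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._xhat, self._inv, self._m = xhat, inv, np.prod([x.shape[a] for a in axes])
            return self.W * xhat + self.b
        inv = 1.0 / np.sqrt(self.run_var + self.eps)
        return self.W * (x - self.run_mean) * inv + self.b

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        xhat, inv, m = self._xhat, self._inv, self._m
        self.dW = (dout * xhat).sum(axis=axes)
        self.db = dout.sum(axis=axes)
        dxhat = dout * self.W
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        self._xhat = None
        return dx.astype(np.float32)


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, rng, d_in, d_out):
        self.W = _he_init(rng, (d_in, d_out), d_in)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class _Dropout:
    def __init__(self, rate, rng):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(np.float32)

    def backward(self, dout):
        if self.rate == 0.0:
            return dout
        return dout * self._mask


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """Configurable conv stack + three dense layers, binary softmax output.

    Each convolutional stage is 3x3 conv (stride 1 or 2), optional batch
    normalisation, ReLU, and optional 2x2 max/average pooling.  With
    ``pool='none'`` downsampling comes from stride-2 convolutions alone.
    """

    def __init__(self, input_size: int, conv_widths, dense_hidden, dropout_rate: float, rng,
                 pool: str = "max", conv_stride: int = 1, batch_norm: bool = True):
        if pool not in ("max", "avg", "none"):
            raise ValueError("pool must be one of 'max', 'avg', 'none'")
        if pool == "none" and conv_stride == 1:
            raise ValueError("without pooling, conv_stride must be > 1 to downsample")
        self.rng = rng
        self.layers = []
        c_in, side = 1, input_size
        for w in conv_widths:
            self.layers.append(_Conv3x3(rng, c_in, w, stride=conv_stride))
            side = (side + conv_stride - 1) // conv_stride
            if batch_norm:
                self.layers.append(_BatchNorm(w))
            self.layers.append(_ReLU())
            if pool == "max":
                self.layers.append(_MaxPool2())
                side //= 2
            elif pool == "avg":
                self.layers.append(_AvgPool2())
                side //= 2
            c_in = w
            if side < 1:
                raise ValueError("input too small for the number of downsampling stages")
        self.layers.append(_Flatten())
        d_in = c_in * side * side
        for h in dense_hidden:
            self.layers += [_Dense(rng, d_in, h), _ReLU(), _Dropout(dropout_rate, rng)]
            d_in = h
        self.layers.append(_Dense(rng, d_in, 2))
        self._trainable = [l for l in self.layers if isinstance(l, (_Conv3x3, _BatchNorm, _Dense))]
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def _forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_proba(self, x, batch_size=256):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        out = [
            _softmax(self._forward(x[i:i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x, batch_size=256):
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- parameters ----------------------------------------------------------

    def _get_params(self):
        return [(layer, name, getattr(layer, name))
                for layer in self._trainable for name in ("W", "b")]

    def _state_items(self):
        items = list(self._get_params())
        for layer in self._trainable:
            if isinstance(layer, _BatchNorm):
                items.append((layer, "run_mean", layer.run_mean))
                items.append((layer, "run_var", layer.run_var))
        return items

    def snapshot(self):
        return [p.copy() for _, _, p in self._state_items()]

    def restore(self, snap):
        for (layer, name, _), p in zip(self._state_items(), snap):
            setattr(layer, name, p.copy())

    # -- training ------------------------------------------------------------

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self._get_params()
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for _, _, p in params],
                "v": [np.zeros_like(p) for _, _, p in params],
            }
        s = self._adam_state
        s["t"] += 1
        for i, (layer, name, p) in enumerate(params):
            g = getattr(layer, "d" + name)
            s["m"][i] = beta1 * s["m"][i] + (1 - beta1) * g
            s["v"][i] = beta2 * s["v"][i] + (1 - beta2) * g * g
            mhat = s["m"][i] / (1 - beta1 ** s["t"])
            vhat = s["v"][i] / (1 - beta2 ** s["t"])
            setattr(layer, name, p - lr * mhat / (np.sqrt(vhat) + eps))

    def _loss_on(self, x, y, batch_size=256):
        losses, n = 0.0, len(x)
        for i in range(0, n, batch_size):
            p = _softmax(self._forward(x[i:i + batch_size], train=False))
            yi = y[i:i + batch_size]
            losses += -np.log(np.clip(p[np.arange(len(yi)), yi], 1e-12, None)).sum()
        return losses / n

    def fit(
        self,
        x,
        y,
        epochs: int = 8,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.1,
        patience: int = 2,
        verbose: bool = False,
    ):
        """Mini-batch Adam with early stopping on validation loss.

        The validation split is carved from a seeded shuffle of the training
        data; the weights with the best validation loss are restored at the
        end.  Returns the per-epoch validation-loss history.
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        y = np.asarray(y, dtype=np.int64)
        order = self.rng.permutation(len(x))
        n_val = max(1, int(round(validation_fraction * len(x)))) if validation_fraction > 0 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        xt, yt = x[train_idx], y[train_idx]
        xv, yv = x[val_idx], y[val_idx]

        best_loss, best_snap, since_best = np.inf, None, 0
        history = []
        for epoch in range(epochs):
            # step decay sharpens the decision boundary in late epochs and
            # makes the restored best-validation snapshot stable across seeds
            if epoch >= 0.75 * epochs:
                lr_now = 0.1 * learning_rate
            elif epoch >= 0.5 * epochs:
                lr_now = 0.3 * learning_rate
            else:
                lr_now = learning_rate
            perm = self.rng.permutation(len(xt))
            for i in range(0, len(xt), batch_size):
                idx = perm[i:i + batch_size]
                logits = self._forward(xt[idx], train=True)
                probs = _softmax(logits)
                grad = probs.copy()
                grad[np.arange(len(idx)), yt[idx]] -= 1.0
                self._backward((grad / len(idx)).astype(np.float32))
                self._adam_step(lr_now)
            val_loss = self._loss_on(xv, yv) if n_val else self._loss_on(xt, yt)
            history.append(float(val_loss))
            if verbose:
                print(f"epoch {epoch + 1}: val_loss={val_loss:.4f}")
            if val_loss < best_loss - 1e-5:
                best_loss, best_snap, since_best = val_loss, self.snapshot(), 0
            else:
                since_best += 1
                if since_best > patience:
                    break
        if best_snap is not None:
            self.restore(best_snap)
        return history
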