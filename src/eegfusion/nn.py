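"""A compact NumPy neural-network engine for small image CNNs.

Implements exactly what the classification models need: 3x3 same-padding
convolutions (shift-and-matmul, so the heavy lifting is BLAS), batch
normalisation, max-pooling, dense layers, ReLU, softmax cross-entropy,
Adam with L2 weight penalty, reduce-on-plateau scheduling and early
stopping. Arrays are channels-last ``(N, H, W, C)`` float32; all randomness
(initialisation, shuffling) flows from one integer seed.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: float32 in, float32 out; params/grads as parallel dicts."""

    name = "layer"

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def weight_keys(self):
        """Parameter keys subject to the L2 penalty (weights, not biases)."""
        return ()


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, same padding, He-initialised."""

    def __init__(self, c_in, c_out, k=3, rng=None, name="conv"):
        super().__init__()
        self.name = name
        self.k = k
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (k * k * c_in))
        self.params["W"] = (rng.standard_normal((k, k, c_in, c_out)) * std).astype(F32)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    @property
    def weight_keys(self):
        return ("W",)

    def forward(self, x, train=True):
        # One contiguous GEMM over the padded array computes all k*k taps at
        # once; the tap outputs are then accumulated with shifted views.
        k = self.k
        p = k // 2
        n, h, w, c_in = x.shape
        hp, wp = h + 2 * p, w + 2 * p
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))).astype(F32, copy=False)
        W = self.params["W"]
        c_out = W.shape[-1]
        wmat = W.transpose(2, 0, 1, 3).reshape(c_in, k * k * c_out)
        z = (xp.reshape(-1, c_in) @ wmat).reshape(n, hp, wp, k * k, c_out)
        y = np.zeros((n, h, w, c_out), dtype=F32)
        for i in range(k):
            for j in range(k):
                y += z[:, i : i + h, j : j + w, i * k + j, :]
        y += self.params["b"]
        if train:
            self._xp = xp
        self._out_shape = (n, h, w, c_out)
        return y

    def backward(self, dout):
        k = self.k
        p = k // 2
        n, h, w, c_out = self._out_shape
        W = self.params["W"]
        c_in = W.shape[2]
        hp, wp = h + 2 * p, w + 2 * p
        xp = self._xp
        # dz holds, for every tap, the gradient it receives from the output
        dz = np.zeros((n, hp, wp, k * k, c_out), dtype=F32)
        for i in range(k):
            for j in range(k):
                dz[:, i : i + h, j : j + w, i * k + j, :] = dout
        dz2 = dz.reshape(-1, k * k * c_out)
        dwmat = xp.reshape(-1, c_in).T @ dz2  # (c_in, k*k*c_out)
        self.grads["W"] = dwmat.reshape(c_in, k, k, c_out).transpose(1, 2, 0, 3)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        wmat = W.transpose(2, 0, 1, 3).reshape(c_in, k * k * c_out)
        dxp = (dz2 @ wmat.T).reshape(n, hp, wp, c_in)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5, name="bn"):
        super().__init__()
        self.name = name
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._axes = xhat, inv.astype(F32), axes
            self._m = x.size // x.shape[-1]
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(F32)

    def backward(self, dout):
        xhat, inv, axes, m = self._xhat, self._inv, self._axes, self._m
        g = self.params["gamma"]
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * g
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool(Layer):
    """Max-pooling with window (ph, pw), stride equal to the window.

    Trailing rows/columns that do not fill a window are dropped.
    """

    def __init__(self, ph=2, pw=2, name="pool"):
        super().__init__()
        self.name = name
        self.ph, self.pw = ph, pw

    def forward(self, x, train=True):
        ph, pw = self.ph, self.pw
        n, h, w, c = x.shape
        h2, w2 = h // ph, w // pw
        xc = x[:, : h2 * ph, : w2 * pw, :]
        blocks = xc.reshape(n, h2, ph, w2, pw, c).transpose(0, 1, 3, 5, 2, 4)
        flat = blocks.reshape(n, h2, w2, c, ph * pw)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        ph, pw = self.ph, self.pw
        n, h, w, c = self._in_shape
        h2, w2 = h // ph, w // pw
        dflat = np.zeros((n, h2, w2, c, ph * pw), dtype=F32)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = dflat.reshape(n, h2, w2, c, ph, pw).transpose(0, 1, 4, 2, 5, 3)
        dxc = dxc.reshape(n, h2 * ph, w2 * pw, c)
        if (h2 * ph, w2 * pw) != (h, w):
            dx = np.zeros((n, h, w, c), dtype=F32)
            dx[:, : h2 * ph, : w2 * pw, :] = dxc
            return dx
        return dxc


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None, name="dense"):
        super().__init__()
        self.name = name
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / d_in)
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * std).astype(F32)
        self.params["b"] = np.zeros(d_out, dtype=F32)

    @property
    def weight_keys(self):
        return ("W",)

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs, labels, eps=1e-12):
    """Mean categorical cross-entropy; ``labels`` are integer class indices."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p, eps))))


class Sequential:
    """A feed-forward stack of layers with a softmax classification head."""

    def __init__(self, layers, feature_layer: int | None = None):
        self.layers = layers
        self.feature_layer = feature_layer

    def forward(self, x, train=True, upto: int | None = None):
        h = x.astype(F32, copy=False)
        stop = len(self.layers) if upto is None else upto + 1
        for layer in self.layers[:stop]:
            h = layer.forward(h, train=train)
        return h

    def predict_proba(self, x, batch_size=64):
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0) if out else np.zeros((0, 0))

    def features(self, x, batch_size=64):
        """Activations of the designated feature layer (inference mode)."""
        if self.feature_layer is None:
            raise ValueError("model has no designated feature layer")
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size], train=False,
                                    upto=self.feature_layer))
        return np.concatenate(out, axis=0)

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    # -- parameter plumbing -------------------------------------------------
    def n_parameters(self):
        return int(sum(v.size for layer in self.layers for v in layer.params.values()))

    def get_weights(self):
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights):
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()


class Adam:
    """Adam optimiser with an L2 weight penalty lambda * sum(w^2)."""

    def __init__(self, model: Sequential, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, l2=1e-4):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2 = l2
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in self.model.layers:
            for key, w in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                g = g.astype(np.float64)
                if self.l2 and key in layer.weight_keys:
                    g = g + 2.0 * self.l2 * w
                state_key = (id(layer), key)
                m = self.m.get(state_key, 0.0)
                v = self.v.get(state_key, 0.0)
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.m[state_key], self.v[state_key] = m, v
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                layer.params[key] = (w - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


def train_model(model: Sequential, x, y, *, x_val=None, y_val=None,
                epochs=150, batch_size=32, lr=1e-3, l2=1e-4,
                plateau_patience=10, plateau_factor=0.5, min_lr=1e-6,
                early_stop_patience=20, augment_fn=None, seed=0,
                val_fraction=0.2, verbose=False):
    """Train a classifier with Adam, plateau scheduling and early stopping.

    Returns a history dict with per-epoch train/validation loss, validation
    accuracy and learning rate. The best-validation-loss weights are
    restored at the end. Deterministic given ``seed`` (and a fixed BLAS
    thread count).
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    x = x.astype(F32, copy=False)
    y = np.asarray(y)

    if x_val is None:
        n_val = max(1, int(round(val_fraction * len(x)))) if len(x) > 1 else 0
        perm = rng.permutation(len(x))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_val, y_val = x[val_idx], y[val_idx]
        x, y = x[tr_idx], y[tr_idx]
    x_val = x_val.astype(F32, copy=False)

    opt = Adam(model, lr=lr, l2=l2)
    history = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best_loss = np.inf
    best_weights = model.get_weights()
    plateau_wait = 0
    stop_wait = 0

    for epoch in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), batch_size):
            idx = order[i : i + batch_size]
            xb, yb = x[idx], y[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            losses.append(cross_entropy(probs, yb))
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward(((probs - onehot) / len(yb)).astype(F32))
            opt.step()

        train_loss = float(np.mean(losses))
        if len(x_val):
            probs_val = model.predict_proba(x_val)
            val_loss = cross_entropy(probs_val, y_val)
            val_acc = float(np.mean(probs_val.argmax(axis=1) == y_val))
        else:
            val_loss, val_acc = train_loss, float("nan")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}: train {train_loss:.4f}  val {val_loss:.4f}"
                  f"  acc {val_acc:.3f}  lr {opt.lr:.2e}")

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= plateau_patience:
                opt.lr = max(opt.lr * plateau_factor, min_lr)
                plateau_wait = 0
            if stop_wait >= early_stop_patience:
                break

    model.set_weights(best_weights)
    return history
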