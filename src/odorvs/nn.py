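"""Minimal NumPy neural networks used by the cost-sensitive classifier.

Two architectures are provided, both trained with Adam and sigmoid outputs
for multi-label targets:

* :class:`MLP` — fully connected ReLU layers with inverted dropout,
  accepting an arbitrary differentiable loss through a (loss, grad)
  callable pair; used for the cost-sensitive multilayer perceptron.
* :class:`SmallCNN` — two strided convolution layers, global average
  pooling and a dense sigmoid head; it exposes the activations and
  gradients of its last convolutional layer, which GradCAM++ requires.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Fully connected network: ReLU hidden layers, sigmoid output."""

    def __init__(self, layer_sizes: list[int], dropout: float = 0.0,
                 seed: int = 0):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.dropout = dropout
        self.rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(self.rng.normal(0, scale, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def forward(self, x: np.ndarray, train: bool = False):
        """Returns (probabilities, cache for backward)."""
        h = np.asarray(x, dtype=float)
        cache = {"acts": [h], "masks": []}
        n_layers = len(self.W)
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if li < n_layers - 1:
                h = np.maximum(z, 0.0)
                if train and self.dropout > 0:
                    mask = (self.rng.random(h.shape) >= self.dropout) / (
                        1 - self.dropout
                    )
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                h = sigmoid(z)
            cache["acts"].append(h)
        return h, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)[0]

    def backward(self, cache, dL_dprob: np.ndarray) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. all parameters.

        dL_dprob is the loss gradient w.r.t. the sigmoid output.
        """
        acts = cache["acts"]
        probs = acts[-1]
        delta = dL_dprob * probs * (1.0 - probs)  # through sigmoid
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            h_prev = acts[li]
            gW[li] = h_prev.T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                mask = cache["masks"][li - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (acts[li] > 0)
        return [*gW, *gb]


# ---------------------------------------------------------------------------
# small CNN with last-conv access for GradCAM++


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """x (N, H, W, C) -> cols (N, OH*OW, k*k*C)."""
    n, h, w, c = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    shp = (n, oh, ow, k, k, c)
    strd = (x.strides[0], x.strides[1] * stride, x.strides[2] * stride,
            x.strides[1], x.strides[2], x.strides[3])
    patches = np.lib.stride_tricks.as_strided(x, shp, strd)
    return patches.reshape(n, oh * ow, k * k * c), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    """Scatter column gradients back to the input tensor."""
    n, h, w, c = x_shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    dx = np.zeros(x_shape)
    dpatch = dcols.reshape(n, oh, ow, k, k, c)
    for i in range(k):
        for j in range(k):
            dx[:, i:i + oh * stride:stride, j:j + ow * stride:stride, :] += (
                dpatch[:, :, :, i, j, :]
            )
    return dx


class _ConvLayer:
    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0, scale, (k * k * cin, cout))
        self.b = np.zeros(cout)
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout

    def forward(self, x: np.ndarray):
        cols, oh, ow = _im2col(x, self.k, self.stride)
        z = cols @ self.w + self.b
        a = np.maximum(z, 0.0)
        cache = (x.shape, cols, z)
        return a.reshape(x.shape[0], oh, ow, self.cout), cache

    def backward(self, da: np.ndarray, cache):
        x_shape, cols, z = cache
        n = x_shape[0]
        dz = da.reshape(n, -1, self.cout) * (z > 0)
        dw = np.einsum("npk,npo->ko", cols, dz)
        db = dz.sum(axis=(0, 1))
        dcols = dz @ self.w.T
        dx = _col2im(dcols, x_shape, self.k, self.stride)
        return dx, dw, db


class SmallCNN:
    """Conv(3->8, 7x7/4) - Conv(8->16, 5x5/3) - flatten - Dense(C) - sigmoid.

    Accepts 224x224x3 spectrum images; the 17x17x16 output of the second
    (last) convolution is the activation stack phi_k that GradCAM++ weights.
    The dense head reads the flattened conv map, so the network is
    position-sensitive — spectra differing only in where along the
    wavenumber axis their bands sit remain separable. Decoupled L2 decay on
    the head and dropout on the flattened map discourage single-pixel
    shortcut solutions: the head is pushed toward the minimum-norm rule
    that spreads weight over all informative evidence.
    """

    def __init__(self, n_classes: int, seed: int = 0, lr: float = 1e-3,
                 weight_decay: float = 1e-3, dropout: float = 0.25):
        rng = np.random.default_rng(seed)
        self.conv1 = _ConvLayer(3, 8, 7, 4, rng)
        self.conv2 = _ConvLayer(8, 16, 5, 3, rng)
        self.map_shape = (17, 17, 16)
        n_flat = int(np.prod(self.map_shape))
        self.wd = rng.normal(0, np.sqrt(1.0 / n_flat), (n_flat, n_classes))
        self.bd = np.zeros(n_classes)
        self.n_classes = n_classes
        self.weight_decay = weight_decay
        self.dropout = dropout
        self._rng = rng
        self._lr = lr
        self._opt = Adam(
            [self.conv1.w, self.conv1.b, self.conv2.w, self.conv2.b,
             self.wd, self.bd],
            lr=lr,
        )

    def forward(self, x: np.ndarray):
        """x (N, 224, 224, 3) -> (probs, scores, cache)."""
        a1, c1 = self.conv1.forward(x)
        a2, c2 = self.conv2.forward(a1)       # (N, 17, 17, 16), post-ReLU
        flat = a2.reshape(x.shape[0], -1)
        scores = flat @ self.wd + self.bd     # pre-sigmoid class scores
        probs = sigmoid(scores)
        return probs, scores, {"c1": c1, "c2": c2, "a2": a2, "flat": flat}

    def predict_proba(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch):
            out.append(self.forward(x[i:i + batch])[0])
        return np.vstack(out)

    def train_epoch(self, x: np.ndarray, y: np.ndarray,
                    loss_grad, rng: np.random.Generator,
                    batch_size: int = 16) -> float:
        """One epoch of minibatch Adam; loss_grad(y, p) -> (loss, dL/dp)."""
        order = rng.permutation(x.shape[0])
        total = 0.0
        for start in range(0, x.shape[0], batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            a1, c1 = self.conv1.forward(xb)
            a2, c2 = self.conv2.forward(a1)
            flat = a2.reshape(xb.shape[0], -1)
            if self.dropout > 0:
                mask = (rng.random(flat.shape) >= self.dropout) / (
                    1 - self.dropout)
                flat_d = flat * mask
            else:
                mask = None
                flat_d = flat
            probs = sigmoid(flat_d @ self.wd + self.bd)
            loss, dprob = loss_grad(yb, probs)
            total += loss * idx.size
            delta = dprob * probs * (1 - probs)          # (n, C)
            dwd = flat_d.T @ delta
            dbd = delta.sum(axis=0)
            dflat = delta @ self.wd.T
            if mask is not None:
                dflat = dflat * mask
            da2 = dflat.reshape(a2.shape)
            da1, dw2, db2 = self.conv2.backward(da2, c2)
            _, dw1, db1 = self.conv1.backward(da1, c1)
            self._opt.step([dw1, db1, dw2, db2, dwd, dbd])
            if self.weight_decay > 0:
                self.wd -= self._lr * self.weight_decay * self.wd
        return total / x.shape[0]

    def last_conv_and_grad(self, x: np.ndarray, class_idx: int):
        """Activations phi (17, 17, 16) of the last conv layer and the
        gradient of the class score w.r.t. them, for one image."""
        x = x[None] if x.ndim == 3 else x
        _, scores, cache = self.forward(x)
        a2 = cache["a2"][0]
        # score is linear in the flattened map: dS/dA = wd column reshaped
        grad = self.wd[:, class_idx].reshape(self.map_shape).copy()
        return a2, grad, float(scores[0, class_idx])
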