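"""Cost-sensitive multi-label classification (CSMLP).

Ordinary multi-label training treats false positives and false negatives
symmetrically, which under heavy label imbalance starves minority notes.
The cost-sensitive multilayer perceptron combines two remedies in one loss:

* weighted binary cross-entropy, with per-class weights
  w_pos_j = (#negatives of class j) / n  and  w_neg_j = (#positives) / n,
  smoothed by an exponent delta, so errors on rare-class positives cost
  more:

      WBCEL = -(1/N) sum_ij [ w_pos_j^delta * y_ij * log(p_ij + eps)
                            + w_neg_j^delta * (1 - y_ij) * log(1 - p_ij + eps) ]

* focal loss, which down-weights already-easy cells by the modulating
  factor (1 - p)^gamma (resp. p^gamma for negatives):

      FL = -(1/N) sum_ij [ (1 - p_ij)^gamma * y_ij * log(p_ij + eps)
                         + p_ij^gamma * (1 - y_ij) * log(1 - p_ij + eps) ]

combined as CL = WBCEL + lambda * FL. With gamma = delta = lambda = 0 the
loss reduces to plain binary cross-entropy (sum over classes, mean over
samples).

Training uses Adam with dropout, sigmoid outputs, and restores the weights
from the epoch with the highest evaluation micro-F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from sklearn.decomposition import PCA

from odorvs.labels import LabelMatrix
from odorvs.nn import MLP
from odorvs.split import SplitResult


@dataclass
class LossParams:
    """Hyper-parameters of the combined loss.

    gamma : focal focusing parameter (>= 0); 2 is the standard choice.
    delta : class-weight smoothing exponent (>= 0); 1 applies the full
        complementary-frequency weighting, 0 switches it off.
    lam : mixing weight of the focal term (>= 0). The focal term is
        class-unweighted, so a large lam re-symmetrizes the cost of
        positive and negative errors and cancels the class weighting; the
        default keeps the weighted term dominant and uses the focal term
        only as a mild hard-example refinement.
    eps : numerical stability constant added inside the logs.
    """

    gamma: float = 2.0
    delta: float = 1.0
    lam: float = 0.1
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        for name in ("gamma", "delta", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class ClassWeights:
    w_pos: np.ndarray = field(repr=False)
    w_neg: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.w_pos = np.asarray(self.w_pos, dtype=float)
        self.w_neg = np.asarray(self.w_neg, dtype=float)
        if self.w_pos.shape != self.w_neg.shape:
            raise ValueError("w_pos and w_neg must have the same shape")


@dataclass
class ModelConfig:
    """CSMLP architecture and training configuration."""

    hidden_sizes: tuple[int, ...] | None = None  # default: sized by input dim
    dropout: float = 0.3
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def compute_class_weights(labels: LabelMatrix | np.ndarray) -> ClassWeights:
    """Per-class complementary weights from label counts.

    w_pos_j is the fraction of *negative* samples of class j (so rare
    classes get positive-term weights near 1) and w_neg_j the fraction of
    positives; they sum to 1 per class.
    """
    y = labels.matrix if isinstance(labels, LabelMatrix) else np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty label matrix")
    n = y.shape[0]
    pos = y.sum(axis=0)
    return ClassWeights(w_pos=(n - pos) / n, w_neg=pos / n)


def _check_batch(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("loss inputs contain NaN or inf")
    return np.atleast_2d(y_true), np.atleast_2d(y_pred)


def focal_loss(y_true: np.ndarray, y_pred: np.ndarray,
               gamma: float = 2.0, eps: float = 1e-7) -> float:
    """Focal loss, summed over classes and averaged over samples."""
    y, p = _check_batch(y_true, y_pred)
    n = y.shape[0]
    # xlogy keeps the 0 * log(0) corner (perfect prediction at eps=0) finite
    term = ((1 - p) ** gamma * xlogy(y, p + eps)
            + p ** gamma * xlogy(1 - y, 1 - p + eps))
    return float(-term.sum() / n)


def wbce_loss(y_true: np.ndarray, y_pred: np.ndarray, weights: ClassWeights,
              delta: float = 0.5, eps: float = 1e-7) -> float:
    """Class-weighted binary cross-entropy."""
    y, p = _check_batch(y_true, y_pred)
    n = y.shape[0]
    wp = weights.w_pos ** delta
    wn = weights.w_neg ** delta
    term = wp * xlogy(y, p + eps) + wn * xlogy(1 - y, 1 - p + eps)
    return float(-term.sum() / n)


def combined_loss(y_true: np.ndarray, y_pred: np.ndarray,
                  weights: ClassWeights, params: LossParams) -> float:
    """CL = WBCEL + lambda * FL."""
    return (wbce_loss(y_true, y_pred, weights, params.delta, params.eps)
            + params.lam * focal_loss(y_true, y_pred, params.gamma, params.eps))


def combined_loss_grad(y_true: np.ndarray, y_pred: np.ndarray,
                       weights: ClassWeights, params: LossParams) -> np.ndarray:
    """Analytic gradient of CL w.r.t. the predicted probabilities."""
    y, p = _check_batch(y_true, y_pred)
    n = y.shape[0]
    g, d, lam, eps = params.gamma, params.delta, params.lam, params.eps
    wp = weights.w_pos ** d
    wn = weights.w_neg ** d
    d_wbce = -(wp * y / (p + eps) - wn * (1 - y) / (1 - p + eps))
    omp = 1 - p
    if g == 0:
        d_pos = y / (p + eps)
        d_neg = -(1 - y) / (omp + eps)
    else:
        d_pos = (-g * omp ** (g - 1) * y * np.log(p + eps)
                 + omp ** g * y / (p + eps))
        d_neg = (g * p ** (g - 1) * (1 - y) * np.log(omp + eps)
                 - p ** g * (1 - y) / (omp + eps))
    d_fl = -(d_pos + d_neg)
    return (d_wbce + lam * d_fl) / n


def micro_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                  threshold: float = 0.5) -> tuple[float, float, float]:
    """Micro-averaged precision, recall, F1 with global TP/FP/FN pooling."""
    y_true = np.asarray(y_true)
    y_hat = np.asarray(y_prob) >= threshold
    if y_true.shape != y_hat.shape:
        raise ValueError("shape mismatch between y_true and predictions")
    tp = float(np.sum(y_hat & (y_true == 1)))
    fp = float(np.sum(y_hat & (y_true == 0)))
    fn = float(np.sum(~y_hat & (y_true == 1)))
    if y_true.sum() == 0 and tp + fp == 0:
        warnings.warn("no positives anywhere; metrics defined as 0")
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    eval_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_f1: float = 0.0


def train_csmlp(
    features: np.ndarray,
    labels: LabelMatrix,
    split: SplitResult,
    config: ModelConfig | None = None,
    params: LossParams | None = None,
    weights: ClassWeights | None = None,
) -> tuple[MLP, TrainingHistory]:
    """Train the cost-sensitive MLP and restore the best-F1 weights.

    The combined loss is minimized with Adam; after every epoch the
    micro-F1 on the evaluation (test) split is recorded, and at the end the
    weights from the best epoch are restored. Class weights default to
    those of the training split.
    """
    config = config or ModelConfig()
    params = params or LossParams()
    features = np.asarray(features, dtype=float)
    y = labels.matrix.astype(float)
    if features.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature rows ({features.shape[0]}) != label rows ({y.shape[0]})"
        )
    tr, te = split.train_indices, split.test_indices
    if weights is None:
        weights = compute_class_weights(y[tr])
    d_in, d_out = features.shape[1], y.shape[1]
    if config.hidden_sizes is None:
        h1 = max(min(d_in // 2, 256), 16)
        hidden = (h1, max(h1 // 2, 8))
    else:
        hidden = tuple(config.hidden_sizes)
    net = MLP([d_in, *hidden, d_out], dropout=config.dropout, seed=config.seed)
    from odorvs.nn import Adam

    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    hist = TrainingHistory()
    best_weights = net.get_weights()
    x_tr, y_tr = features[tr], y[tr]
    x_te, y_te = features[te], y[te]
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr))
        epoch_loss = 0.0
        for start in range(0, len(tr), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs, cache = net.forward(xb, train=True)
            if not np.isfinite(probs).all():
                raise FloatingPointError(f"non-finite output at epoch {epoch}")
            loss = combined_loss(yb, probs, weights, params)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            dprob = combined_loss_grad(yb, probs, weights, params)
            opt.step(net.backward(cache, dprob))
        hist.loss.append(epoch_loss / len(tr))
        _, _, f1 = micro_metrics(y_te, net.predict_proba(x_te), config.threshold)
        hist.eval_f1.append(f1)
        if f1 > hist.best_f1 or hist.best_epoch < 0:
            hist.best_f1, hist.best_epoch = f1, epoch
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    return net, hist


def fuse_features(
    img_features: np.ndarray,
    dff: np.ndarray,
    train_indices: np.ndarray,
    img_dims: int = 3036,
    dff_variance: float = 0.85,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """PCA-reduce image features and fingerprints, then concatenate.

    Image features are reduced to min(img_dims, feasible) components;
    fingerprints to the smallest component count reaching the target
    explained-variance fraction. Both PCA fits use only the training rows
    and are applied to all rows. Returns (fused matrix, info dict).
    """
    img_features = np.asarray(img_features, dtype=float)
    dff = np.asarray(dff, dtype=float)
    if img_features.shape[0] != dff.shape[0]:
        raise ValueError("image-feature and fingerprint row counts differ")
    if not 0 < dff_variance <= 1:
        raise ValueError("dff_variance must be in (0, 1]")
    tr = np.asarray(train_indices, dtype=int)
    max_img = min(img_dims, len(tr) - 1, img_features.shape[1])
    pca_img = PCA(n_components=max_img, random_state=seed)
    pca_img.fit(img_features[tr])
    img_red = pca_img.transform(img_features)

    max_dff = min(len(tr) - 1, dff.shape[1])
    pca_dff = PCA(n_components=max_dff, random_state=seed)
    pca_dff.fit(dff[tr])
    cum = np.cumsum(pca_dff.explained_variance_ratio_)
    if cum[-1] < dff_variance:
        warnings.warn(
            f"variance target {dff_variance:.2f} unreachable "
            f"(max {cum[-1]:.3f}); using all {max_dff} components"
        )
        n_dff = max_dff
    else:
        n_dff = int(np.searchsorted(cum, dff_variance) + 1)
    dff_red = pca_dff.transform(dff)[:, :n_dff]
    fused = np.concatenate([img_red, dff_red], axis=1)
    info = {
        "img_components": max_img,
        "dff_components": n_dff,
        "dff_variance_reached": float(cum[n_dff - 1]),
    }
    return fused, info
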