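"""Model explainability: permutation importance and GradCAM++ saliency.

Permutation feature importance (PFI) measures how much shuffling one
feature column across samples degrades a model's error e: with the default
sign convention FI_j = e_perm - e_orig, so informative features score
positive (the alternative orientation e_orig - e_perm is available via
``paper_sign=True``).

GradCAM++ produces a class-discriminative saliency map from a
convolutional network: the last conv layer's activation maps phi_k are
combined with weights

    w_k = sum_ij alpha_kij * relu(dY/dA_kij),
    alpha_kij = (d2Y/dA^2) / (2 d2Y/dA^2 + sum_ab A_kab d3Y/dA^3),

where Y = exp(score_c) (the closed form of Chattopadhay et al.), followed
by ReLU over sum_k w_k phi_k, bilinear upsampling to the input size and
min-max rescaling to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom

from odorvs.imaging import SpectrumImage
from odorvs.nn import SmallCNN


@dataclass
class ImportanceResult:
    """Per-feature permutation importances."""

    importances: np.ndarray = field(repr=False)  # (n_features,)
    per_repeat: np.ndarray = field(repr=False)   # (n_repeats, n_features)
    n_repeats: int = 1
    seed: int = 0
    paper_sign: bool = False  # True: FI = e_orig - e_perm

    def ranking(self) -> np.ndarray:
        """Feature indices from most to least important."""
        return np.argsort(-self.importances)


@dataclass
class SaliencyMap:
    """Non-negative per-pixel relevance, rescaled so max = 1."""

    relevance: np.ndarray = field(repr=False)  # (side, side) in [0, 1]
    class_index: int = 0

    def __post_init__(self) -> None:
        self.relevance = np.asarray(self.relevance, dtype=float)
        if (self.relevance < 0).any():
            raise ValueError("saliency must be non-negative")


def permutation_importance(
    model,
    x: np.ndarray,
    y: np.ndarray,
    error_fn,
    n_repeats: int = 5,
    seed: int = 0,
    paper_sign: bool = False,
) -> ImportanceResult:
    """Model-agnostic permutation feature importance.

    ``model`` must expose predict_proba (or be a callable); ``error_fn``
    maps (y_true, y_prob) to a scalar error (lower = better), e.g. the
    combined loss or 1 - micro-F1. Each feature column is permuted
    ``n_repeats`` times with distinct sub-seeds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    predict = model.predict_proba if hasattr(model, "predict_proba") else model
    e_orig = float(error_fn(y, predict(x)))
    rng = np.random.default_rng(seed)
    n_features = x.shape[1]
    per_repeat = np.zeros((n_repeats, n_features))
    for r in range(n_repeats):
        perm = rng.permutation(x.shape[0])
        for j in range(n_features):
            col = x[:, j].copy()
            if np.all(col == col[0]):
                per_repeat[r, j] = 0.0  # constant column: permuting is a no-op
                continue
            x[:, j] = col[perm]
            e_perm = float(error_fn(y, predict(x)))
            x[:, j] = col
            per_repeat[r, j] = (e_orig - e_perm) if paper_sign else (e_perm - e_orig)
    return ImportanceResult(
        importances=per_repeat.mean(axis=0),
        per_repeat=per_repeat,
        n_repeats=n_repeats,
        seed=seed,
        paper_sign=paper_sign,
    )


def gradcam_pp(
    cnn: SmallCNN,
    image: SpectrumImage | np.ndarray,
    class_index: int,
    out_side: int = 224,
) -> SaliencyMap:
    """GradCAM++ saliency for one image and one class."""
    if not hasattr(cnn, "last_conv_and_grad"):
        raise TypeError(
            "model does not expose convolutional activations/gradients; "
            "use permutation_importance for non-convolutional models"
        )
    x = image.pixels if isinstance(image, SpectrumImage) else np.asarray(image)
    phi, grad, score = cnn.last_conv_and_grad(x, class_index)
    # derivatives of Y = exp(score) w.r.t. the activations; score is
    # (locally) linear in phi so d^nY/dA^n = exp(score) * grad^n
    g1 = grad                      # up to the common exp(score) factor
    g2 = grad ** 2
    g3 = grad ** 3
    sum_a = phi.sum(axis=(0, 1), keepdims=True)
    denom = 2.0 * g2 + sum_a * g3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1, denom), 0.0)
    w = (alpha * np.maximum(g1, 0.0)).sum(axis=(0, 1))  # (K,)
    cam = np.maximum((phi * w[None, None, :]).sum(axis=2), 0.0)
    cam_up = zoom(cam, (out_side / cam.shape[0], out_side / cam.shape[1]),
                  order=1)
    cam_up = np.maximum(cam_up, 0.0)
    if cam_up.max() > 0:
        cam_up = cam_up / cam_up.max()
    return SaliencyMap(cam_up, class_index)


def average_saliency(
    images: list[SpectrumImage],
    cnn: SmallCNN,
    class_index: int,
) -> tuple[SaliencyMap, np.ndarray]:
    """Element-wise mean saliency map and mean channel image over molecules.

    Averaging over all molecules carrying a note suppresses per-molecule
    idiosyncrasies and highlights the spectral regions the model uses for
    that note in general.
    """
    if not images:
        raise ValueError("need at least one image")
    maps = [gradcam_pp(cnn, im, class_index).relevance for im in images]
    mean_map = np.mean(maps, axis=0)
    if mean_map.max() > 0:
        mean_map = mean_map / mean_map.max()
    mean_channels = np.mean([im.pixels for im in images], axis=0)
    return SaliencyMap(mean_map, class_index), mean_channels


def overlay_importance_on_spectrum(
    importance: ImportanceResult | SaliencyMap,
    grid: np.ndarray,
    top_fraction: float = 0.1,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Map feature/pixel relevance back to wavenumber bands.

    For an :class:`ImportanceResult` the relevance profile is the
    per-feature importance on the descriptor's wavenumber grid; for a
    :class:`SaliencyMap` the 2-D map is reduced to a profile by column
    means (columns index series position = wavenumber) and resampled to the
    grid length. Returns (relevance per grid point, list of contiguous
    (lo, hi) wavenumber intervals covering the top ``top_fraction`` of
    relevance ranks).
    """
    grid = np.asarray(grid, dtype=float)
    if isinstance(importance, SaliencyMap):
        profile = importance.relevance.mean(axis=0)
        if profile.size != grid.size:
            profile = zoom(profile, grid.size / profile.size, order=1)
            profile = profile[: grid.size]
            if profile.size != grid.size:
                profile = np.pad(profile, (0, grid.size - profile.size),
                                 mode="edge")
    else:
        profile = importance.importances
        if profile.size != grid.size:
            raise ValueError(
                f"importance length {profile.size} does not match "
                f"grid length {grid.size}"
            )
    n_top = max(int(round(top_fraction * grid.size)), 1)
    top_idx = np.sort(np.argsort(-profile)[:n_top])
    bands = []
    start = prev = top_idx[0]
    for i in top_idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            bands.append((float(grid[start]), float(grid[prev])))
            start = prev = i
    bands.append((float(grid[start]), float(grid[prev])))
    return profile, bands
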