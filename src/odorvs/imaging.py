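"""Image encoding of spectral descriptors: Gramian and Markov fields.

A normalized GS_VS series Y (values in [0, 1]) is mapped to polar
coordinates, theta_i = arccos(Y_i) in [0, pi/2] with radius t_i / N, and
expanded into

* GASF — the Gramian angular summation field cos(theta_i + theta_j),
  symmetric, diagonal 2*Y_i^2 - 1 (so the series is recoverable from the
  diagonal: the mapping is bijective);
* GADF — the Gramian angular difference field sin(theta_i - theta_j),
  antisymmetric with zero diagonal;
* MTF — the Markov transition field: the series is quantile-binned into Q
  bins, a row-stochastic Q x Q transition matrix Z is estimated from
  consecutive pairs, and the field N_kl = Z[bin(x_k), bin(x_l)] indexes it
  by the bin membership of every pair of positions.

The three n x n fields (n = 224 after piecewise aggregate approximation of
the 800-point series) are stacked into a 224 x 224 x 3 image per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np


@dataclass
class PolarSeries:
    """Polar encoding of a [0, 1]-valued series."""

    angles: np.ndarray = dc_field(repr=False)   # arccos(Y_i), radians in [0, pi/2]
    radii: np.ndarray = dc_field(repr=False)    # t_i / N, non-decreasing

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)

    @property
    def values(self) -> np.ndarray:
        """Original series values, cos(theta)."""
        return np.cos(self.angles)


@dataclass
class GramianField:
    kind: str  # 'GASF' or 'GADF'
    matrix: np.ndarray = dc_field(repr=False)


@dataclass
class MarkovField:
    n_bins: int
    markov_matrix: np.ndarray = dc_field(repr=False)  # Q x Q row-stochastic Z
    bin_of: np.ndarray = dc_field(repr=False)         # bin index per position
    field: np.ndarray = dc_field(repr=False)          # n x n expanded field
    unvisited_bins: np.ndarray = dc_field(repr=False)  # bins padded uniform


@dataclass
class SpectrumImage:
    """3-channel field image of one spectrum (channels GASF, GADF, MTF).

    pixels holds the per-channel min-max rescaled values in [0, 1];
    channel_ranges records the (min, max) used, so the raw fields are
    recoverable via :meth:`raw_channel`.
    """

    molecule_id: str
    pixels: np.ndarray = dc_field(repr=False)  # side x side x 3, rescaled [0, 1]
    channel_ranges: np.ndarray = dc_field(repr=False)  # 3 x 2 (min, max)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (side, side, 3)")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    def raw_channel(self, c: int) -> np.ndarray:
        """Undo the per-channel affine rescale."""
        lo, hi = self.channel_ranges[c]
        return self.pixels[:, :, c] * (hi - lo) + lo


def to_polar(series: np.ndarray) -> PolarSeries:
    """Map a [0, 1] series to polar coordinates (theta = arccos, r = t/n)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if ((series < 0) | (series > 1)).any():
        bad = series[(series < 0) | (series > 1)][0]
        raise ValueError(
            f"value {bad:g} outside [0, 1]; the Gramian angular mapping "
            "requires a normalized series (arccos argument in [0, 1])"
        )
    n = series.size
    angles = np.arccos(series)
    radii = np.arange(1, n + 1) / n
    return PolarSeries(angles, radii)


def gasf(polar: PolarSeries) -> GramianField:
    """Gramian angular summation field cos(theta_i + theta_j)."""
    th = polar.angles
    return GramianField("GASF", np.cos(th[:, None] + th[None, :]))


def gadf(polar: PolarSeries) -> GramianField:
    """Gramian angular difference field sin(theta_i - theta_j)."""
    th = polar.angles
    return GramianField("GADF", np.sin(th[:, None] - th[None, :]))


def _quantile_bins(series: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Quantile bin membership; duplicate edges merge (skewed series)."""
    edges = np.quantile(series, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges[1:-1])
    bin_of = np.searchsorted(edges, series, side="right")
    return bin_of, n_bins


def markov_matrix(series: np.ndarray, n_bins: int = 8) -> MarkovField:
    """First-order Markov transition matrix over quantile bins.

    Z[i, j] is the probability of moving from bin i to bin j between
    consecutive positions; every row sums to 1. Bins never visited get a
    uniform row and are flagged in ``unvisited_bins``. Quantile binning
    avoids empty bins on skewed spectra; coincident quantile edges (highly
    repetitive series) merge bins, so fewer than n_bins may be occupied.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    bin_of, q = _quantile_bins(series, n_bins)
    counts = np.zeros((q, q))
    np.add.at(counts, (bin_of[:-1], bin_of[1:]), 1.0)
    row_sums = counts.sum(axis=1)
    unvisited = row_sums == 0
    z = np.empty_like(counts)
    z[~unvisited] = counts[~unvisited] / row_sums[~unvisited, None]
    z[unvisited] = 1.0 / q
    n = series.size
    fld = z[np.ix_(bin_of, bin_of)]
    return MarkovField(q, z, bin_of, fld, np.flatnonzero(unvisited))


def mtf(series: np.ndarray, n_bins: int = 8) -> MarkovField:
    """Markov transition field N_kl = Z[bin(x_k), bin(x_l)]."""
    return markov_matrix(series, n_bins)


def paa_reduce(series: np.ndarray, target: int = 224) -> np.ndarray:
    """Piecewise aggregate approximation with fractional-boundary weighting.

    The series is divided into ``target`` equal-length segments (length
    n/target, possibly fractional); each output value is the weighted mean
    of the covered samples, so the overall mean is preserved exactly and a
    divisible n reduces to plain block means.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < target:
        raise ValueError(f"cannot PAA-reduce length {n} to {target}")
    if n == target:
        return series.copy()
    # weight matrix row k covers [k*n/target, (k+1)*n/target)
    bounds = np.linspace(0, n, target + 1)
    cumsum = np.concatenate([[0.0], np.cumsum(series)])

    def frac_sum(b: float) -> float:
        i = int(np.floor(b))
        s = cumsum[i]
        if i < n and b > i:
            s += series[i] * (b - i)
        return s

    sums = np.array([frac_sum(b) for b in bounds])
    seg = np.diff(sums)
    return seg / (n / target)


def encode_image(
    gsvs, n_bins: int = 8, side: int = 224
) -> SpectrumImage:
    """GS_VS descriptor -> 3-channel (GASF, GADF, MTF) field image.

    The 800-point series is PAA-reduced to ``side`` points first (PAA of a
    [0, 1] series stays in [0, 1], keeping the polar mapping valid), then
    each field is computed on the reduced series and min-max rescaled to
    [0, 1] per channel; the ranges are kept in the image metadata.
    """
    from odorvs.featurize import GSVSVector

    if isinstance(gsvs, GSVSVector):
        series, mid = gsvs.values, gsvs.molecule_id
    else:
        series, mid = np.asarray(gsvs, dtype=float), "series"
    reduced = paa_reduce(series, side)
    reduced = np.clip(reduced, 0.0, 1.0)
    polar = to_polar(reduced)
    channels = [
        gasf(polar).matrix,
        gadf(polar).matrix,
        mtf(reduced, n_bins).field,
    ]
    pixels = np.empty((side, side, 3))
    ranges = np.empty((3, 2))
    for c, ch in enumerate(channels):
        lo, hi = float(ch.min()), float(ch.max())
        ranges[c] = (lo, hi)
        pixels[:, :, c] = (ch - lo) / (hi - lo) if hi > lo else 0.0
    return SpectrumImage(mid, pixels, ranges)


class RandomConvFeaturizer:
    """Small fixed-seed convolutional encoder for flattened image features.

    Two strided random-projection convolution layers with ReLU
    (3->8 channels, 7x7 stride 4; 8->16 channels, 5x5 stride 3) followed by
    flattening: 224 x 224 x 3 -> 17 x 17 x 16 = 4624 features. Weights are
    drawn once from a seeded He-scaled Gaussian, so the encoder is
    deterministic and needs no pretrained download. Random convolutional
    projections are a standard cheap featurizer; a pretrained backbone
    (e.g. ResNet50) can be plugged in via any callable with the same
    signature.
    """

    n_features = 17 * 17 * 16

    def __init__(self, seed: int = 1234) -> None:
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0, np.sqrt(2 / (7 * 7 * 3)), (8, 3, 7, 7))
        self.b1 = np.zeros(8)
        self.w2 = rng.normal(0, np.sqrt(2 / (5 * 5 * 8)), (16, 8, 5, 5))
        self.b2 = np.zeros(16)

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
        """Valid convolution, x (H, W, Cin), w (Cout, Cin, k, k)."""
        cout, cin, k, _ = w.shape
        h, wd, _ = x.shape
        oh = (h - k) // stride + 1
        ow = (wd - k) // stride + 1
        shp = (oh, ow, k, k, cin)
        strd = (
            x.strides[0] * stride, x.strides[1] * stride,
            x.strides[0], x.strides[1], x.strides[2],
        )
        patches = np.lib.stride_tricks.as_strided(x, shp, strd)
        cols = patches.reshape(oh * ow, k * k * cin)
        wmat = w.transpose(0, 2, 3, 1).reshape(cout, k * k * cin)
        out = cols @ wmat.T + b
        return out.reshape(oh, ow, cout)

    def __call__(self, image: SpectrumImage | np.ndarray) -> np.ndarray:
        x = image.pixels if isinstance(image, SpectrumImage) else np.asarray(image)
        if x.shape != (224, 224, 3):
            raise ValueError(f"backbone expects 224x224x3 input, got {x.shape}")
        h1 = np.maximum(self._conv(x, self.w1, self.b1, 4), 0.0)
        h2 = np.maximum(self._conv(h1, self.w2, self.b2, 3), 0.0)
        return h2.ravel()


_default_backbone: RandomConvFeaturizer | None = None


def extract_features(image: SpectrumImage, backbone=None) -> np.ndarray:
    """Flattened backbone features of a spectrum image (VS_IMG)."""
    global _default_backbone
    if backbone is None:
        if _default_backbone is None:
            _default_backbone = RandomConvFeaturizer()
        backbone = _default_backbone
    return np.asarray(backbone(image), dtype=float)


def extract_features_batch(
    images: list[SpectrumImage], backbone=None
) -> np.ndarray:
    return np.vstack([extract_features(im, backbone) for im in images])
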