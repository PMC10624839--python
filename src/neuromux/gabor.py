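"""Image complexity via a 68-filter Gabor bank (4 orientations x 17 sizes).

Each filter is a Gabor patch

    G(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lambda)

with rotated coordinates x' = x cos(theta) + y sin(theta),
y' = -x sin(theta) + y cos(theta), orientations theta in {0, 45, 90, 135}
degrees, and a size parameter s in 1..17 that sets the envelope width

    sigma(s) = 0.0036 s^2 + 0.35 s + 0.18        (pixels)
    lambda(s) = sigma(s) / 0.8

An image's feature vector holds, per filter, the mean absolute value of the
filtered (2-D convolved) image; the median of the 68 features is the scalar
"median feature density" used as the complexity index.

Normalization modes
-------------------
``unit_sum`` (default)
    F = G / sum(G+). The positive filter mass sums to 1, so convolving an
    image with values in [0, 1] can never exceed 1 (the stated contract for
    the bank).
``reciprocal``
    The literal reading N = 1 / (integral of G), combined with the Heaviside
    correction F = [1 + N * H(G - 1)] G (H(G-1) is nonzero only at points
    where G reaches 1). Because lambda = sigma / 0.8 makes G nearly zero-mean,
    N is numerically explosive; an error suggests ``unit_sum`` instead.
``zero_mean``
    F = (G - mean(G)) / sum((G - mean(G))+). Exactly DC-free: constant images
    yield features of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

THETAS_DEG = (0.0, 45.0, 90.0, 135.0)
SIZES = tuple(range(1, 18))
N_FILTERS = len(THETAS_DEG) * len(SIZES)  # 68
NORMALIZATION_MODES = ("unit_sum", "reciprocal", "zero_mean")

#: Rec. 601 luma weights for RGB -> luminance conversion.
REC601 = np.array([0.299, 0.587, 0.114])


def sigma_of_size(s: int) -> float:
    """Envelope width sigma(s) in pixels for size index s in 1..17."""
    if not (1 <= s <= 17) or int(s) != s:
        raise ValueError(f"size index s must be an integer in 1..17, got {s}")
    return 0.0036 * s**2 + 0.35 * s + 0.18


def lambda_of_size(s: int) -> float:
    """Carrier wavelength lambda(s) = sigma(s) / 0.8 in pixels."""
    return sigma_of_size(s) / 0.8


@dataclass(frozen=True)
class GaborFilter:
    """One discretized Gabor filter with its sampled array."""

    theta_deg: float
    size_s: int
    sigma: float
    lambda_: float
    gamma: float
    support_halfwidth: int
    array: np.ndarray

    @property
    def support(self) -> int:
        return 2 * self.support_halfwidth + 1


def gabor_value(x: float, y: float, filt: GaborFilter) -> float:
    """Raw (unnormalized) Gabor function of ``filt`` at coordinates (x, y)."""
    return float(
        _gabor_raw(
            np.asarray(x, dtype=float),
            np.asarray(y, dtype=float),
            np.deg2rad(filt.theta_deg),
            filt.sigma,
            filt.lambda_,
            filt.gamma,
        )
    )


def _gabor_raw(x, y, theta: float, sigma: float, lam: float, gamma: float):
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    return np.exp(-(xp**2 + gamma**2 * yp**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * xp / lam
    )


@dataclass
class GaborFilterBank:
    """All 68 filters, ordered orientation-major then by size."""

    filters: list[GaborFilter]
    gamma: float
    normalization_mode: str

    def __len__(self) -> int:
        return len(self.filters)

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(sorted({f.theta_deg for f in self.filters}))

    @property
    def max_halfwidth(self) -> int:
        return max(f.support_halfwidth for f in self.filters)


def _normalize(G: np.ndarray, mode: str) -> np.ndarray:
    if mode == "unit_sum":
        return G / G[G > 0].sum()
    if mode == "zero_mean":
        G0 = G - G.mean()
        return G0 / G0[G0 > 0].sum()
    if mode == "reciprocal":
        total = G.sum()
        if abs(total) < 1e-4 * np.abs(G).sum():
            raise FloatingPointError(
                "integral of G is numerically ~0 at lambda = sigma/0.8; the "
                "reciprocal normalization is undefined here - use "
                "normalization_mode='unit_sum' instead"
            )
        N = 1.0 / total
        heaviside = (G >= 1.0 - 1e-12).astype(float)
        return (1.0 + N * heaviside) * G
    raise ValueError(f"normalization_mode must be one of {NORMALIZATION_MODES}")


def build_bank(gamma: float = 1.0, normalization_mode: str = "unit_sum") -> GaborFilterBank:
    """Construct the 68-filter bank on integer pixel grids.

    Each filter is sampled on a square grid with half-width ceil(5 sigma)
    pixels (covering > 99.999% of the Gaussian envelope mass) and normalized
    per ``normalization_mode``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if normalization_mode not in NORMALIZATION_MODES:
        raise ValueError(f"normalization_mode must be one of {NORMALIZATION_MODES}")
    filters = []
    for theta_deg in THETAS_DEG:
        theta = np.deg2rad(theta_deg)
        for s in SIZES:
            sigma = sigma_of_size(s)
            lam = lambda_of_size(s)
            half = int(np.ceil(5.0 * sigma))
            yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
            G = _gabor_raw(xx, yy, theta, sigma, lam, gamma)
            filters.append(
                GaborFilter(
                    theta_deg=theta_deg,
                    size_s=s,
                    sigma=sigma,
                    lambda_=lam,
                    gamma=gamma,
                    support_halfwidth=half,
                    array=_normalize(G, normalization_mode),
                )
            )
    return GaborFilterBank(filters=filters, gamma=gamma,
                           normalization_mode=normalization_mode)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Coerce an image array to 2-D luminance (Rec. 601 for RGB input)."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3] @ REC601
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {image.shape}")


def feature_vector(image: np.ndarray, bank: GaborFilterBank) -> np.ndarray:
    """The 68 mean-absolute filter responses of one image.

    The image is converted to luminance, reflectively padded by each filter's
    support half-width, and 2-D convolved at 'same' extent; the feature is
    the mean of the absolute filtered pixel values.
    """
    lum = to_luminance(image)
    max_half = bank.max_halfwidth
    if min(lum.shape) <= max_half:
        raise ValueError(
            f"image min side {min(lum.shape)} must exceed the largest filter "
            f"support half-width ({max_half} px) for reflective-border convolution"
        )
    feats = np.empty(len(bank))
    for i, f in enumerate(bank.filters):
        h = f.support_halfwidth
        padded = np.pad(lum, h, mode="reflect")
        # Gabor arrays are point-symmetric, so convolution == correlation
        out = fftconvolve(padded, f.array, mode="valid")
        feats[i] = np.mean(np.abs(out))
    return feats


def median_feature_density(features: np.ndarray) -> float:
    """Median of the 68 features (mean-of-middle-two for even length)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 1 or len(features) != N_FILTERS:
        raise ValueError(f"expected a length-{N_FILTERS} feature vector")
    return float(np.median(features))


class GaborFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping image stacks to 68-feature vectors.

    Parameters
    ----------
    gamma : float, default 1.0
        Envelope aspect ratio (1 = circular).
    normalization_mode : str, default "unit_sum"
        See module docstring.

    Attributes
    ----------
    bank_ : GaborFilterBank
        The constructed filter bank (after :meth:`fit`).
    """

    def __init__(self, gamma: float = 1.0, normalization_mode: str = "unit_sum"):
        self.gamma = gamma
        self.normalization_mode = normalization_mode

    def fit(self, X=None, y=None) -> "GaborFeatureExtractor":
        self.bank_ = build_bank(self.gamma, self.normalization_mode)
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of images (2-D luminance or RGB) -> (n, 68) features."""
        if not hasattr(self, "bank_"):
            raise RuntimeError("call fit() before transform()")
        return np.vstack([feature_vector(img, self.bank_) for img in X])

    def median_density(self, X) -> np.ndarray:
        """Per-image median feature density, the scalar complexity index."""
        return np.median(self.transform(X), axis=1)
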