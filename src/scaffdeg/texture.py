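"""Per-pixel texture features for trainable segmentation.

Two texture descriptors are computed per colour channel, in both RGB and
hue/saturation/brightness space:

* the eigenvalues of the smoothed structure tensor

      J = [ <f_x, f_x>_w  <f_x, f_y>_w ]
          [ <f_x, f_y>_w  <f_y, f_y>_w ]

  where f_x, f_y are central-difference partial derivatives and <.,.>_w is
  a Gaussian averaging window of width sigma — the eigenvalues summarise
  local orientation strength;

* the Shannon entropy of the intensity histogram in a circular
  neighbourhood of radius r around each pixel.

Together with the raw intensities this gives a 24-feature stack
(6 channels x {intensity, lambda_max, lambda_min, entropy}) per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ValidationError, as_rgb_array, check, rgb_to_hsb_u8

__all__ = [
    "StructureTensorParams",
    "EntropyParams",
    "FeatureStack",
    "structure_tensor_eigen",
    "local_entropy",
    "build_feature_stack",
    "TextureFeatureExtractor",
]

CHANNEL_NAMES = ("R", "G", "B", "H", "S", "V")
PER_CHANNEL_FEATURES = ("intensity", "lambda_max", "lambda_min", "entropy")


@dataclass(frozen=True)
class StructureTensorParams:
    """Gaussian window width of the <.,.>_w products, in pixels."""

    sigma: float = 2.0

    def __post_init__(self):
        check(self.sigma > 0, "sigma must be > 0")


@dataclass(frozen=True)
class EntropyParams:
    """Circular neighbourhood radius and histogram resolution.

    Entropy is in bits (log base 2) and bounded by log2(n_bins).
    """

    radius: int = 4
    n_bins: int = 256

    def __post_init__(self):
        check(self.radius >= 1, "radius must be >= 1")
        check(self.n_bins >= 2, "n_bins must be >= 2")


@dataclass(frozen=True)
class FeatureStack:
    """(H, W, F) float32 feature array with its ordered feature names."""

    data: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        check(self.data.ndim == 3, "feature stack must be (H, W, F)")
        check(self.data.shape[2] == len(self.feature_names),
              "feature_names must match the stack depth")

    @property
    def shape(self):
        return self.data.shape

    def to_matrix(self) -> np.ndarray:
        """Flatten to an (n_pixels, F) matrix in row-major pixel order."""
        h, w, f = self.data.shape
        return self.data.reshape(h * w, f)


def structure_tensor_eigen(channel, params: StructureTensorParams | None = None):
    """Per-pixel eigenvalues of the smoothed structure tensor.

    Gradients are central differences with reflect boundary handling; the
    tensor entries are Gaussian-smoothed products of gradients; the
    eigenvalues come from the closed form for a symmetric 2x2 matrix,
    lambda = tr/2 +- sqrt((tr/2)^2 - det).  Returns ``(lambda_max,
    lambda_min)`` maps of the input's shape; both are >= 0 up to numerical
    slack because J is positive semidefinite.
    """
    params = params or StructureTensorParams()
    f = np.asarray(channel, dtype=np.float64)
    check(f.ndim == 2, "channel must be 2-D")
    check(f.shape[0] >= 3 and f.shape[1] >= 3, "channel must be at least 3x3")
    if not np.all(np.isfinite(f)):
        raise ValidationError("channel contains non-finite values")
    fy, fx = np.gradient(f)
    s = params.sigma
    jxx = gaussian_filter(fx * fx, s, mode="reflect")
    jxy = gaussian_filter(fx * fy, s, mode="reflect")
    jyy = gaussian_filter(fy * fy, s, mode="reflect")
    half_tr = 0.5 * (jxx + jyy)
    # discriminant of the characteristic polynomial; clip tiny negatives
    disc = np.sqrt(np.clip(half_tr**2 - (jxx * jyy - jxy**2), 0.0, None))
    return half_tr + disc, half_tr - disc


def _circular_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy**2 + xx**2 <= radius**2).astype(np.uint8)


def local_entropy(channel, params: EntropyParams | None = None) -> np.ndarray:
    """Shannon entropy (bits) of the intensity histogram in a circular
    neighbourhood around each pixel.

    Intensities are binned into ``n_bins`` equal-width bins over [0, 256);
    at image borders the neighbourhood is cropped to the image.  A constant
    neighbourhood has entropy 0; the upper bound is log2(n_bins).
    """
    from skimage.filters.rank import entropy as _rank_entropy

    params = params or EntropyParams()
    f = np.asarray(channel)
    check(f.ndim == 2, "channel must be 2-D")
    check(params.radius <= min(f.shape) // 2,
          "entropy radius exceeds half the smaller image dimension")
    check(np.all((f >= 0) & (f <= 255)), "intensities must lie in [0, 255]")
    binned = (np.asarray(f, dtype=np.float64) * params.n_bins / 256.0)
    binned = np.clip(np.floor(binned), 0, params.n_bins - 1).astype(np.uint8 if params.n_bins <= 256 else np.uint16)
    return _rank_entropy(binned, _circular_footprint(params.radius))


def build_feature_stack(image,
                        tensor_params: StructureTensorParams | None = None,
                        entropy_params: EntropyParams | None = None) -> FeatureStack:
    """Compute the full 24-feature per-pixel stack of an RGB image.

    For each of the six channels (R, G, B, then hue, saturation,
    brightness scaled to [0, 255]) the stack holds the raw intensity, both
    structure-tensor eigenvalues and the local entropy, in that order.
    The feature name order is part of the public contract: models trained
    on one stack check it before predicting on another.
    """
    tensor_params = tensor_params or StructureTensorParams()
    entropy_params = entropy_params or EntropyParams()
    rgb = as_rgb_array(image)
    hsb = rgb_to_hsb_u8(rgb)
    channels = [rgb[..., i] for i in range(3)] + [hsb[..., i].astype(np.float64) for i in range(3)]
    planes, names = [], []
    for name, ch in zip(CHANNEL_NAMES, channels):
        lam_max, lam_min = structure_tensor_eigen(ch, tensor_params)
        ent = local_entropy(ch, entropy_params)
        for feat, plane in zip(PER_CHANNEL_FEATURES, (ch, lam_max, lam_min, ent)):
            planes.append(plane)
            names.append(f"{name}_{feat}")
    data = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(data=data, feature_names=tuple(names))


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer from RGB images to per-pixel feature stacks.

    ``transform`` accepts one (H, W, 3) image or a list of them and returns
    the corresponding :class:`FeatureStack` (or list).  Exposed as an
    estimator so texture parameters participate in sklearn parameter
    search / cloning; ``fit`` is a no-op.
    """

    def __init__(self, sigma: float = 2.0, entropy_radius: int = 4,
                 n_bins: int = 256):
        self.sigma = sigma
        self.entropy_radius = entropy_radius
        self.n_bins = n_bins

    def _params(self):
        return (StructureTensorParams(sigma=self.sigma),
                EntropyParams(radius=self.entropy_radius, n_bins=self.n_bins))

    def fit(self, X=None, y=None):
        self._params()  # validate
        return self

    def transform(self, X):
        tp, ep = self._params()
        if isinstance(X, (list, tuple)):
            return [build_feature_stack(img, tp, ep) for img in X]
        return build_feature_stack(X, tp, ep)
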