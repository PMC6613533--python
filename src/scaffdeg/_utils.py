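"""Shared helpers: validation, colour conversion, seeding."""

from __future__ import annotations

import numpy as np

#: Luma weights used for every grayscale conversion in the package
#: (thresholding baseline, histogram mode).
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Physical pixel scale of the micrographs: 300 um are imaged over 189 px.
DEFAULT_PIXEL_SCALE_UM = 300.0 / 189.0

#: Label encoding shared by every module.
LABEL_BACKGROUND = 0
LABEL_COLLAGEN = 1
LABEL_ECM = 2
LABEL_NUCLEI = 3
CLASS_NAMES = ("background", "collagen", "extracellular_matrix", "nuclei")
N_CLASSES = 4


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def as_rgb_array(image) -> np.ndarray:
    """Return ``image`` as an (H, W, 3) float array; reject non-RGB input.

    Accepts a raw array or any object with a ``pixels`` attribute (e.g. a
    :class:`~scaffdeg.synthetic.Micrograph`).
    """
    if hasattr(image, "pixels"):
        image = image.pixels
    arr = np.asarray(image)
    check(arr.ndim == 3 and arr.shape[2] == 3,
          f"expected an RGB image of shape (H, W, 3), got shape {arr.shape}")
    check(np.all(np.isfinite(arr)), "image contains non-finite values")
    return arr.astype(np.float64)


def to_grayscale_u8(image) -> np.ndarray:
    """8-bit luma conversion (0.299 R + 0.587 G + 0.114 B, rounded)."""
    arr = as_rgb_array(image)
    luma = arr @ LUMA_WEIGHTS
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def rgb_to_hsb_u8(image) -> np.ndarray:
    """RGB -> hue/saturation/brightness, each scaled to [0, 255].

    Hue is treated as an ordinary linear channel; its circularity is ignored
    downstream (documented limitation of the entropy binning).
    """
    from skimage.color import rgb2hsv

    arr = as_rgb_array(image) / 255.0
    hsv = rgb2hsv(arr)
    return np.clip(np.rint(hsv * 255.0), 0, 255).astype(np.uint8)


def rng_from_seed(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
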