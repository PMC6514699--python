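"""Pre-processing: greyscale conversion, Gaussian smoothing, binarisation.

Images are plain :class:`numpy.ndarray` rasters, origin at the top-left,
``x`` increasing rightward (columns) and ``y`` downward (rows).  RGB images
are ``(H, W, 3)`` uint8; intensity images are ``(H, W)`` in ``[0, 255]``;
binary masks are ``(H, W)`` arrays whose values are exactly 0 or 1, with
1 marking *dark* foreground (leaf, frame, tick marks on a light plate).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import PreprocessConfig
from .errors import DegenerateImageError, InvalidInputError, InvalidParameterError

__all__ = ["to_grayscale", "smooth", "binarize", "preprocess"]


def _require_intensity(image: np.ndarray, op: str) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise InvalidInputError(f"{op} expects a non-empty 2D intensity image, got shape {image.shape}")
    return image


def to_grayscale(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Convert an RGB image to intensity by the weighted-average method.

    Each output pixel is ``round(wR*R + wG*G + wB*B)``.  The default
    weights are ITU-R BT.601 ``(0.299, 0.587, 0.114)``.  Images that are
    already single-channel greyscale are rejected: callers should skip the
    conversion (the operation is the identity on R=G=B inputs anyway).
    """
    config = config or PreprocessConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise InvalidInputError(f"to_grayscale expects an (H, W, 3) RGB image, got shape {image.shape}")
    w = np.asarray(config.gray_weights, dtype=np.float64)
    gray = image.astype(np.float64) @ w
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective border handling.

    ``sigma`` is the kernel standard deviation in pixels; ``sigma == 0``
    returns the input unchanged (the identity filter).  Reflective borders
    conserve total image mass, so the mean intensity is preserved.
    """
    image = _require_intensity(image, "smooth")
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return image.astype(np.float64, copy=True)
    return ndimage.gaussian_filter(image.astype(np.float64), sigma=sigma, mode="reflect")


def binarize(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Threshold an intensity image into a {0, 1} mask, dark pixels -> 1.

    With ``threshold_method == "otsu"`` the threshold maximises the
    between-class variance of the intensity histogram; a constant image has
    no two classes and raises :class:`DegenerateImageError`.  With
    ``"fixed"``, pixels strictly below ``fixed_threshold`` are foreground.
    """
    config = config or PreprocessConfig()
    image = _require_intensity(image, "binarize")
    if config.threshold_method == "fixed":
        return (image < float(config.fixed_threshold)).astype(np.uint8)
    if np.ptp(image) == 0:
        raise DegenerateImageError("constant image: Otsu threshold undefined (no two classes)")
    # quantise to 8-bit so the criterion is an exact search over integer
    # thresholds; skimage's threshold is the last value of the dark class
    quant = np.rint(image).clip(0, 255).astype(np.uint8)
    if np.ptp(quant) == 0:
        raise DegenerateImageError("constant image after quantisation")
    thresh = int(threshold_otsu(quant))
    return (quant <= thresh).astype(np.uint8)


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full pre-processing chain: greyscale -> smooth -> binarise.

    Accepts either RGB or intensity input and returns a {0, 1} mask with
    dark-object polarity.
    """
    config = config or PreprocessConfig()
    image = np.asarray(image)
    if image.ndim == 3:
        image = to_grayscale(image, config)
    gray = smooth(image, config.gauss_sigma)
    return binarize(gray, config)
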