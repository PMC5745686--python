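"""Channel normalization and colorspace conversions.

Intraoral fluorescence photographs arrive as 8-bit RGB rasters whose
exposure varies between shots.  The pipeline first rescales each color
channel to the unit interval per image, then converts to the cylindrical
HSV representation (for 405 nm fluorescence images, where plaque reds and
enamel greens separate cleanly in hue) or to CIE L*a*b* (for reference
intraoral cameras that recolor plaque in yellow/orange hues).

Conversions delegate to :mod:`skimage.color`; this module adds input
validation, the unit-interval hue convention, and an exactly neutral gray
axis in L*a*b* (see :func:`rgb_to_lab`).
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "as_float_rgb",
    "normalize_channels",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb_to_lab",
]


def _validate_shape(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[-1] == 4:
        warnings.warn("alpha channel dropped", stacklevel=3)
        image = image[..., :3]
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB raster, got shape {image.shape}; "
            "grayscale inputs are not supported"
        )
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("empty image: height and width must be >= 1")
    return image


def as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Validate an RGB raster and return it as float64.

    8-bit integer input is mapped to [0, 1] by dividing by 255; float input
    must already lie in [0, 1].  Alpha channels are dropped with a warning;
    anything that is not an H x W x 3 (or H x W x 4) raster is rejected.
    """
    image = _validate_shape(image)
    if np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() > 255:
            raise ValueError("integer RGB values must lie in [0, 255]")
        return image.astype(np.float64) / 255.0
    out = image.astype(np.float64)
    if not np.isfinite(out).all():
        raise ValueError("RGB values must be finite")
    if out.min() < 0.0 or out.max() > 1.0:
        raise ValueError("float RGB values must lie in [0, 1]")
    return out


def normalize_channels(image: np.ndarray) -> np.ndarray:
    """Min-max rescale each color channel independently to [0, 1].

    Equalizes the dynamic range of the red, green and blue channels per
    image so that exposure and illumination differences between shots do
    not move pixels across fixed thresholds.  A channel with zero range
    (constant value) maps to all zeros.  Idempotent: a channel already
    spanning [0, 1] is returned unchanged.
    """
    out = as_float_rgb(image).copy()
    for c in range(3):
        ch = out[..., c]
        lo, hi = ch.min(), ch.max()
        if hi > lo:
            out[..., c] = (ch - lo) / (hi - lo)
        else:
            out[..., c] = 0.0
    return out


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert unit-interval RGB to HSV with hue on [0, 1].

    Standard hexcone mapping: hue is the color angle divided by 360 deg
    (so the plaque-red union wraps through 1 == 0), saturation and value
    are on [0, 1].  Achromatic pixels get hue 0 and saturation exactly 0.
    """
    image = _validate_shape(image)
    if np.issubdtype(image.dtype, np.integer):
        raise ValueError("rgb_to_hsv expects normalized unit-interval RGB")
    image = as_float_rgb(image)
    return _skcolor.rgb2hsv(image)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse hexcone mapping, HSV (all channels on [0, 1]) to RGB."""
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 HSV raster, got {hsv.shape}")
    if hsv.min() < 0.0 or hsv.max() > 1.0:
        raise ValueError("HSV channels must lie in [0, 1]")
    return _skcolor.hsv2rgb(hsv)


# White point of the sRGB linear-transform matrix itself (XYZ of RGB white).
# skimage's rounded matrix maps pure white slightly off its stored D65
# coordinates; rescaling by the ratio puts every gray exactly on the
# neutral axis (a* = b* = 0) instead of ~2e-3 off.
_MATRIX_WHITE = _skcolor.rgb2xyz(np.ones((1, 1, 3)))
_D65_WHITE = _skcolor.lab2xyz(np.array([[[100.0, 0.0, 0.0]]]))


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert RGB (8-bit or unit-interval, interpreted as sRGB) to CIE L*a*b*.

    Uses the sRGB transfer function and primaries with the D65 white point.
    L* lies in [0, 100]; a* and b* are signed chroma axes (green-red and
    blue-yellow).  Gray pixels map exactly onto a* = b* = 0.
    """
    image = as_float_rgb(image)
    xyz = _skcolor.rgb2xyz(image)
    return _skcolor.xyz2lab(xyz * (_D65_WHITE / _MATRIX_WHITE))


def relative_value(image: np.ndarray) -> np.ndarray:
    """Per-pixel HSV value (max channel) of a unit-interval RGB raster."""
    return as_float_rgb(image).max(axis=-1)
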