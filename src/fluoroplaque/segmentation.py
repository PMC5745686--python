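"""Per-pixel plaque / tooth / background segmentation.

Two imaging modes are supported:

* **fluorescence** — 405 nm illumination.  Porphyrins in mature plaque
  fluoresce red (~640 nm) and sound enamel autofluoresces green, so pixels
  are classified by closed-interval threshold bands in HSV.  The shipped
  plaque bands are H in [0, 0.1] or [0.82, 1], S in [0.15, 1], V in
  [0.1, 1]; the tooth (green autofluorescence) band defaults to
  H in [0.16, 0.50] with the same S/V floors.
* **reference** — a commercial plaque-mode intraoral camera that recolors
  detected plaque yellow/deep-orange.  Plaque pixels are isolated by bands
  in CIE L*a*b*: L* in [0, 90], a* in [-20, 13], b* in [17, 78].

Segmentation is pure per-pixel thresholding with no morphological
post-processing; plaque takes precedence over tooth if a user-supplied
configuration makes the bands overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .colorspace import (
    as_float_rgb,
    normalize_channels,
    relative_value,
    rgb_to_hsv,
    rgb_to_lab,
)

__all__ = [
    "BACKGROUND",
    "TOOTH",
    "PLAQUE",
    "ThresholdBand",
    "FluorescenceThresholds",
    "ReferenceThresholds",
    "SegmentationResult",
    "classify_pixel_fluorescence",
    "segment_hsv",
    "segment_fluorescence",
    "segment_reference",
    "render_overlay",
]

# Label codes for the segmentation raster.
BACKGROUND = 0
TOOTH = 1
PLAQUE = 2


@dataclass(frozen=True)
class ThresholdBand:
    """A closed numeric interval [lo, hi]; membership is lo <= x <= hi."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValueError("band bounds must be finite")
        if self.lo > self.hi:
            raise ValueError(f"band lower bound {self.lo} exceeds upper bound {self.hi}")

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x)
        return (x >= self.lo) & (x <= self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _as_bands(bands) -> tuple[ThresholdBand, ...]:
    if isinstance(bands, ThresholdBand):
        return (bands,)
    return tuple(
        b if isinstance(b, ThresholdBand) else ThresholdBand(*b) for b in bands
    )


def _in_any(bands: Sequence[ThresholdBand], x) -> np.ndarray:
    x = np.asarray(x)
    mask = np.zeros(x.shape, dtype=bool)
    for band in bands:
        mask |= band.contains(x)
    return mask


@dataclass(frozen=True)
class FluorescenceThresholds:
    """HSV threshold bands for 405 nm fluorescence images.

    Plaque defaults are the red hue union with saturation and value floors
    that exclude washed-out and near-black pixels.  Tooth defaults cover the
    green autofluorescence of enamel (hue centered near 1/3) with the same
    floors.  Hue is circular on [0, 1]: 1.0 and 0.0 are the same angle and
    both endpoints fall inside the red union.
    """

    plaque_hue: tuple[ThresholdBand, ...] = (
        ThresholdBand(0.0, 0.1),
        ThresholdBand(0.82, 1.0),
    )
    plaque_sat: ThresholdBand = ThresholdBand(0.15, 1.0)
    plaque_val: ThresholdBand = ThresholdBand(0.1, 1.0)
    tooth_hue: tuple[ThresholdBand, ...] = (ThresholdBand(0.16, 0.50),)
    tooth_sat: ThresholdBand = ThresholdBand(0.15, 1.0)
    tooth_val: ThresholdBand = ThresholdBand(0.1, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "plaque_hue", _as_bands(self.plaque_hue))
        object.__setattr__(self, "tooth_hue", _as_bands(self.tooth_hue))
        for name in ("plaque_sat", "plaque_val", "tooth_sat", "tooth_val"):
            band = getattr(self, name)
            if not isinstance(band, ThresholdBand):
                object.__setattr__(self, name, ThresholdBand(*band))
        for band in (
            *self.plaque_hue,
            self.plaque_sat,
            self.plaque_val,
            *self.tooth_hue,
            self.tooth_sat,
            self.tooth_val,
        ):
            if band.lo < 0.0 or band.hi > 1.0:
                raise ValueError("HSV threshold bounds must lie in [0, 1]")

    def replace(self, **kwargs) -> "FluorescenceThresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ReferenceThresholds:
    """L*a*b* plaque bands for reference-device plaque-mode images."""

    L_band: ThresholdBand = ThresholdBand(0.0, 90.0)
    a_band: ThresholdBand = ThresholdBand(-20.0, 13.0)
    b_band: ThresholdBand = ThresholdBand(17.0, 78.0)

    def __post_init__(self) -> None:
        for name in ("L_band", "a_band", "b_band"):
            band = getattr(self, name)
            if not isinstance(band, ThresholdBand):
                object.__setattr__(self, name, ThresholdBand(*band))
        if self.L_band.lo < 0.0 or self.L_band.hi > 100.0:
            raise ValueError("L* band must lie within [0, 100]")

    def replace(self, **kwargs) -> "ReferenceThresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SegmentationResult:
    """Label raster over {background, tooth, plaque} plus class pixel counts."""

    labels: np.ndarray
    n_plaque: int
    n_tooth: int
    n_background: int

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "SegmentationResult":
        labels = np.asarray(labels)
        return cls(
            labels=labels,
            n_plaque=int(np.count_nonzero(labels == PLAQUE)),
            n_tooth=int(np.count_nonzero(labels == TOOTH)),
            n_background=int(np.count_nonzero(labels == BACKGROUND)),
        )

    @property
    def n_pixels(self) -> int:
        return self.labels.size


def classify_pixel_fluorescence(
    hsv_pixel: Sequence[float],
    thresholds: FluorescenceThresholds | None = None,
) -> int:
    """Classify a single (hue, sat, val) pixel; plaque takes precedence."""
    t = thresholds or FluorescenceThresholds()
    h, s, v = (float(x) for x in hsv_pixel)
    if _in_any(t.plaque_hue, h) and t.plaque_sat.contains(s) and t.plaque_val.contains(v):
        return PLAQUE
    if _in_any(t.tooth_hue, h) and t.tooth_sat.contains(s) and t.tooth_val.contains(v):
        return TOOTH
    return BACKGROUND


def segment_hsv(
    hsv: np.ndarray, thresholds: FluorescenceThresholds | None = None
) -> SegmentationResult:
    """Vectorized fluorescence classification of an H x W x 3 HSV raster."""
    t = thresholds or FluorescenceThresholds()
    hsv = np.asarray(hsv, dtype=np.float64)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    plaque = _in_any(t.plaque_hue, h) & t.plaque_sat.contains(s) & t.plaque_val.contains(v)
    tooth = _in_any(t.tooth_hue, h) & t.tooth_sat.contains(s) & t.tooth_val.contains(v)
    labels = np.zeros(h.shape, dtype=np.uint8)
    labels[tooth] = TOOTH
    labels[plaque] = PLAQUE  # assigned last: plaque precedence on overlap
    return SegmentationResult.from_labels(labels)


def segment_fluorescence(
    image: np.ndarray,
    thresholds: FluorescenceThresholds | None = None,
    *,
    normalize: bool = True,
) -> SegmentationResult:
    """Segment a 405 nm fluorescence RGB image into plaque/tooth/background.

    Pipeline: per-channel min-max normalization (skippable for inputs that
    are already normalized), hexcone HSV transform, per-pixel closed-band
    thresholding.
    """
    rgb = normalize_channels(image) if normalize else as_float_rgb(image)
    return segment_hsv(rgb_to_hsv(rgb), thresholds)


def classify_lab(
    lab: np.ndarray, thresholds: ReferenceThresholds | None = None
) -> np.ndarray:
    """Boolean plaque mask from an L*a*b* raster (all three bands must hold)."""
    t = thresholds or ReferenceThresholds()
    lab = np.asarray(lab, dtype=np.float64)
    return (
        t.L_band.contains(lab[..., 0])
        & t.a_band.contains(lab[..., 1])
        & t.b_band.contains(lab[..., 2])
    )


def segment_reference(
    image: np.ndarray,
    thresholds: ReferenceThresholds | None = None,
    *,
    value_floor: float = 0.1,
) -> SegmentationResult:
    """Segment a reference-device plaque-mode RGB image.

    Plaque pixels satisfy the three L*a*b* bands simultaneously.  The
    reference device only recolors plaque, so the tooth class is defined
    operationally: any non-plaque pixel bright enough to be on a tooth
    (HSV value >= ``value_floor``, the same floor the fluorescence bands
    use) counts toward the coverage denominator; near-black pixels are
    background.  Channels are not renormalized: the L*a*b* bands are stated
    on the absolute 8-bit sRGB scale.
    """
    rgb = as_float_rgb(image)
    plaque = classify_lab(rgb_to_lab(rgb), thresholds)
    bright = relative_value(rgb) >= value_floor
    labels = np.zeros(plaque.shape, dtype=np.uint8)
    labels[bright] = TOOTH
    labels[plaque] = PLAQUE
    return SegmentationResult.from_labels(labels)


#: Default overlay highlight: cyan, maximally distinct from both the red
#: plaque fluorescence and the green tooth autofluorescence.
HIGHLIGHT_COLOR = (0.0, 1.0, 1.0)


def render_overlay(
    image: np.ndarray,
    result: SegmentationResult,
    *,
    color: Sequence[float] = HIGHLIGHT_COLOR,
    opacity: float = 0.5,
) -> np.ndarray:
    """Tint plaque pixels with a highlight color; other pixels pass through.

    Output pixel = (1 - opacity) * input + opacity * color on plaque pixels.
    """
    rgb = as_float_rgb(image)
    if result.labels.shape != rgb.shape[:2]:
        raise ValueError(
            f"label raster {result.labels.shape} does not match image {rgb.shape[:2]}"
        )
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must lie in [0, 1]")
    out = rgb.copy()
    mask = result.labels == PLAQUE
    out[mask] = (1.0 - opacity) * out[mask] + opacity * np.asarray(color, dtype=np.float64)
    return out
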