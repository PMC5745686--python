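"""Seeded phantom intraoral fluorescence images with exact ground truth.

No clinical image set accompanies the published method, so validation runs
on synthetic phantoms that reproduce the color logic of a 405 nm
fluorescence photograph: a band of rectangular "teeth" whose pixels sit
strictly inside the green-autofluorescence HSV band, plaque blobs drawn
strictly inside the red plaque bands and concentrated along the gingival
margin and interproximal gaps (where plaque actually accumulates),
optional dark non-fluorescent restoration patches, and dark out-of-band
background.  Every pixel carries an exact truth label, so with zero noise
the full normalize-convert-threshold pipeline must recover the true
coverage ratio bit-exactly.

Geometry is deliberately schematic — rectangles and gaps, not tooth
anatomy — because exact ground truth matters more here than realism.
Each phantom plants one pure-black and one pure-white background pixel so
that per-channel min-max normalization is the identity on the noise-free
image (real photographs are assumed to span their dynamic range).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .colorspace import hsv_to_rgb
from .metrics import coverage_ratio
from .segmentation import (
    BACKGROUND,
    PLAQUE,
    TOOTH,
    FluorescenceThresholds,
    ThresholdBand,
    segment_fluorescence,
)

__all__ = [
    "RESTORATION",
    "HSVBandModel",
    "PhantomSpec",
    "PhantomImage",
    "sample_in_band",
    "generate_phantom",
    "corruption_sweep",
]

#: Truth-only label for non-fluorescent filling material inside the tooth
#: region.  Restorations lack autofluorescence, render dark, and are
#: excluded from the coverage denominator (the pipeline sees background).
RESTORATION = 3

_DEFAULT_BANDS = FluorescenceThresholds()


def sample_in_band(
    hue_bands: ThresholdBand | Sequence[ThresholdBand],
    sat_band: ThresholdBand,
    val_band: ThresholdBand,
    rng: np.random.Generator,
    *,
    margin: float = 0.01,
    size: int | None = None,
) -> np.ndarray:
    """Draw HSV pixels uniformly from strictly inside a band triple.

    Each coordinate is sampled from [lo + margin, hi - margin] so that
    float round-off in rendering and re-conversion cannot push a pixel
    across a closed band edge.  ``hue_bands`` may be a union; a band is
    then picked per pixel with probability proportional to its usable
    width.  Any band narrower than ``2 * margin`` is rejected.
    """
    if isinstance(hue_bands, ThresholdBand):
        hue_bands = (hue_bands,)
    hue_bands = tuple(hue_bands)
    for band in (*hue_bands, sat_band, val_band):
        if band.width < 2 * margin:
            raise ValueError(
                f"band [{band.lo}, {band.hi}] is narrower than 2*margin={2 * margin}"
            )
    n = 1 if size is None else int(size)
    widths = np.array([b.width - 2 * margin for b in hue_bands])
    if widths.sum() > 0:
        choice = rng.choice(len(hue_bands), size=n, p=widths / widths.sum())
    else:  # all hue bands degenerate to points at lo + margin
        choice = rng.integers(0, len(hue_bands), size=n)
    lo = np.array([b.lo + margin for b in hue_bands])[choice]
    hi = np.array([b.hi - margin for b in hue_bands])[choice]
    hue = rng.uniform(lo, hi)
    sat = rng.uniform(sat_band.lo + margin, sat_band.hi - margin, size=n)
    val = rng.uniform(val_band.lo + margin, val_band.hi - margin, size=n)
    out = np.stack([hue, sat, val], axis=-1)
    return out[0] if size is None else out


@dataclass(frozen=True)
class HSVBandModel:
    """Uniform HSV color model confined strictly inside a band triple."""

    hue_bands: tuple[ThresholdBand, ...]
    sat_band: ThresholdBand
    val_band: ThresholdBand
    margin: float = 0.02

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return sample_in_band(
            self.hue_bands, self.sat_band, self.val_band, rng, margin=self.margin, size=n
        )


def _default_plaque_model() -> HSVBandModel:
    return HSVBandModel(
        _DEFAULT_BANDS.plaque_hue, _DEFAULT_BANDS.plaque_sat, _DEFAULT_BANDS.plaque_val
    )


def _default_tooth_model() -> HSVBandModel:
    return HSVBandModel(
        _DEFAULT_BANDS.tooth_hue, _DEFAULT_BANDS.tooth_sat, _DEFAULT_BANDS.tooth_val
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Defaults describe a plausible anterior-teeth frame: a 192 x 256 image
    whose tooth region (plaque included) covers 60% of the frame, with the
    plaque fraction set to 0.079 — the average coverage ratio observed
    clinically — and no sensor noise.
    """

    height: int = 192
    width: int = 256
    plaque_fraction: float = 0.079
    tooth_fraction: float = 0.6
    restoration_fraction: float = 0.0
    noise_sd: float = 0.0
    n_teeth: int = 4
    plaque_color_model: HSVBandModel = field(default_factory=_default_plaque_model)
    tooth_color_model: HSVBandModel = field(default_factory=_default_tooth_model)
    background_value_range: tuple[float, float] = (0.0, 0.09)
    restoration_value_range: tuple[float, float] = (0.0, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if not 0.0 <= self.plaque_fraction <= 1.0:
            raise ValueError("plaque_fraction must lie in [0, 1]")
        if not 0.0 < self.tooth_fraction <= 1.0:
            raise ValueError("tooth_fraction must lie in (0, 1]")
        if not 0.0 <= self.restoration_fraction < 1.0:
            raise ValueError("restoration_fraction must lie in [0, 1)")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_teeth < 1:
            raise ValueError("n_teeth must be >= 1")

    def replace(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhantomImage:
    """A rendered phantom: unit-interval RGB image plus exact truth."""

    image: np.ndarray
    truth_labels: np.ndarray
    true_ratio: float
    spec: PhantomSpec

    @property
    def n_true_plaque(self) -> int:
        return int(np.count_nonzero(self.truth_labels == PLAQUE))

    @property
    def n_true_tooth(self) -> int:
        return int(np.count_nonzero(self.truth_labels == TOOTH))


def _tooth_region(spec: PhantomSpec, rng: np.random.Generator):
    """Lay out the tooth-region mask with exact pixel count.

    A horizontal band of ``n_teeth`` rectangles separated by 1-3 px
    interproximal gaps; the band height is chosen so the region holds
    exactly round(tooth_fraction * H * W) pixels (a partial last row
    absorbs the remainder).
    """
    H, W = spec.height, spec.width
    n_region = round(spec.tooth_fraction * H * W)
    if n_region < 1:
        raise ValueError("tooth_fraction leaves no tooth pixels at this image size")

    n_teeth = spec.n_teeth if W >= 4 * spec.n_teeth else max(1, W // 4)
    gap_widths = rng.integers(1, 4, size=max(0, n_teeth - 1))
    gap_cols: set[int] = set()
    for i, gw in enumerate(gap_widths):
        start = round((i + 1) * W / n_teeth)
        gap_cols.update(range(start, min(start + int(gw), W)))
    tooth_cols = np.array(sorted(set(range(W)) - gap_cols), dtype=int)
    w_eff = len(tooth_cols)

    band_h, rem = divmod(n_region, w_eff)
    rows_needed = band_h + (1 if rem else 0)
    if rows_needed > H:
        raise ValueError(
            f"tooth_fraction {spec.tooth_fraction} infeasible: needs {rows_needed} "
            f"rows of {w_eff} usable columns but the image has only {H} rows"
        )
    r0 = (H - rows_needed) // 2
    mask = np.zeros((H, W), dtype=bool)
    mask[r0 : r0 + band_h, tooth_cols] = True
    if rem:
        mask[r0 + band_h, tooth_cols[:rem]] = True
    if np.count_nonzero(~mask) < 2:
        raise ValueError(
            "tooth_fraction leaves fewer than 2 background pixels; the phantom "
            "needs room for its black/white dynamic-range anchors"
        )
    return mask, r0, np.array(sorted(gap_cols), dtype=int)


def generate_phantom(spec: PhantomSpec) -> PhantomImage:
    """Render one phantom; deterministic given ``spec.seed``.

    Plaque pixels are the round(plaque_fraction * region) region pixels
    closest (with a small seeded jitter, for irregular blob outlines) to
    the gingival margin at the top of the tooth band or to an
    interproximal gap.  Restoration pixels, if requested, fill the deepest
    interior of the band.  Raises ``ValueError`` for infeasible fractions.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    mask, r0, gap_cols = _tooth_region(spec, rng)
    n_region = int(np.count_nonzero(mask))
    n_plaque = round(spec.plaque_fraction * n_region)
    n_rest = round(spec.restoration_fraction * n_region)
    if n_plaque + n_rest > n_region:
        raise ValueError(
            f"plaque_fraction + restoration_fraction request {n_plaque + n_rest} "
            f"pixels but the tooth region holds only {n_region}"
        )

    rows, cols = np.nonzero(mask)
    dist_margin = rows - r0
    if gap_cols.size:
        dist_gap = np.abs(cols[:, None] - gap_cols[None, :]).min(axis=1)
    else:
        dist_gap = np.full(cols.shape, H + W)
    score = np.minimum(dist_margin, dist_gap) + rng.uniform(0.0, 0.9, size=n_region)
    order = np.argsort(score, kind="stable")
    plaque_sel = order[:n_plaque]
    rest_sel = order[n_region - n_rest :] if n_rest else np.empty(0, dtype=int)

    truth = np.full((H, W), BACKGROUND, dtype=np.uint8)
    truth[rows, cols] = TOOTH
    truth[rows[plaque_sel], cols[plaque_sel]] = PLAQUE
    truth[rows[rest_sel], cols[rest_sel]] = RESTORATION

    hsv = np.zeros((H, W, 3), dtype=np.float64)
    bg_lo, bg_hi = spec.background_value_range
    hsv[..., 2] = rng.uniform(bg_lo, bg_hi, size=(H, W))  # dark achromatic base
    tooth_mask = truth == TOOTH
    plaque_mask = truth == PLAQUE
    rest_mask = truth == RESTORATION
    hsv[tooth_mask] = spec.tooth_color_model.sample(rng, int(tooth_mask.sum()))
    hsv[plaque_mask] = spec.plaque_color_model.sample(rng, int(plaque_mask.sum()))
    rlo, rhi = spec.restoration_value_range
    hsv[rest_mask, 2] = rng.uniform(rlo, rhi, size=int(rest_mask.sum()))
    hsv[rest_mask, 0] = 0.0
    hsv[rest_mask, 1] = 0.0

    image = hsv_to_rgb(hsv)
    # Dynamic-range anchors: one pure-black and one pure-white background
    # pixel make per-channel min-max normalization the identity map.
    bg = np.argwhere(~mask)
    image[tuple(bg[0])] = 0.0
    image[tuple(bg[-1])] = 1.0

    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, size=image.shape), 0.0, 1.0)

    n_tooth = int(np.count_nonzero(truth == TOOTH))
    denom = n_plaque + n_tooth
    true_ratio = n_plaque / denom if denom else float("nan")
    return PhantomImage(image=image, truth_labels=truth, true_ratio=true_ratio, spec=spec)


def pixel_error_rate(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels misclassified against truth.

    Restoration truth pixels are expected to segment as background (they
    do not fluoresce), so they are compared against the background label.
    """
    expected = np.where(truth == RESTORATION, BACKGROUND, truth)
    return float(np.mean(predicted != expected))


def corruption_sweep(
    spec: PhantomSpec,
    noise_levels: Sequence[float],
    thresholds: FluorescenceThresholds | None = None,
) -> pd.DataFrame:
    """Segmentation accuracy versus additive RGB Gaussian noise.

    One phantom per noise level, all sharing the geometry and colors of
    ``spec`` at zero noise; noise is redrawn per level from a sub-seed of
    ``spec.seed``.  Returns a table of noise_sd, true_ratio,
    recovered_ratio and pixel error rate.
    """
    base = generate_phantom(spec.replace(noise_sd=0.0))
    rows = []
    for i, sd in enumerate(noise_levels):
        if sd > 0:
            rng = np.random.default_rng([spec.seed, i])
            img = np.clip(base.image + rng.normal(0.0, sd, size=base.image.shape), 0.0, 1.0)
        else:
            img = base.image
        seg = segment_fluorescence(img, thresholds)
        rec = coverage_ratio(seg.n_plaque, seg.n_tooth)
        rows.append(
            {
                "noise_sd": float(sd),
                "true_ratio": base.true_ratio,
                "recovered_ratio": float("nan") if rec.ratio is None else rec.ratio,
                "pixel_error_rate": pixel_error_rate(seg.labels, base.truth_labels),
            }
        )
    return pd.DataFrame(rows, columns=["noise_sd", "true_ratio", "recovered_ratio", "pixel_error_rate"])
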