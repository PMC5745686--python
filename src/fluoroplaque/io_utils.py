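"""Reading and writing images, masks, overlays and phantom sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .colorspace import as_float_rgb
from .segmentation import PLAQUE, TOOTH, SegmentationResult
from .synthetic import PhantomImage

__all__ = [
    "read_rgb",
    "write_image",
    "write_mask",
    "read_mask",
    "write_phantom",
]

#: Gray levels used in mask PNGs: background 0, tooth 128, plaque 255.
_MASK_LEVELS = {0: 0, TOOTH: 128, PLAQUE: 255}


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG/TIFF as a unit-interval RGB array.

    Alpha channels are dropped (with a warning); grayscale files are
    rejected since the method needs color information.
    """
    raw = iio.imread(path)
    if raw.ndim == 2:
        raise ValueError(f"{path}: grayscale image; the pipeline requires color input")
    return as_float_rgb(raw)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a unit-interval RGB array as an 8-bit PNG/JPEG/TIFF."""
    img = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(path, (np.round(img * 255)).astype(np.uint8))


def write_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write a label raster as an 8-bit mask PNG (0/128/255 = bg/tooth/plaque)."""
    out = np.zeros(labels.shape, dtype=np.uint8)
    out[labels == TOOTH] = _MASK_LEVELS[TOOTH]
    out[labels == PLAQUE] = _MASK_LEVELS[PLAQUE]
    iio.imwrite(path, out)


def read_mask(path: str | Path) -> SegmentationResult:
    """Read a mask PNG written by :func:`write_mask` back into labels."""
    raw = iio.imread(path)
    labels = np.zeros(raw.shape, dtype=np.uint8)
    labels[raw == _MASK_LEVELS[TOOTH]] = TOOTH
    labels[raw == _MASK_LEVELS[PLAQUE]] = PLAQUE
    return SegmentationResult.from_labels(labels)


def write_phantom(outdir: str | Path, name: str, phantom: PhantomImage) -> dict:
    """Write a phantom as image PNG + truth-label PNG + sidecar JSON.

    The sidecar echoes the generating parameters and the exact true ratio.
    Returns the sidecar dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(outdir / f"{name}.png", phantom.image)
    iio.imwrite(outdir / f"{name}_truth.png", (phantom.truth_labels * 60).astype(np.uint8))
    spec = phantom.spec
    sidecar = {
        "name": name,
        "true_ratio": phantom.true_ratio,
        "n_true_plaque": phantom.n_true_plaque,
        "n_true_tooth": phantom.n_true_tooth,
        "spec": {
            "height": spec.height,
            "width": spec.width,
            "plaque_fraction": spec.plaque_fraction,
            "tooth_fraction": spec.tooth_fraction,
            "restoration_fraction": spec.restoration_fraction,
            "noise_sd": spec.noise_sd,
            "n_teeth": spec.n_teeth,
            "seed": spec.seed,
        },
    }
    (outdir / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
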