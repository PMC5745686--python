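"""Run configuration: YAML/JSON loading, threshold overrides, validation.

Unspecified threshold keys always fall back to the shipped defaults (the
published HSV plaque bands and L*a*b* reference bands), so an empty config
file reproduces the published analysis exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import (
    FluorescenceThresholds,
    ReferenceThresholds,
    ThresholdBand,
)

__all__ = ["RunConfig", "load_config", "thresholds_from_dict", "reference_from_dict"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


def _band(value, key: str) -> ThresholdBand:
    try:
        lo, hi = (float(x) for x in value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: expected a [lo, hi] pair, got {value!r}") from exc
    try:
        return ThresholdBand(lo, hi)
    except ValueError as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def _band_list(value, key: str) -> tuple[ThresholdBand, ...]:
    if value and not isinstance(value[0], (list, tuple)):
        value = [value]
    return tuple(_band(v, key) for v in value)


def thresholds_from_dict(d: dict) -> FluorescenceThresholds:
    """Build fluorescence thresholds from a config mapping; missing keys default."""
    kwargs = {}
    for key in ("plaque_hue", "tooth_hue"):
        if key in d:
            kwargs[key] = _band_list(d[key], key)
    for key in ("plaque_sat", "plaque_val", "tooth_sat", "tooth_val"):
        if key in d:
            kwargs[key] = _band(d[key], key)
    unknown = set(d) - {"plaque_hue", "tooth_hue", "plaque_sat", "plaque_val", "tooth_sat", "tooth_val"}
    if unknown:
        raise ConfigError(f"unknown fluorescence threshold keys: {sorted(unknown)}")
    try:
        return FluorescenceThresholds(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def reference_from_dict(d: dict) -> ReferenceThresholds:
    """Build reference-device thresholds from a config mapping."""
    kwargs = {}
    for key in ("L_band", "a_band", "b_band"):
        if key in d:
            kwargs[key] = _band(d[key], key)
    unknown = set(d) - {"L_band", "a_band", "b_band"}
    if unknown:
        raise ConfigError(f"unknown reference threshold keys: {sorted(unknown)}")
    try:
        return ReferenceThresholds(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunConfig:
    """Everything a batch run needs besides the input paths."""

    mode: str = "fluorescence"  # or "reference"
    fluorescence_thresholds: FluorescenceThresholds = field(
        default_factory=FluorescenceThresholds
    )
    reference_thresholds: ReferenceThresholds = field(default_factory=ReferenceThresholds)
    aggregation: str = "pooled"  # or "mean"
    subject_pattern: str = r"^([A-Za-z]+\d+)"  # capture group 1 = subject id
    overlay_opacity: float = 0.5
    normalize: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("fluorescence", "reference"):
            raise ConfigError(f"mode: must be 'fluorescence' or 'reference', got {self.mode!r}")
        if self.aggregation not in ("pooled", "mean"):
            raise ConfigError(f"aggregation: must be 'pooled' or 'mean', got {self.aggregation!r}")
        if not 0.0 <= self.overlay_opacity <= 1.0:
            raise ConfigError(f"overlay_opacity: must lie in [0, 1], got {self.overlay_opacity}")
        try:
            re.compile(self.subject_pattern)
        except re.error as exc:
            raise ConfigError(f"subject_pattern: invalid regex ({exc})") from exc

    def subject_of(self, filename: str) -> str:
        """Subject id from a filename via the configured capture group."""
        m = re.search(self.subject_pattern, Path(filename).stem)
        return m.group(1) if m and m.groups() else Path(filename).stem


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; missing keys take defaults."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text) or {}
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse config ({exc})") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    kwargs = {}
    fluo = data.pop("fluorescence_thresholds", None)
    ref = data.pop("reference_thresholds", None)
    if fluo is not None:
        kwargs["fluorescence_thresholds"] = thresholds_from_dict(fluo)
    if ref is not None:
        kwargs["reference_thresholds"] = reference_from_dict(ref)
    for key in ("mode", "aggregation", "subject_pattern", "overlay_opacity", "normalize", "log_level"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ConfigError(f"{path}: unknown config keys: {sorted(data)}")
    return RunConfig(**kwargs)
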