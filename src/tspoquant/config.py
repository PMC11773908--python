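"""Pipeline configuration.

Every tunable of the quantification pipeline lives in one flat config object
serialisable to YAML.  Intensity thresholds are deliberately data-dependent
(the original analysis set its TSPO threshold by manual inspection), so none
is hard-coded: on synthetic data they default to the generator's
foreground/background midpoint, on real data the user must supply them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


@dataclass
class PipelineConfig:
    """All tunables of the segmentation/phenotyping pipeline.

    Attributes
    ----------
    channel_map
        TIFF page index -> channel name.
    thresholds
        Per-channel intensity thresholds theta_c (strict ``>`` comparisons).
    dapi_threshold
        Fixed DAPI binarisation threshold; ``None`` selects Otsu.
    min_area, max_area
        Pixel-area bounds for a single nucleus; sub-minimum objects are
        debris ("visible nucleus" is operationalised as area >= min_area).
    c_spherical, s_min, e_min
        Shape-class cutoffs: circularity (4*pi*A/P^2) for spherical,
        solidity and eccentricity for elliptical.
    peak_h_frac
        Depth of a distance-transform maximum, as a fraction of the object's
        maximal inscribed radius, required to count as a separate lobe.
    split_step_frac
        Re-threshold increment for splitting clusters, as a fraction of the
        object's local intensity maximum.
    r_px
        Radius (Euclidean, in pixels) around the nucleus edge scanned for
        contiguous Iba1+ pixels when building the cell mask.
    min_iba1_px, min_pos_px
        Minimum above-threshold pixel counts for Iba1 positivity of a cell
        and for positivity of any other marker.
    """

    channel_map: dict[int, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    dapi_threshold: float | None = None
    min_area: int = 30
    max_area: int = 5000
    c_spherical: float = 0.85
    s_min: float = 0.90
    e_min: float = 0.85
    peak_h_frac: float = 0.20
    split_step_frac: float = 0.05
    r_px: int = 15
    min_iba1_px: int = 5
    min_pos_px: int = 5
    pixel_size_um: float = 0.325
    seed: int = 0
    output_dir: str = "."
    strict_16bit: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, value in self.thresholds.items():
            if not 0 <= value <= 65535:
                raise ConfigError(f"thresholds[{name!r}]: {value} outside [0, 65535]")
        if self.dapi_threshold is not None and not 0 <= self.dapi_threshold <= 65535:
            raise ConfigError(f"dapi_threshold: {self.dapi_threshold} outside [0, 65535]")
        if self.r_px < 0:
            raise ConfigError(f"r_px: {self.r_px} must be >= 0")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigError(f"seed: {self.seed} must be a non-negative integer")
        if self.min_area < 1:
            raise ConfigError(f"min_area: {self.min_area} must be >= 1")
        if self.max_area < self.min_area:
            raise ConfigError(f"max_area: {self.max_area} < min_area {self.min_area}")
        for key in ("c_spherical", "s_min", "peak_h_frac", "split_step_frac"):
            value = getattr(self, key)
            if not 0 < value <= 1:
                raise ConfigError(f"{key}: {value} outside (0, 1]")
        if not 0 <= self.e_min < 1:
            raise ConfigError(f"e_min: {self.e_min} outside [0, 1)")
        for key in ("min_iba1_px", "min_pos_px"):
            if getattr(self, key) < 1:
                raise ConfigError(f"{key}: {getattr(self, key)} must be >= 1")
        if self.pixel_size_um <= 0:
            raise ConfigError(f"pixel_size_um: {self.pixel_size_um} must be > 0")

    def threshold_for(self, channel: str) -> float:
        try:
            return self.thresholds[channel]
        except KeyError:
            raise ConfigError(
                f"thresholds[{channel!r}]: no threshold configured for this channel"
            ) from None

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        # YAML mapping keys must be plain scalars
        data["channel_map"] = {int(k): v for k, v in data["channel_map"].items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "channel_map" in raw and raw["channel_map"]:
            raw["channel_map"] = {int(k): str(v) for k, v in raw["channel_map"].items()}
        return cls(**raw)
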