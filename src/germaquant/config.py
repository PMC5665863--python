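"""Run configuration: channel roles, detection sizes, normalization, regions.

A single YAML file mirrors :class:`RunConfig`; every stage of the pipeline
reads its parameters from here so a run is reproducible from the config
plus the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

NORMALIZATION_MODES = ("max", "control", "decay")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    nuclear_channel: str = "nuclear"
    marker_channels: list[str] = field(default_factory=lambda: ["eya", "cas"])
    reporter_channel: str | None = "reporter"
    clone_channel: str | None = "clone"
    clone_polarity: str = "positive"  # marker present in clones / lost from clones
    coarse_diameter_um: float = 2.5
    core_diameter_um: float = 1.75
    sensitivity: float = 0.25
    background_spots: int = 10
    normalization: str = "max"
    region_boundaries_um: list[float] = field(default_factory=list)
    anterior_hint: list[float] = field(default_factory=lambda: [0.0, 0.0, -1.0])
    fate_thresholds: list[float] | None = None  # None -> auto
    depth_qc_tolerance: float = 0.15
    alpha: float = 0.05
    voxel_size_override: list[float] | None = None
    manual_add_spots: list[list[float]] = field(default_factory=list)
    manual_remove_radius_um: float = 1.0
    manual_remove_spots: list[list[float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.core_diameter_um > 0 or self.coarse_diameter_um < self.core_diameter_um:
            raise ConfigError("need coarse diameter >= core diameter > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.normalization not in NORMALIZATION_MODES:
            raise ConfigError(
                f"unknown normalization mode {self.normalization!r}; one of {NORMALIZATION_MODES}"
            )
        if self.clone_polarity not in ("positive", "negative"):
            raise ConfigError("clone_polarity must be 'positive' or 'negative'")

    @property
    def all_channels(self) -> list[str]:
        chans = [self.nuclear_channel] + list(self.marker_channels)
        if self.reporter_channel:
            chans.append(self.reporter_channel)
        if self.clone_channel:
            chans.append(self.clone_channel)
        return chans

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
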