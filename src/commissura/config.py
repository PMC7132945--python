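"""Run configuration: YAML parsing, defaults and range validation.

Two parameter "flavors" are built in, reflecting the two acquisition regimes
the pipeline is designed around:

* ``human``  — 1.25 mm isotropic voxels, 0.5 mm tracking step;
* ``ex_vivo`` — 0.5 mm isotropic voxels, 0.1 mm tracking step.

Both share a 60 degree angle threshold and 4x4x4 supersampled seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .io import ValidationError

__all__ = ["TrackingConfig", "DissectionConfig", "StatsConfig", "RunConfig", "load_config"]


@dataclass
class TrackingConfig:
    step_size_mm: float = 0.5
    angle_threshold_deg: float = 60.0
    supersample: int = 4
    max_length_mm: float = 250.0
    min_vertices: int = 3
    fa_floor: float = 0.1

    def validate(self) -> None:
        if not self.step_size_mm > 0:
            raise ValidationError("tracking.step_size_mm must be > 0")
        if not 0 < self.angle_threshold_deg < 180:
            raise ValidationError("tracking.angle_threshold_deg must be in (0, 180)")
        if self.supersample < 1:
            raise ValidationError("tracking.supersample must be >= 1")
        if not self.max_length_mm > self.step_size_mm:
            raise ValidationError("tracking.max_length_mm must exceed the step size")
        if self.min_vertices < 2:
            raise ValidationError("tracking.min_vertices must be >= 2")
        if not 0 <= self.fa_floor < 1:
            raise ValidationError("tracking.fa_floor must be in [0, 1)")


@dataclass
class DissectionConfig:
    #: transverse-segment cut planes, in sagittal slices either side of midline
    cut_offset_slices: int = 5
    #: or an explicit mm offset (overrides the slice count when set)
    cut_offset_mm: float | None = None
    #: require streamlines to *terminate* in AND ROIs rather than pass through
    and_requires_termination: bool = False

    def validate(self) -> None:
        if self.cut_offset_slices < 1:
            raise ValidationError("dissection.cut_offset_slices must be >= 1")
        if self.cut_offset_mm is not None and not self.cut_offset_mm > 0:
            raise ValidationError("dissection.cut_offset_mm must be > 0")


@dataclass
class StatsConfig:
    n_boot: int = 1000
    alpha: float = 0.05
    bayes_prior_width: float = 1.0

    def validate(self) -> None:
        if self.n_boot < 0:
            raise ValidationError("stats.n_boot must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("stats.alpha must be in (0, 1)")
        if not self.bayes_prior_width > 0:
            raise ValidationError("stats.bayes_prior_width must be > 0")


@dataclass
class RunConfig:
    flavor: str = "human"
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    dissection: DissectionConfig = field(default_factory=DissectionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> None:
        if self.flavor not in ("human", "ex_vivo"):
            raise ValidationError(f"unknown flavor {self.flavor!r}")
        self.tracking.validate()
        self.dissection.validate()
        self.stats.validate()


_FLAVOR_TRACKING = {
    "human": {"step_size_mm": 0.5, "max_length_mm": 250.0},
    "ex_vivo": {"step_size_mm": 0.1, "max_length_mm": 100.0},
}


def _apply_section(obj, section: dict, name: str) -> None:
    known = {f.name for f in fields(obj)}
    for key, value in section.items():
        if key not in known:
            raise ValidationError(f"unknown config key {name}.{key!r}")
        setattr(obj, key, value)


def load_config(path: str | None = None, flavor: str | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file (or pure defaults).

    The file may contain a top-level ``flavor`` plus ``tracking``,
    ``dissection`` and ``stats`` sections; unknown keys are rejected.  An
    explicit ``flavor`` argument wins over the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValidationError(f"config {path!r} is not a key/value mapping")
            raw = loaded
    cfg = RunConfig()
    file_flavor = raw.pop("flavor", None)
    cfg.flavor = flavor or file_flavor or "human"
    if cfg.flavor not in _FLAVOR_TRACKING:
        raise ValidationError(f"unknown flavor {cfg.flavor!r}")
    for key, value in _FLAVOR_TRACKING[cfg.flavor].items():
        setattr(cfg.tracking, key, value)
    for name, obj in (("tracking", cfg.tracking), ("dissection", cfg.dissection),
                      ("stats", cfg.stats)):
        section = raw.pop(name, None)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ValidationError(f"config section {name!r} must be a mapping")
        _apply_section(obj, section, name)
    if raw:
        raise ValidationError(f"unknown config section(s): {sorted(raw)}")
    cfg.validate()
    return cfg
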