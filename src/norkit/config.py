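"""Experiment configuration: arena calibration, objects, thresholds, gating.

The configuration is declarative (YAML or JSON) and fails closed: unknown
keys are errors, because a silently ignored typo in ``thresholds_cm`` or
``likelihood_cutoff`` would corrupt downstream science.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import yaml

__all__ = [
    "CANONICAL_LANDMARKS",
    "ConfigError",
    "LandmarkSchema",
    "ObjectSpec",
    "ExperimentConfig",
    "load_config",
]

#: The five body landmarks the pose model tracks.
CANONICAL_LANDMARKS = ("nose_tip", "left_ear", "right_ear", "body_center", "tail_base")


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass(frozen=True)
class LandmarkSchema:
    """Ordered set of landmark identifiers expected in a pose file."""

    names: tuple[str, ...] = CANONICAL_LANDMARKS

    def __post_init__(self) -> None:
        if not self.names:
            raise ConfigError("landmark schema must name at least one landmark")
        if len(set(self.names)) != len(self.names):
            raise ConfigError("landmark names must be unique")
        if any(not n for n in self.names):
            raise ConfigError("landmark names must be non-empty")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class ObjectSpec:
    """One arena object: identity, role, position and circular footprint."""

    id: str
    role: str  # "novel" | "familiar"
    center_cm: tuple[float, float]
    footprint_radius_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("novel", "familiar"):
            raise ConfigError(
                f"object {self.id!r}: role must be 'novel' or 'familiar', got {self.role!r}"
            )
        if self.footprint_radius_cm < 0:
            raise ConfigError(f"object {self.id!r}: footprint radius must be >= 0")


@dataclass(frozen=True)
class ExperimentConfig:
    """Arena geometry, object roles and all analysis parameters.

    Distances are centimetres, times seconds. ``thresholds_cm`` are the
    graded nose-to-object distance thresholds; body-centre and combined
    modes are fixed at 2 cm. The orientation gate admits a frame only when
    the head vector (ear midpoint -> nose) points within
    ``orientation_half_angle_deg`` of the nose -> object-centre direction.
    """

    objects: tuple[ObjectSpec, ...]
    px_per_cm: float = 1.0
    arena_size_cm: tuple[float, float] = (50.0, 50.0)
    thresholds_cm: tuple[float, ...] = (1.0, 1.5, 2.0)
    orientation_half_angle_deg: float = 45.0
    touch_margin_cm: float = 0.2
    min_bout_s: float = 0.1
    merge_gap_s: float = 0.2
    likelihood_cutoff: float = 0.6
    max_interp_gap_s: float = 0.5
    median_filter_window: int = 0  # odd window in frames; 0 disables smoothing
    exclude_climbing: bool = False
    preference_formula: str = "ratio"  # "ratio" | "discrimination"
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be > 0")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if self.preference_formula not in ("ratio", "discrimination"):
            raise ConfigError(
                f"preference_formula must be 'ratio' or 'discrimination', "
                f"got {self.preference_formula!r}"
            )
        thr = self.thresholds_cm
        if not thr or any(t <= 0 for t in thr) or any(
            b <= a for a, b in zip(thr, thr[1:])
        ):
            raise ConfigError("thresholds_cm must be strictly increasing and > 0")
        if self.touch_margin_cm < 0:
            raise ConfigError("touch_margin_cm must be >= 0")
        if not 0 <= self.likelihood_cutoff <= 1:
            raise ConfigError("likelihood_cutoff must be in [0, 1]")
        if self.median_filter_window not in (0, 1) and self.median_filter_window % 2 == 0:
            raise ConfigError("median_filter_window must be odd (or 0 to disable)")
        if len(self.objects) != 2:
            raise ConfigError(f"exactly 2 objects required, got {len(self.objects)}")
        roles = sorted(o.role for o in self.objects)
        if roles != ["familiar", "novel"]:
            raise ConfigError("objects must have distinct roles 'novel' and 'familiar'")
        w, h = self.arena_size_cm
        for o in self.objects:
            x, y = o.center_cm
            if not (0 <= x <= w and 0 <= y <= h):
                raise ConfigError(f"object {o.id!r} center {o.center_cm} outside arena")
        a, b = self.objects
        sep = math.dist(a.center_cm, b.center_cm)
        needed = a.footprint_radius_cm + b.footprint_radius_cm + 2 * max(thr)
        if sep <= needed:
            raise ConfigError(
                f"object zones overlap at the largest threshold: objects "
                f"{a.id!r} and {b.id!r} are {sep:.2f} cm apart but must be "
                f"> {needed:.2f} cm"
            )

    @property
    def novel(self) -> ObjectSpec:
        return next(o for o in self.objects if o.role == "novel")

    @property
    def familiar(self) -> ObjectSpec:
        return next(o for o in self.objects if o.role == "familiar")

    def object_by_id(self, object_id: str) -> ObjectSpec:
        for o in self.objects:
            if o.id == object_id:
                return o
        raise KeyError(object_id)


_TUPLE_FIELDS = {"arena_size_cm", "thresholds_cm"}


def load_config(path) -> ExperimentConfig:
    """Load and validate an :class:`ExperimentConfig` from YAML/JSON.

    Unknown keys raise :class:`ConfigError` (fail closed). Omitted keys get
    the documented defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ExperimentConfig:
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    for key in _TUPLE_FIELDS & set(kwargs):
        kwargs[key] = tuple(kwargs[key])
    if "objects" in kwargs:
        objs = []
        for entry in kwargs["objects"]:
            if isinstance(entry, ObjectSpec):
                objs.append(entry)
                continue
            entry = dict(entry)
            unknown_o = set(entry) - {"id", "role", "center_cm", "footprint_radius_cm"}
            if unknown_o:
                raise ConfigError(f"unknown object key(s): {sorted(unknown_o)}")
            entry["center_cm"] = tuple(entry["center_cm"])
            objs.append(ObjectSpec(**entry))
        kwargs["objects"] = tuple(objs)
    else:
        raise ConfigError("config must define exactly 2 objects")
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:  # e.g. malformed nested value
        raise ConfigError(str(exc)) from exc


def dump_config(config: ExperimentConfig, path) -> None:
    """Write a config back out as YAML (round-trips through load_config)."""
    doc = {
        "px_per_cm": config.px_per_cm,
        "arena_size_cm": list(config.arena_size_cm),
        "thresholds_cm": list(config.thresholds_cm),
        "orientation_half_angle_deg": config.orientation_half_angle_deg,
        "touch_margin_cm": config.touch_margin_cm,
        "min_bout_s": config.min_bout_s,
        "merge_gap_s": config.merge_gap_s,
        "likelihood_cutoff": config.likelihood_cutoff,
        "max_interp_gap_s": config.max_interp_gap_s,
        "median_filter_window": config.median_filter_window,
        "exclude_climbing": config.exclude_climbing,
        "preference_formula": config.preference_formula,
        "fps": config.fps,
        "objects": [
            {
                "id": o.id,
                "role": o.role,
                "center_cm": list(o.center_cm),
                "footprint_radius_cm": o.footprint_radius_cm,
            }
            for o in config.objects
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
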