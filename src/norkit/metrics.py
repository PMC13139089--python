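"""The 36-indicator registry for one test-phase session.

For each of the six landmark modes (NT at 1/1.5/2 cm, BC at 2 cm, combined
NT+BC at 2 cm, nose touch) and each object role we report exploration
frequency (bout count) and duration (summed bout time, s), plus a novelty
preference per mode for frequency and duration — 6 modes x (2 roles x 2
quantities + 2 preferences) = 36 indicators.

The preference index defaults to the novelty *share*,
``novel / (novel + familiar)`` in [0, 1]; the discrimination-index variant
``(novel - familiar) / (novel + familiar)`` in [-1, 1] is one config switch
away. A preference is *missing* (NaN), never 0, when the animal explored
neither object in that mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import ConfigError, ExperimentConfig
from .dlc_io import PoseRecording
from .events import default_modes, frame_mask, segment_events

__all__ = [
    "MetricSet",
    "preference_index",
    "indicator_names",
    "metric_families",
    "compute_metric_set",
]

_ROLE_SUFFIX = {"novel": "novel", "familiar": "familiar"}


@dataclass
class MetricSet:
    """Named indicator values for one session, in canonical order."""

    session_id: str
    values: dict[str, float] = field(default_factory=dict)
    paradigm: str = "NOR"  # "NOR" | "OLR" — reporting tag only

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


def preference_index(novel_value: float, familiar_value: float, formula: str = "ratio") -> float:
    """Novelty preference; NaN when the denominator (total exploration) is 0."""
    if novel_value < 0 or familiar_value < 0:
        raise ValueError("preference inputs must be non-negative")
    total = novel_value + familiar_value
    if total == 0:
        return math.nan
    if formula == "ratio":
        return novel_value / total
    if formula == "discrimination":
        return (novel_value - familiar_value) / total
    raise ValueError(f"unknown preference formula {formula!r}")


def indicator_names(config: ExperimentConfig | None = None) -> tuple[str, ...]:
    """Canonical indicator order: per mode, freq/dur x novel/familiar, then prefs."""
    config = config or _default_config()
    names = []
    for mode in default_modes(config):
        lab = mode.label
        for qty in ("freq", "dur"):
            for role in ("novel", "familiar"):
                names.append(f"{lab}_{qty}_{role}")
        names.append(f"{lab}_freq_pref")
        names.append(f"{lab}_dur_pref")
    return tuple(names)


def metric_families(config: ExperimentConfig | None = None) -> dict[str, tuple[str, ...]]:
    """Partition indicators into the traditional and refined families.

    Traditional = the six nose-tip-at-2-cm indicators scored by classic
    visual observation; refined = the remaining thirty fine-grained ones.
    """
    config = config or _default_config()
    all_names = indicator_names(config)
    trad_label = f"NT{max(config.thresholds_cm):g}"
    traditional = tuple(n for n in all_names if n.startswith(trad_label + "_"))
    refined = tuple(n for n in all_names if n not in traditional)
    return {"traditional": traditional, "refined": refined}


def compute_metric_set(
    track: PoseRecording,
    config: ExperimentConfig,
    session_id: str,
    paradigm: str = "NOR",
) -> MetricSet:
    """Run masks + segmentation for all modes and objects; assemble the registry.

    Frequency is the number of debounced bouts; duration the summed bout
    time in seconds.
    """
    if track.duration_s < 1.0:
        raise ValueError(
            f"session {session_id!r} is {track.duration_s:.2f} s long; at least 1 s required"
        )
    roles = {o.role: o for o in config.objects}
    if set(roles) != {"novel", "familiar"}:
        raise ConfigError("config must assign one novel and one familiar object")

    values: dict[str, float] = {}
    for mode in default_modes(config):
        per_role: dict[str, tuple[int, float]] = {}
        for role in ("novel", "familiar"):
            mask = frame_mask(track, roles[role], mode, config)
            events = segment_events(mask, track.fps, config.min_bout_s, config.merge_gap_s)
            per_role[role] = (len(events), sum(e.duration_s for e in events))
        lab = mode.label
        for qty, idx in (("freq", 0), ("dur", 1)):
            for role in ("novel", "familiar"):
                values[f"{lab}_{qty}_{role}"] = per_role[role][idx]
        values[f"{lab}_freq_pref"] = preference_index(
            per_role["novel"][0], per_role["familiar"][0], config.preference_formula
        )
        values[f"{lab}_dur_pref"] = preference_index(
            per_role["novel"][1], per_role["familiar"][1], config.preference_formula
        )
    return MetricSet(session_id=session_id, values=values, paradigm=paradigm)


def _default_config() -> ExperimentConfig:
    from .config import ObjectSpec

    return ExperimentConfig(
        objects=(
            ObjectSpec(id="A", role="novel", center_cm=(12.5, 12.5), footprint_radius_cm=2.0),
            ObjectSpec(id="B", role="familiar", center_cm=(37.5, 37.5), footprint_radius_cm=2.0),
        )
    )
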