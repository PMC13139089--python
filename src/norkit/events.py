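"""Exploration-event detection: per-frame masks and bout segmentation.

A frame counts toward exploration of an object under a *landmark mode*:

* ``NT(d)``  — nose tip within ``d`` cm of the object footprint **and** the
  head oriented toward the object (head-triangle gate);
* ``BC(2)``  — body centre within 2 cm of the footprint;
* ``NT_BC(2)`` — both of the above simultaneously;
* ``TOUCH`` — nose within the touch margin of the footprint, oriented.

Distances are measured to the *footprint boundary* (circle), not the object
centre, so thresholds mean the same thing for objects of different sizes.
The head-orientation gate rejects frames where the animal merely passes or
idles near the object without facing it: the head vector runs from the ear
midpoint to the nose, and must lie within a half-angle cone of the
nose-to-object direction. Maximal true runs are then debounced — runs
separated by at most ``merge_gap_s`` are merged, merged runs shorter than
``min_bout_s`` are discarded — which excludes sub-perceptual threshold
crossings due to tracking jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ExperimentConfig, ObjectSpec
from .dlc_io import PoseRecording

__all__ = [
    "LandmarkMode",
    "FrameMask",
    "ExplorationEvent",
    "default_modes",
    "distance_to_object",
    "head_direction",
    "is_oriented",
    "frame_mask",
    "segment_events",
    "brute_force_events",
]

#: Below this ear-midpoint-to-nose distance (cm) head direction is undefined.
DEGENERATE_HEAD_CM = 0.05

BC_THRESHOLD_CM = 2.0  # body-centre and combined modes are fixed at 2 cm


@dataclass(frozen=True)
class LandmarkMode:
    """Body-point rule defining exploration; NT carries a distance threshold."""

    kind: str  # "NT" | "BC" | "NT_BC" | "TOUCH"
    threshold_cm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("NT", "BC", "NT_BC", "TOUCH"):
            raise ValueError(f"unknown landmark mode kind {self.kind!r}")
        if self.kind == "NT" and (self.threshold_cm is None or self.threshold_cm <= 0):
            raise ValueError("NT mode requires a positive threshold")
        if self.kind in ("BC", "NT_BC") and self.threshold_cm not in (None, BC_THRESHOLD_CM):
            raise ValueError(f"{self.kind} mode is fixed at {BC_THRESHOLD_CM} cm")
        if self.kind == "TOUCH" and self.threshold_cm is not None:
            raise ValueError("TOUCH mode carries no threshold")

    @property
    def label(self) -> str:
        if self.kind == "NT":
            return f"NT{self.threshold_cm:g}"
        if self.kind == "BC":
            return f"BC{BC_THRESHOLD_CM:g}"
        if self.kind == "NT_BC":
            return f"NTBC{BC_THRESHOLD_CM:g}"
        return "Touch"


def default_modes(config: ExperimentConfig) -> tuple[LandmarkMode, ...]:
    """NT at each configured threshold, then BC, NT_BC, TOUCH (6 under defaults)."""
    nts = tuple(LandmarkMode("NT", t) for t in config.thresholds_cm)
    return nts + (LandmarkMode("BC"), LandmarkMode("NT_BC"), LandmarkMode("TOUCH"))


@dataclass(frozen=True)
class FrameMask:
    mode: LandmarkMode
    object_id: str
    bits: np.ndarray  # bool, length = frames


@dataclass(frozen=True)
class ExplorationEvent:
    """One contiguous valid-exploration bout (frame indices inclusive)."""

    mode: LandmarkMode
    object_id: str
    start_frame: int
    end_frame: int
    fps: float

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame + 1) / self.fps


def distance_to_object(point, obj: ObjectSpec) -> float:
    """Distance (cm) from a point to the object's footprint boundary; 0 inside."""
    d = math.dist(point, obj.center_cm) - obj.footprint_radius_cm
    return max(0.0, d)


def head_direction(nose, left_ear, right_ear):
    """Unit vector from the ear midpoint toward the nose, or None if degenerate."""
    mx = (left_ear[0] + right_ear[0]) / 2.0
    my = (left_ear[1] + right_ear[1]) / 2.0
    vx, vy = nose[0] - mx, nose[1] - my
    norm = math.hypot(vx, vy)
    if norm < DEGENERATE_HEAD_CM:
        return None
    return (vx / norm, vy / norm)


def is_oriented(nose, direction, obj: ObjectSpec, half_angle_deg: float) -> bool:
    """True iff the head vector points within ``half_angle_deg`` of the object.

    When the nose is inside the footprint the gate passes unconditionally:
    the nose-to-centre direction is ill-conditioned at contact.
    """
    tx, ty = obj.center_cm[0] - nose[0], obj.center_cm[1] - nose[1]
    tnorm = math.hypot(tx, ty)
    if tnorm <= obj.footprint_radius_cm:
        return True
    cosang = (direction[0] * tx + direction[1] * ty) / tnorm
    return cosang >= math.cos(math.radians(half_angle_deg)) - 1e-12


def _distances(track: PoseRecording, landmark: str, obj: ObjectSpec) -> np.ndarray:
    xy = track.xy(landmark)
    d = np.hypot(xy[:, 0] - obj.center_cm[0], xy[:, 1] - obj.center_cm[1])
    return np.maximum(0.0, d - obj.footprint_radius_cm)


def _orientation_ok(track: PoseRecording, obj: ObjectSpec, half_angle_deg: float) -> np.ndarray:
    """Vectorized head-triangle gate; False wherever any head landmark is invalid."""
    nose = track.xy("nose_tip")
    le = track.xy("left_ear")
    re_ = track.xy("right_ear")
    mid = (le + re_) / 2.0
    head = nose - mid
    hnorm = np.hypot(head[:, 0], head[:, 1])
    tgt = np.asarray(obj.center_cm) - nose
    tnorm = np.hypot(tgt[:, 0], tgt[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (head[:, 0] * tgt[:, 0] + head[:, 1] * tgt[:, 1]) / (hnorm * tnorm)
    ok = cosang >= math.cos(math.radians(half_angle_deg)) - 1e-12
    ok &= hnorm >= DEGENERATE_HEAD_CM  # degenerate head triangle -> invalid
    inside = tnorm <= obj.footprint_radius_cm  # containment override
    valid = (
        track.valid("nose_tip") & track.valid("left_ear") & track.valid("right_ear")
    )
    out = np.where(inside, True, ok)
    out &= valid
    return out


def frame_mask(
    track: PoseRecording, obj: ObjectSpec, mode: LandmarkMode, config: ExperimentConfig
) -> FrameMask:
    """Per-frame truth table for one (mode, object) pair on a cm-unit track."""
    if track.unit != "cm":
        raise ValueError("frame_mask requires a calibrated (cm) track")
    if mode.kind == "NT" and mode.threshold_cm not in config.thresholds_cm:
        raise ValueError(
            f"NT threshold {mode.threshold_cm} not in configured thresholds "
            f"{config.thresholds_cm}"
        )

    if mode.kind in ("NT", "TOUCH", "NT_BC"):
        d_nose = _distances(track, "nose_tip", obj)
        oriented = _orientation_ok(track, obj, config.orientation_half_angle_deg)
        nose_ok = track.valid("nose_tip")
    if mode.kind in ("BC", "NT_BC"):
        d_bc = _distances(track, "body_center", obj)
        bc_ok = track.valid("body_center")

    with np.errstate(invalid="ignore"):
        if mode.kind == "NT":
            bits = nose_ok & (d_nose <= mode.threshold_cm) & oriented
        elif mode.kind == "TOUCH":
            bits = nose_ok & (d_nose <= config.touch_margin_cm) & oriented
        elif mode.kind == "BC":
            bits = bc_ok & (d_bc <= BC_THRESHOLD_CM)
        else:  # NT_BC: framewise AND of NT(2) and BC(2)
            bits = (
                nose_ok
                & (d_nose <= BC_THRESHOLD_CM)
                & oriented
                & bc_ok
                & (d_bc <= BC_THRESHOLD_CM)
            )

    if config.exclude_climbing and mode.kind in ("NT", "TOUCH", "NT_BC"):
        # body centre on top of the object => nose frames do not count
        bc_xy = track.xy("body_center")
        with np.errstate(invalid="ignore"):
            on_obj = (
                np.hypot(bc_xy[:, 0] - obj.center_cm[0], bc_xy[:, 1] - obj.center_cm[1])
                <= obj.footprint_radius_cm
            )
        bits &= ~on_obj

    return FrameMask(mode=mode, object_id=obj.id, bits=np.asarray(bits, dtype=bool))


def segment_events(
    mask: FrameMask, fps: float, min_bout_s: float, merge_gap_s: float
) -> list[ExplorationEvent]:
    """Debounce a frame mask into exploration bouts.

    Maximal true runs separated by at most ``merge_gap_s * fps`` false
    frames are merged; merged runs shorter than ``min_bout_s`` are dropped.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    bits = np.asarray(mask.bits, dtype=bool)
    padded = np.concatenate(([False], bits, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    starts, stops = edges[::2], edges[1::2]  # runs are [start, stop)
    if starts.size == 0:
        return []

    max_gap = merge_gap_s * fps + 1e-9
    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    events = []
    for s, e in merged:
        if (e - s) / fps >= min_bout_s - 1e-9:
            events.append(
                ExplorationEvent(
                    mode=mask.mode, object_id=mask.object_id,
                    start_frame=s, end_frame=e - 1, fps=fps,
                )
            )
    return events


def brute_force_events(
    mask: FrameMask, fps: float, min_bout_s: float, merge_gap_s: float
) -> list[ExplorationEvent]:
    """Naive frame-by-frame reference implementation of :func:`segment_events`.

    Same contract, O(frames) python loop; kept as an independent oracle for
    the vectorized implementation and intended for tests and small inputs.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    bits = list(np.asarray(mask.bits, dtype=bool))
    # 1. collect maximal true runs
    runs = []
    i = 0
    while i < len(bits):
        if bits[i]:
            j = i
            while j + 1 < len(bits) and bits[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # 2. merge runs across short gaps
    max_gap = merge_gap_s * fps + 1e-9
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    # 3. discard short bouts
    out = []
    for s, e in merged:
        if (e - s + 1) / fps >= min_bout_s - 1e-9:
            out.append(
                ExplorationEvent(
                    mode=mask.mode, object_id=mask.object_id,
                    start_frame=s, end_frame=e, fps=fps,
                )
            )
    return out
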