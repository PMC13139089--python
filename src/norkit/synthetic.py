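"""Synthetic pose sessions with scripted, ground-truth-known exploration.

Emulates a 10-minute two-object arena session recorded at 30 fps: the body
centre follows a reflecting correlated random walk that avoids the object
zones, and a rigid head (nose 2 cm ahead of the body centre, ears 1 cm to
each side, 1.2 cm behind the nose) rides on the heading, so the
head-triangle orientation gate is meaningfully exercised. Scripted bouts
override the walk: the nose is parked at a commanded distance from the
object footprint with the head facing the object (or rotated 120 deg off
target for deliberately non-oriented bouts). Gaussian pose jitter and
likelihood dropouts are applied last, and coordinates are emitted in the
DLC pixel dialect at the configured scale.

Ground truth is recomputed from the *realized* noise-free trajectory, not
the script, so detector tests compare against the identical geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ExperimentConfig
from .dlc_io import PoseRecording
from .metrics import MetricSet, compute_metric_set
from .preprocess import preprocess

__all__ = [
    "Bout",
    "BoutScript",
    "GroundTruth",
    "ScriptError",
    "simulate_session",
    "random_script",
    "generate_group_study",
]

NOSE_AHEAD_CM = 2.0  # nose is this far ahead of the body centre
EAR_BEHIND_NOSE_CM = 1.2
EAR_HALF_SPAN_CM = 1.0
TAIL_BEHIND_CM = 3.0
WALL_MARGIN_CM = 3.0  # body centre keeps this far from the walls
ZONE_EXCLUSION_CM = 5.0  # body centre keeps this far from object footprints off-bout


class ScriptError(ValueError):
    """Invalid bout script."""


@dataclass(frozen=True)
class Bout:
    object_id: str
    start_s: float
    duration_s: float
    nose_distance_cm: float = 0.5
    oriented: bool = True

    def __post_init__(self) -> None:
        if self.nose_distance_cm < 0:
            raise ScriptError("nose_distance_cm must be >= 0")
        if self.duration_s <= 0:
            raise ScriptError("bout duration must be > 0")


@dataclass(frozen=True)
class BoutScript:
    """Scripted bouts plus background-motion and noise parameters."""

    bouts: tuple[Bout, ...] = ()
    speed_cm_s: float = 6.0  # background walking speed
    turn_sd_rad: float = 0.4  # per-frame heading diffusion (turning concentration)
    jitter_sd_cm: float = 0.1  # Gaussian landmark jitter
    dropout_p: float = 0.05  # per frame-landmark likelihood dropout
    dropout_likelihood: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple(sorted(self.bouts, key=lambda b: b.start_s)))
        for prev, cur in zip(self.bouts, self.bouts[1:]):
            if cur.start_s < prev.start_s + prev.duration_s:
                raise ScriptError(
                    f"bouts overlap: one ending at {prev.start_s + prev.duration_s:.2f} s, "
                    f"next starting at {cur.start_s:.2f} s"
                )


@dataclass
class GroundTruth:
    """Realized noise-free geometry plus per-threshold truth.

    ``per_threshold`` maps ``(object_id, threshold_cm)`` to
    ``(bout_count, total_time_s)`` computed from the emitted noise-free
    trajectory with the configured orientation gate (maximal runs, no
    debouncing). The touch margin appears as its own threshold entry.
    """

    fps: float
    nose_cm: np.ndarray
    body_cm: np.ndarray
    left_ear_cm: np.ndarray
    right_ear_cm: np.ndarray
    scripted_bouts: dict[str, int] = field(default_factory=dict)
    per_threshold: dict[tuple[str, float], tuple[int, float]] = field(default_factory=dict)


def _rot(vx: float, vy: float, ang: float) -> tuple[float, float]:
    c, s = math.cos(ang), math.sin(ang)
    return c * vx - s * vy, s * vx + c * vy


def simulate_session(
    script: BoutScript,
    config: ExperimentConfig,
    length_s: float = 600.0,
    fps: float = 30.0,
) -> tuple[PoseRecording, GroundTruth]:
    """Emit a pixel-unit DLC-style recording plus its ground truth."""
    if length_s <= 0:
        raise ScriptError("length_s must be > 0")
    for b in script.bouts:
        if b.start_s < 0 or b.start_s + b.duration_s > length_s:
            raise ScriptError(
                f"bout on {b.object_id!r} at {b.start_s:.2f}+{b.duration_s:.2f} s "
                f"falls outside the {length_s:.1f} s session"
            )
        config.object_by_id(b.object_id)  # KeyError -> unknown object

    frames = int(round(length_s * fps))
    rng = np.random.default_rng(script.seed)
    w, h = config.arena_size_cm
    cx, cy = w / 2.0, h / 2.0

    # frame -> active bout index (or -1)
    bout_of = np.full(frames, -1, dtype=int)
    for i, b in enumerate(script.bouts):
        f0 = int(round(b.start_s * fps))
        f1 = int(round((b.start_s + b.duration_s) * fps))
        bout_of[f0:f1] = i

    turn_steps = rng.normal(0.0, script.turn_sd_rad, size=frames)
    step = script.speed_cm_s / fps

    bx, by = cx, cy
    theta = float(rng.uniform(0, 2 * math.pi))
    body = np.empty((frames, 2))
    heading = np.empty((frames, 2))

    objs = {o.id: o for o in config.objects}
    lo_x, hi_x = WALL_MARGIN_CM, w - WALL_MARGIN_CM
    lo_y, hi_y = WALL_MARGIN_CM, h - WALL_MARGIN_CM

    for f in range(frames):
        bi = bout_of[f]
        if bi >= 0:
            b = script.bouts[bi]
            o = objs[b.object_id]
            ox, oy = o.center_cm
            ux, uy = cx - ox, cy - oy  # place the mouse on the arena-centre side
            un = math.hypot(ux, uy)
            if un < 1e-9:
                ux, uy, un = 1.0, 0.0, 1.0
            ux, uy = ux / un, uy / un
            nx = ox + (o.footprint_radius_cm + b.nose_distance_cm) * ux
            ny = oy + (o.footprint_radius_cm + b.nose_distance_cm) * uy
            hx, hy = -ux, -uy  # face the object
            if not b.oriented:
                hx, hy = _rot(hx, hy, 2 * math.pi / 3)  # 120 deg off target
            bx, by = nx - NOSE_AHEAD_CM * hx, ny - NOSE_AHEAD_CM * hy
            theta = math.atan2(hy, hx)
        else:
            theta += turn_steps[f]
            bx += step * math.cos(theta)
            by += step * math.sin(theta)
            # reflect off the walls
            if bx < lo_x:
                bx = 2 * lo_x - bx
                theta = math.pi - theta
            elif bx > hi_x:
                bx = 2 * hi_x - bx
                theta = math.pi - theta
            if by < lo_y:
                by = 2 * lo_y - by
                theta = -theta
            elif by > hi_y:
                by = 2 * hi_y - by
                theta = -theta
            # keep the body centre out of the object zones between bouts
            for o in objs.values():
                dx, dy = bx - o.center_cm[0], by - o.center_cm[1]
                dist = math.hypot(dx, dy)
                keep = o.footprint_radius_cm + ZONE_EXCLUSION_CM
                if dist < keep:
                    if dist < 1e-9:
                        dx, dy, dist = 1.0, 0.0, 1.0
                    bx = o.center_cm[0] + dx / dist * keep
                    by = o.center_cm[1] + dy / dist * keep
                    theta = math.atan2(dy, dx)  # walk away from the object
        body[f, 0], body[f, 1] = bx, by
        heading[f, 0], heading[f, 1] = math.cos(theta), math.sin(theta)

    nose = body + NOSE_AHEAD_CM * heading
    perp = np.column_stack([-heading[:, 1], heading[:, 0]])
    ear_mid = nose - EAR_BEHIND_NOSE_CM * heading
    left_ear = ear_mid + EAR_HALF_SPAN_CM * perp
    right_ear = ear_mid - EAR_HALF_SPAN_CM * perp
    tail = body - TAIL_BEHIND_CM * heading

    gt = GroundTruth(
        fps=fps, nose_cm=nose, body_cm=body,
        left_ear_cm=left_ear, right_ear_cm=right_ear,
    )
    for b in script.bouts:
        gt.scripted_bouts[b.object_id] = gt.scripted_bouts.get(b.object_id, 0) + 1
    half = math.radians(config.orientation_half_angle_deg)
    for o in config.objects:
        to_obj = np.asarray(o.center_cm) - nose
        tnorm = np.hypot(to_obj[:, 0], to_obj[:, 1])
        head = nose - ear_mid
        hnorm = np.hypot(head[:, 0], head[:, 1])
        cosang = (head[:, 0] * to_obj[:, 0] + head[:, 1] * to_obj[:, 1]) / (hnorm * tnorm)
        oriented = (cosang >= math.cos(half) - 1e-12) | (tnorm <= o.footprint_radius_cm)
        d_nose = np.maximum(0.0, np.hypot(to_obj[:, 0], to_obj[:, 1]) - o.footprint_radius_cm)
        for thr in tuple(config.thresholds_cm) + (config.touch_margin_cm,):
            m = (d_nose <= thr) & oriented
            n_runs = int(np.count_nonzero(np.diff(m.astype(np.int8), prepend=0) == 1))
            gt.per_threshold[(o.id, thr)] = (n_runs, float(m.sum() / fps))

    # --- noise & pixel emission -------------------------------------------
    stack = np.stack([nose, left_ear, right_ear, body, tail])  # (5, frames, 2)
    if script.jitter_sd_cm > 0:
        stack = stack + rng.normal(0.0, script.jitter_sd_cm, size=stack.shape)
    likelihood = rng.uniform(0.9, 1.0, size=(frames, 5))
    if script.dropout_p > 0:
        drop = rng.random(size=(frames, 5)) < script.dropout_p
        likelihood[drop] = script.dropout_likelihood

    landmarks = ("nose_tip", "left_ear", "right_ear", "body_center", "tail_base")
    x = np.column_stack([stack[i, :, 0] for i in range(5)]) * config.px_per_cm
    y = np.column_stack([stack[i, :, 1] for i in range(5)]) * config.px_per_cm
    rec = PoseRecording(
        landmarks=landmarks, x=x, y=y, likelihood=likelihood, fps=fps, unit="pixel"
    )
    return rec, gt


def random_script(
    rng: np.random.Generator,
    config: ExperimentConfig,
    length_s: float = 600.0,
    n_bouts_range: tuple[int, int] = (4, 8),
    duration_range_s: tuple[float, float] = (0.8, 2.0),
    distance_range_cm: tuple[float, float] = (0.2, 1.6),
    touch_fraction: float = 0.3,
    novel_duration_scale: float = 1.0,
    seed: int | None = None,
) -> BoutScript:
    """Draw a plausible session script: several bouts per object, random times.

    ``novel_duration_scale`` multiplies novel-object bout durations (the
    injected group effect); bouts are separated by at least 2 s so scripted
    bouts never merge during debouncing.
    """
    lo, hi = n_bouts_range
    specs = []
    for o in config.objects:
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            dur = float(rng.uniform(*duration_range_s))
            if o.role == "novel":
                dur *= novel_duration_scale
            dist = 0.0 if rng.random() < touch_fraction else float(rng.uniform(*distance_range_cm))
            specs.append((o.id, dur, dist))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    total_dur = sum(s[1] for s in specs)
    k = len(specs)
    min_gap = 2.0
    slack = length_s - total_dur - min_gap * (k + 1)
    if slack < 0:
        raise ScriptError("session too short for the requested bouts")
    fracs = rng.dirichlet(np.ones(k + 1))
    t = 0.0
    bouts = []
    for i, (obj_id, dur, dist) in enumerate(specs):
        t += min_gap + fracs[i] * slack
        bouts.append(Bout(object_id=obj_id, start_s=t, duration_s=dur, nose_distance_cm=dist))
        t += dur
    return BoutScript(
        bouts=tuple(bouts),
        seed=int(seed if seed is not None else rng.integers(0, 2**31 - 1)),
    )


def generate_group_study(
    n_per_group: int,
    effect: float = 1.0,
    config: ExperimentConfig | None = None,
    seed: int = 0,
    length_s: float = 600.0,
    fps: float = 30.0,
) -> tuple[list[MetricSet], list[MetricSet]]:
    """Two groups of simulated subjects; group B's novel-object bout
    durations are scaled by ``effect`` (1.0 = null study).

    Each subject gets an independent seed derived from the master seed; the
    full pose pipeline (noise, confidence gating, interpolation,
    calibration) runs before metrics, so group statistics see realistic
    per-subject variability.
    """
    if n_per_group < 3:
        from .group_stats import InsufficientSampleError

        raise InsufficientSampleError(
            f"need >= 3 subjects per group, got {n_per_group}"
        )
    if effect <= 0:
        raise ValueError("effect must be > 0")
    from .metrics import _default_config

    config = config or _default_config()
    master = np.random.default_rng(seed)

    groups: tuple[list[MetricSet], list[MetricSet]] = ([], [])
    for g, scale in ((0, 1.0), (1, effect)):
        label = "AB"[g]
        for i in range(n_per_group):
            sub_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            script = random_script(
                sub_rng, config, length_s=length_s, novel_duration_scale=scale
            )
            rec, _ = simulate_session(script, config, length_s=length_s, fps=fps)
            track = preprocess(rec, config)
            groups[g].append(
                compute_metric_set(track, config, session_id=f"{label}{i + 1}")
            )
    return groups


def metric_sets_to_table(metric_sets: list[MetricSet]):
    """Convenience: MetricSets -> flat per-subject DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [{"session_id": ms.session_id, **ms.values} for ms in metric_sets]
    )
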