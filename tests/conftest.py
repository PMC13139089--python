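import numpy as np
import pytest

from norkit import Bout, BoutScript, ExperimentConfig, ObjectSpec, PoseRecording

LANDMARKS = ("nose_tip", "left_ear", "right_ear", "body_center", "tail_base")


@pytest.fixture
def config() -> ExperimentConfig:
    """Default two-object arena: 50x50 cm, objects in opposite corners."""
    return ExperimentConfig(
        objects=(
            ObjectSpec(id="A", role="novel", center_cm=(12.5, 12.5), footprint_radius_cm=2.0),
            ObjectSpec(id="B", role="familiar", center_cm=(37.5, 37.5), footprint_radius_cm=2.0),
        ),
        px_per_cm=21.6,  # 1080 px across a 50 cm arena
    )


@pytest.fixture
def noise_free_script() -> BoutScript:
    """Five oriented 1-second bouts at 0.5 cm from the novel object."""
    return BoutScript(
        bouts=tuple(Bout("A", 30.0 + 20.0 * i, 1.0, 0.5) for i in range(5)),
        jitter_sd_cm=0.0,
        dropout_p=0.0,
        seed=7,
    )


def make_recording(coords: dict[str, np.ndarray], fps: float = 30.0,
                   unit: str = "cm", likelihood: np.ndarray | None = None) -> PoseRecording:
    """Build a recording from per-landmark (frames, 2) arrays; omitted landmarks
    sit parked far from both objects at (25, 45)."""
    frames = next(iter(coords.values())).shape[0]
    x = np.full((frames, 5), 25.0)
    y = np.full((frames, 5), 45.0)
    for name, arr in coords.items():
        j = LANDMARKS.index(name)
        x[:, j] = arr[:, 0]
        y[:, j] = arr[:, 1]
    lk = likelihood if likelihood is not None else np.ones((frames, 5))
    return PoseRecording(landmarks=LANDMARKS, x=x, y=y, likelihood=lk, fps=fps, unit=unit)


def parked_head(frames: int, nose_at: tuple[float, float], facing: tuple[float, float]):
    """Static head triangle: nose at ``nose_at`` facing unit vector ``facing``."""
    hx, hy = facing
    nose = np.tile(nose_at, (frames, 1)).astype(float)
    mid = nose - 1.2 * np.array([hx, hy])
    perp = np.array([-hy, hx])
    return {
        "nose_tip": nose,
        "left_ear": mid + perp,
        "right_ear": mid - perp,
        "body_center": nose - 2.0 * np.array([hx, hy]),
    }
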