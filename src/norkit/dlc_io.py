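"""Read/write DeepLabCut-dialect pose CSVs and metric/statistics tables.

The DLC CSV dialect has three header rows (scorer, bodyparts, coords) over
an index column of frame numbers, then one row per frame with an
``x, y, likelihood`` triplet per bodypart. Coordinates are pixels; the time
base (fps) is not in the file and comes from the experiment configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LandmarkSchema

__all__ = [
    "PoseFileError",
    "PoseRecording",
    "read_dlc_csv",
    "write_dlc_csv",
    "write_metrics",
    "read_metrics",
    "write_stats",
]

log = logging.getLogger("norkit")


class PoseFileError(ValueError):
    """Malformed or incomplete pose file."""


@dataclass
class PoseRecording:
    """Per-frame planar coordinates plus confidence for a set of landmarks.

    ``x``, ``y``, ``likelihood`` are float arrays of shape
    ``(frames, n_landmarks)``; missing markers are NaN in all three.
    """

    landmarks: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = 30.0
    unit: str = "pixel"  # "pixel" | "cm"
    n_dropped: dict[str, int] = field(default_factory=dict)
    n_interpolated: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        shape = (self.frames, len(self.landmarks))
        if not (self.x.shape == self.y.shape == self.likelihood.shape == shape):
            raise PoseFileError("x/y/likelihood arrays must share shape (frames, landmarks)")
        if self.fps <= 0:
            raise PoseFileError("fps must be > 0")
        if self.frames < 1:
            raise PoseFileError("recording must contain at least one frame")
        lk = self.likelihood[np.isfinite(self.likelihood)]
        if lk.size and (lk.min() < 0 or lk.max() > 1):
            raise PoseFileError("likelihood values must lie in [0, 1]")

    @property
    def frames(self) -> int:
        return self.x.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames / self.fps

    def index(self, name: str) -> int:
        return self.landmarks.index(name)

    def xy(self, name: str) -> np.ndarray:
        """(frames, 2) coordinate array for one landmark."""
        i = self.index(name)
        return np.column_stack([self.x[:, i], self.y[:, i]])

    def valid(self, name: str) -> np.ndarray:
        """Boolean validity per frame: coordinates present (non-NaN)."""
        i = self.index(name)
        return np.isfinite(self.x[:, i]) & np.isfinite(self.y[:, i])

    def copy(self) -> "PoseRecording":
        return PoseRecording(
            landmarks=self.landmarks,
            x=self.x.copy(),
            y=self.y.copy(),
            likelihood=self.likelihood.copy(),
            fps=self.fps,
            unit=self.unit,
            n_dropped=dict(self.n_dropped),
            n_interpolated=dict(self.n_interpolated),
        )


def read_dlc_csv(path, schema: LandmarkSchema | None = None, fps: float = 30.0) -> PoseRecording:
    """Parse a DeepLabCut CSV export into a pixel-unit :class:`PoseRecording`.

    Every landmark in ``schema`` must appear in the file's bodyparts header
    with x, y and likelihood columns; extra bodyparts are ignored with a
    warning. The frame index is taken from the first column.
    """
    schema = schema or LandmarkSchema()
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PoseFileError(f"{path}: not a readable DLC CSV: {exc}") from exc
    if df.columns.nlevels != 3:
        raise PoseFileError(
            f"{path}: expected three header rows (scorer/bodyparts/coords), "
            f"found {df.columns.nlevels}"
        )
    if len(df) == 0:
        raise PoseFileError(f"{path}: file contains a header but zero data rows")

    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    extra = [bp for bp in bodyparts if bp not in schema.names]
    if extra:
        log.warning("%s: ignoring extra bodyparts %s", path, extra)

    n = len(df)
    cols = {"x": np.empty((n, len(schema))), "y": np.empty((n, len(schema))),
            "likelihood": np.empty((n, len(schema)))}
    for j, name in enumerate(schema.names):
        for coord, arr in cols.items():
            matches = [
                c for c in df.columns if c[1] == name and c[2] == coord
            ]
            if not matches:
                raise PoseFileError(
                    f"{path}: landmark {name!r} has no {coord!r} column"
                )
            series = df[matches[0]]
            vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
            bad = np.isnan(vals) & ~series.isna().to_numpy()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise PoseFileError(
                    f"{path}: non-numeric value {series.iloc[row]!r} for "
                    f"{name}/{coord} at data row {row}"
                )
            arr[:, j] = vals

    return PoseRecording(
        landmarks=tuple(schema.names),
        x=cols["x"], y=cols["y"], likelihood=cols["likelihood"],
        fps=fps, unit="pixel",
    )


def write_dlc_csv(rec: PoseRecording, path, scorer: str = "norkit") -> None:
    """Write a recording in the DLC CSV dialect (inverse of read_dlc_csv)."""
    columns = pd.MultiIndex.from_tuples(
        [(scorer, lm, coord) for lm in rec.landmarks for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((rec.frames, 3 * len(rec.landmarks)))
    for j in range(len(rec.landmarks)):
        data[:, 3 * j] = rec.x[:, j]
        data[:, 3 * j + 1] = rec.y[:, j]
        data[:, 3 * j + 2] = rec.likelihood[:, j]
    df = pd.DataFrame(data, columns=columns)
    df.index.name = scorer
    df.to_csv(path, float_format="%.17g")  # %.17g round-trips doubles exactly


def write_metrics(metric_sets, path) -> None:
    """Write one or more MetricSets as a flat CSV, one row per session.

    Columns are ``session_id`` followed by the canonical indicator order.
    Undefined preferences are empty cells, never 0.
    """
    if not isinstance(metric_sets, (list, tuple)):
        metric_sets = [metric_sets]
    rows, names = [], None
    for ms in metric_sets:
        if names is None:
            names = list(ms.indicator_names)
        rows.append({"session_id": ms.session_id, **ms.values})
    df = pd.DataFrame(rows, columns=["session_id"] + (names or []))
    df.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    """Read a metric table written by :func:`write_metrics`."""
    df = pd.read_csv(path)
    if "session_id" not in df.columns:
        raise PoseFileError(f"{path}: not a metric table (no session_id column)")
    return df


def write_stats(comparisons, path) -> None:
    """Write GroupComparison rows: metric, test, p, q, effect_size, effect_type."""
    df = pd.DataFrame(
        [
            {
                "metric": c.metric,
                "family": c.family,
                "test": c.test,
                "p": c.p,
                "q": c.q,
                "effect_size": c.effect_size,
                "effect_type": c.effect_type,
                "n_a": c.n_a,
                "n_b": c.n_b,
            }
            for c in comparisons
        ]
    )
    df.to_csv(path, index=False)
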