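"""Core containers and on-disk formats.

Trajectories live in HDF5 files with a single ``keypoints3d`` dataset
(frames x 48, float64, millimetres) and ``fps`` / ``keypoint_names``
attributes.  Label sequences are single-column CSV files with a header.
Result tables are plain CSV.  Arena and rule parameters round-trip through
YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .vocab import KEYPOINT_NAMES, N_KEYPOINTS, ROW_WIDTH, VOCABULARIES

TRAJECTORY_DATASET = "keypoints3d"


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates the documented layout."""


class LabelVocabularyError(ValueError):
    """Raised when a label token is not a member of its declared vocabulary."""


@dataclass
class KeypointTrajectory:
    """Per-frame 3D coordinates of the 16 tracked body keypoints.

    Parameters
    ----------
    coords
        Array of shape (frames, 16, 3) in millimetres.  x and y span the
        horizontal plane; z is height above the arena floor.
    fps
        Recording frame rate (frames per second), 30 by default.
    """

    coords: np.ndarray
    fps: float = 30.0
    keypoint_names: tuple[str, ...] = KEYPOINT_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim == 2:
            if self.coords.shape[1] != ROW_WIDTH:
                raise TrajectoryFormatError(
                    f"flattened trajectory must have {ROW_WIDTH} columns, "
                    f"got {self.coords.shape[1]}"
                )
            self.coords = self.coords.reshape(-1, N_KEYPOINTS, 3)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 3):
            raise TrajectoryFormatError(
                f"trajectory must have shape (frames, {N_KEYPOINTS}, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise TrajectoryFormatError("trajectory must contain at least one frame")
        if not np.isfinite(self.coords).all():
            raise TrajectoryFormatError("trajectory contains non-finite coordinates")
        if self.fps <= 0:
            raise TrajectoryFormatError("fps must be positive")
        if tuple(self.keypoint_names) != KEYPOINT_NAMES:
            raise TrajectoryFormatError(
                "keypoint_names must match the canonical 16-keypoint order"
            )

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames / self.fps

    def keypoint(self, name: str) -> np.ndarray:
        """Return the (frames, 3) coordinate track of one named keypoint."""
        from .vocab import KEYPOINT_INDEX

        return self.coords[:, KEYPOINT_INDEX[name], :]

    def flat(self) -> np.ndarray:
        """Flattened (frames, 48) view in the canonical column order."""
        return self.coords.reshape(self.frames, ROW_WIDTH)


@dataclass
class LabelSequence:
    """Per-frame behavior labels paired with a named vocabulary."""

    labels: np.ndarray
    vocabulary: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or len(self.labels) < 1:
            raise LabelVocabularyError("labels must be a non-empty 1-D sequence")
        if self.vocabulary not in VOCABULARIES:
            raise LabelVocabularyError(
                f"unknown vocabulary {self.vocabulary!r}; "
                f"expected one of {sorted(VOCABULARIES)}"
            )
        allowed = set(VOCABULARIES[self.vocabulary])
        bad = sorted({t for t in self.labels if t not in allowed})
        if bad:
            raise LabelVocabularyError(
                f"tokens {bad[:5]} not in vocabulary {self.vocabulary!r}"
            )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ArenaGeometry:
    """Cylindrical open-field geometry, radii in millimetres.

    The origin sits at the centre of the arena floor; ``zone_bounds`` are the
    outer radii of the concentric center / middle / peripheral zones.
    """

    radius: float = 250.0
    zone_bounds: tuple[float, ...] = (75.0, 150.0, 250.0)
    zone_names: tuple[str, ...] = ("center", "middle", "peripheral")

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.zone_bounds)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("zone_bounds must be strictly increasing")
        if bounds[-1] != self.radius:
            raise ValueError("last zone bound must equal the arena radius")
        if len(self.zone_names) != len(bounds):
            raise ValueError("one zone name per bound required")
        self.zone_bounds = bounds


@dataclass
class RuleConfig:
    """Thresholds for the label-revision rules and kinematic filters.

    All lengths are millimetres, speeds millimetres per second, durations
    frames, so the revision thresholds read in their conventional units.
    """

    jump_back_z_mm: float = 100.0
    jump_min_frames: int = 2
    pause_speed_mm_s: float = 15.0
    climb_radius_fraction: float = 0.8
    climb_back_z_mm: float = 40.0
    rear_neck_z_mm: float = 50.0
    rear_min_frames: int = 15
    groom_min_frames: int = 300
    speed_median_window: int = 5
    stride_smooth_window: int = 5
    peak_min_prominence_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "jump_back_z_mm",
            "jump_min_frames",
            "pause_speed_mm_s",
            "climb_radius_fraction",
            "climb_back_z_mm",
            "rear_neck_z_mm",
            "rear_min_frames",
            "groom_min_frames",
            "peak_min_prominence_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("speed_median_window", "stride_smooth_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer")


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(traj: KeypointTrajectory, path: str | Path) -> None:
    """Write a trajectory to HDF5 in the package's documented layout."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(TRAJECTORY_DATASET, data=traj.flat(), dtype="float64")
        ds.attrs["fps"] = float(traj.fps)
        ds.attrs["keypoint_names"] = list(traj.keypoint_names)


def read_trajectory(path: str | Path) -> KeypointTrajectory:
    """Read and validate a frames x 48 keypoint trajectory from HDF5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if TRAJECTORY_DATASET not in f:
            raise TrajectoryFormatError(
                f"{path} has no dataset {TRAJECTORY_DATASET!r}"
            )
        ds = f[TRAJECTORY_DATASET]
        data = np.asarray(ds, dtype=np.float64)
        if data.ndim != 2 or data.shape[1] != ROW_WIDTH:
            raise TrajectoryFormatError(
                f"{path}: dataset width {data.shape[1] if data.ndim == 2 else data.shape} "
                f"does not match the expected {ROW_WIDTH} columns "
                f"({N_KEYPOINTS} keypoints x 3 coordinates)"
            )
        fps = float(ds.attrs.get("fps", 30.0))
        names = ds.attrs.get("keypoint_names", list(KEYPOINT_NAMES))
        names = tuple(n.decode() if isinstance(n, bytes) else str(n) for n in names)
    return KeypointTrajectory(coords=data, fps=fps, keypoint_names=names)


# ---------------------------------------------------------------------------
# label I/O


def write_labels(seq: LabelSequence, path: str | Path) -> None:
    """Write one label token per frame as a single-column CSV."""
    pd.DataFrame({"label": seq.labels}).to_csv(path, index=False)


def read_labels(path: str | Path, vocabulary: str) -> LabelSequence:
    """Read a per-frame label CSV and validate it against a vocabulary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] != 1:
        raise LabelVocabularyError(f"{path}: expected a single label column")
    return LabelSequence(labels=df.iloc[:, 0].to_numpy(), vocabulary=vocabulary)


# ---------------------------------------------------------------------------
# tables and configs


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write homogeneous records as UTF-8 CSV with a deterministic column order.

    Column order follows the first record (or the DataFrame); an empty record
    list yields a header-only file when passed as a DataFrame, or an empty
    file with no columns otherwise.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            cols = list(rows[0].keys())
            for r in rows:
                if list(r.keys()) != cols:
                    raise ValueError("records are not homogeneous")
            df = pd.DataFrame(rows, columns=cols)
        else:
            df = pd.DataFrame()
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(obj: ArenaGeometry | RuleConfig, path: str | Path) -> None:
    d = asdict(obj)
    d["__type__"] = type(obj).__name__
    # YAML-friendly scalars
    d = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in d.items()
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> ArenaGeometry | RuleConfig:
    d = yaml.safe_load(Path(path).read_text())
    kind = d.pop("__type__")
    cls = {"ArenaGeometry": ArenaGeometry, "RuleConfig": RuleConfig}[kind]
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return cls(**d)
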