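"""Shared fixtures: rule/arena configs, a hand-traced rule-exercise
recording, and helpers to build skeleton trajectories programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from etho3d.io_core import ArenaGeometry, KeypointTrajectory, LabelSequence, RuleConfig
from etho3d.taxonomy import default_taxonomy
from etho3d.vocab import KEYPOINT_INDEX, N_KEYPOINTS


@pytest.fixture
def rules() -> RuleConfig:
    return RuleConfig()


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture
def taxonomy():
    return default_taxonomy()


def make_skeleton(n_frames: int) -> np.ndarray:
    """A resting skeleton: all keypoints at the origin region, floor heights."""
    coords = np.zeros((n_frames, N_KEYPOINTS, 3))
    coords[:, KEYPOINT_INDEX["back"], 2] = 25.0
    coords[:, KEYPOINT_INDEX["neck"], 2] = 30.0
    coords[:, KEYPOINT_INDEX["nose"], 2] = 35.0
    return coords


def rule_exercise_recording():
    """Hand-traced 740-frame recording exercising every revision rule.

    Walking buffers separate the vertical-posture phases, since consecutive
    raw ids that merge to the same behavior would fuse into one segment.

    Phase script (frames, raw id -> merged behavior, programmed kinematics):
      0-39    c07 Walking, 60 mm/s; back z 120 on frames 20-22 (jump rule),
              back z 110 on frame 30 only (below the 2-frame minimum)
      40-79   c22 Rising at radial 210 mm, back z 60  -> Climbing_up
      80-99   c07 Walking buffer
      100-139 c23 Rising at centre, neck z 60 for 40 frames -> Rearing
      140-159 c07 Walking buffer
      160-189 c24 Rising, neck z 60 for 10 frames only, 24 mm/s -> Rising
      190-539 c13 Right_turning for 350 frames at 30 mm/s -> Grooming
      540-599 c19 Sniffing at 6 mm/s (nose and back)     -> Pausing
      600-659 c20 Sniffing, back 6 mm/s but nose 27 mm/s -> stays Sniffing
      660-739 c37 Pausing, motionless                    -> Pausing
    """
    n = 740
    fps = 30.0
    coords = make_skeleton(n)
    raw = np.empty(n, dtype=object)
    bi = KEYPOINT_INDEX["back"]
    ni = KEYPOINT_INDEX["nose"]
    ki = KEYPOINT_INDEX["neck"]

    def set_x(sl, x):
        coords[sl, :, 0] = x[:, None]

    # P0: walking along +x at 2 mm/frame
    raw[0:40] = "c07"
    set_x(slice(0, 40), np.arange(40) * 2.0)
    coords[20:23, bi, 2] = 120.0
    coords[30, bi, 2] = 110.0

    # P1: stationary near the wall, elevated back
    raw[40:80] = "c22"
    coords[40:80, :, 0] = 210.0
    coords[40:80, bi, 2] = 60.0
    coords[40:80, ki, 2] = 45.0

    # buffer
    raw[80:100] = "c07"
    set_x(slice(80, 100), np.arange(20) * 2.0)

    # P2: rearing posture at the centre
    raw[100:140] = "c23"
    coords[100:140, ki, 2] = 60.0
    coords[100:140, bi, 2] = 30.0

    # buffer
    raw[140:160] = "c07"
    set_x(slice(140, 160), np.arange(20) * 2.0)

    # P3: rising, tall neck for only 10 frames, moving at 0.8 mm/frame
    raw[160:190] = "c24"
    set_x(slice(160, 190), np.arange(30) * 0.8)
    coords[160:170, ki, 2] = 60.0
    coords[170:190, ki, 2] = 45.0

    # P4: long turning bout at 1 mm/frame
    raw[190:540] = "c13"
    set_x(slice(190, 540), np.arange(350) * 1.0)

    # P5: slow sniffing, 0.2 mm/frame everywhere
    raw[540:600] = "c19"
    set_x(slice(540, 600), np.arange(60) * 0.2)

    # P6: sniffing with only the nose moving fast enough
    raw[600:660] = "c20"
    set_x(slice(600, 660), np.arange(60) * 0.2)
    coords[600:660, ni, 0] += np.arange(60) * 0.7

    # P7: motionless pausing
    raw[660:740] = "c37"

    traj = KeypointTrajectory(coords=coords, fps=fps)
    labels = LabelSequence(labels=raw, vocabulary="raw40")
    return traj, labels


@pytest.fixture
def rule_recording():
    return rule_exercise_recording()


def random_recording(seed: int, n_frames: int = 500):
    """Randomized trajectory + raw labels for oracle-equivalence testing.

    Coordinates hover around the rule thresholds so every branch of every
    revision rule is exercised with realistic frequency.
    """
    rng = np.random.default_rng(seed)
    coords = make_skeleton(n_frames)
    # random-walk position inside the arena
    steps = rng.normal(0, 2.0, size=(n_frames, 2))
    pos = np.cumsum(steps, axis=0)
    r = np.linalg.norm(pos, axis=1)
    scale = np.where(r > 230, 230 / np.maximum(r, 1e-9), 1.0)
    pos = pos * scale[:, None] + rng.uniform(-150, 150, size=2)
    r = np.linalg.norm(pos, axis=1)
    pos *= np.where(r > 240, 240 / np.maximum(r, 1e-9), 1.0)[:, None]
    coords[:, :, 0] += pos[:, 0:1]
    coords[:, :, 1] += pos[:, 1:2]
    # z values straddling the jump/rear/climb thresholds
    coords[:, 12, 2] = rng.uniform(20, 130, size=n_frames)
    coords[:, 3, 2] = rng.uniform(30, 80, size=n_frames)
    # raw labels in runs of random length
    raw = np.empty(n_frames, dtype=object)
    ids = [f"c{i:02d}" for i in range(40)]
    t = 0
    while t < n_frames:
        length = int(rng.integers(1, 60))
        raw[t : t + length] = ids[int(rng.integers(40))]
        t += length
    return KeypointTrajectory(coords=coords, fps=30.0), LabelSequence(
        labels=raw, vocabulary="raw40"
    )
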