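"""Kinematic parameters from 3D keypoint trajectories.

Four parameter families: instantaneous movement speed (median-filtered XY
velocity of a keypoint), gait metrics (stride length / frequency from the
left fore-hind limb distance), posture angles (upper: nose-neck-back;
lower: nose-back-root_tail) and the body stretch ratio (sum of distances
from the back to seven peripheral keypoints, normalised to a reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks

from .io_core import KeypointTrajectory, RuleConfig
from .segments import SegmentList
from .vocab import LOCOMOTOR_BEHAVIORS

STRETCH_PERIPHERAL_KEYPOINTS = (
    "nose",
    "neck",
    "left_front_limb",
    "right_front_limb",
    "left_hind_limb",
    "right_hind_limb",
    "root_tail",
)


@dataclass
class GaitSummary:
    """Stride metrics for one locomotor segment.

    ``defined`` is False when fewer than one peak-valley pair was detected
    (or the segment is shorter than the smoothing window); the numeric
    fields are then NaN rather than raising.
    """

    segment_id: int
    label: str
    stride_length_mm: float
    stride_frequency_hz: float
    n_cycles: int
    defined: bool


def compute_speed_series(
    traj: KeypointTrajectory, keypoint: str, rules: RuleConfig | None = None
) -> np.ndarray:
    """Median-filtered instantaneous XY speed of one keypoint, mm/s.

    Speed at frame t is the horizontal displacement from frame t-1 to t
    times fps; the first frame copies the second.  A centred median filter
    (default 5 frames, edges replicated) suppresses single-frame tracking
    spikes.
    """
    rules = rules or RuleConfig()
    if traj.frames < 2:
        raise ValueError("speed requires at least 2 frames")
    xy = traj.keypoint(keypoint)[:, :2]
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = np.empty(traj.frames)
    speed[1:] = disp * traj.fps
    speed[0] = speed[1]
    return median_filter(speed, size=rules.speed_median_window, mode="nearest")


def compute_path_length(traj: KeypointTrajectory, rules: RuleConfig | None = None) -> float:
    """Total XY travel distance of the back keypoint, millimetres.

    Frame-to-frame displacements pass through the same median-filter policy
    as the speed series before summation, so isolated tracking spikes do not
    inflate the total.
    """
    rules = rules or RuleConfig()
    xy = traj.keypoint("back")[:, :2]
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    if disp.size == 0:
        return 0.0
    disp = median_filter(disp, size=rules.speed_median_window, mode="nearest")
    return float(disp.sum())


def compute_posture_angles(traj: KeypointTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame upper (nose-neck-back) and lower (nose-back-root_tail) angles.

    Interior angle at the middle keypoint between the two 3D bone vectors,
    in degrees within [0, 180].  Frames with a zero-length bone vector are
    flagged NaN.
    """
    upper = _interior_angle(
        traj.keypoint("nose"), traj.keypoint("neck"), traj.keypoint("back")
    )
    lower = _interior_angle(
        traj.keypoint("nose"), traj.keypoint("back"), traj.keypoint("root_tail")
    )
    return upper, lower


def _interior_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angles[(nu == 0) | (nv == 0)] = np.nan
    return angles


def compute_total_body_distance(traj: KeypointTrajectory) -> np.ndarray:
    """Per-frame sum of 3D distances from the back to 7 peripheral keypoints."""
    back = traj.keypoint("back")
    total = np.zeros(traj.frames)
    for name in STRETCH_PERIPHERAL_KEYPOINTS:
        total += np.linalg.norm(traj.keypoint(name) - back, axis=1)
    return total


def compute_stretch_ratio(
    traj: KeypointTrajectory, reference_total_mm: float
) -> np.ndarray:
    """Body stretch ratio per frame, percent of a reference total body distance.

    The reference is conventionally the control group's mean total body
    distance during sniffing, which then reads as 100%.
    """
    if reference_total_mm <= 0:
        raise ValueError("reference_total_mm must be positive")
    return 100.0 * compute_total_body_distance(traj) / reference_total_mm


def compute_stride_metrics(
    traj: KeypointTrajectory,
    segments: SegmentList,
    rules: RuleConfig | None = None,
) -> list[GaitSummary]:
    """Stride length and frequency per locomotor segment.

    Within each Running/Trotting/Walking/Stepping segment the 3D distance
    between the left fore and hind limbs is smoothed with a centred moving
    average, local peaks and valleys are detected with a prominence floor of
    ``peak_min_prominence_fraction`` times the series range, and stride
    length is the mean difference between each peak and the valley that
    follows it.  Stride frequency is detected cycles per second.
    """
    rules = rules or RuleConfig()
    dist = np.linalg.norm(
        traj.keypoint("left_front_limb") - traj.keypoint("left_hind_limb"), axis=1
    )
    out: list[GaitSummary] = []
    for seg_id, (start, end, label) in enumerate(segments):
        if label not in LOCOMOTOR_BEHAVIORS:
            continue
        series = dist[start:end]
        out.append(
            _stride_from_series(
                series, seg_id, label, traj.fps, rules
            )
        )
    return out


def _stride_from_series(
    series: np.ndarray, seg_id: int, label: str, fps: float, rules: RuleConfig
) -> GaitSummary:
    n = len(series)
    undefined = GaitSummary(seg_id, label, np.nan, np.nan, 0, False)
    if n < rules.stride_smooth_window:
        return undefined
    smooth = uniform_filter1d(
        series, size=rules.stride_smooth_window, mode="nearest"
    )
    rng = float(smooth.max() - smooth.min())
    if rng == 0.0:
        return undefined
    prom = rules.peak_min_prominence_fraction * rng
    peaks, _ = find_peaks(smooth, prominence=prom)
    valleys, _ = find_peaks(-smooth, prominence=prom)
    if len(peaks) == 0 or len(valleys) == 0:
        return undefined
    # pair each peak with the first valley after it; drop unpaired trailing peaks
    diffs = []
    for p in peaks:
        later = valleys[valleys > p]
        if later.size:
            diffs.append(smooth[p] - smooth[later[0]])
    if not diffs:
        return undefined
    stride_length = float(np.mean(diffs))
    n_cycles = len(diffs)
    duration_s = n / fps
    return GaitSummary(
        segment_id=seg_id,
        label=label,
        stride_length_mm=stride_length,
        stride_frequency_hz=n_cycles / duration_s,
        n_cycles=n_cycles,
        defined=True,
    )
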