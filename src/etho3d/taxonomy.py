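"""Ethogram taxonomy: raw-phenotype merging and rule-based label revision.

The upstream unsupervised clustering emits 40 anonymous phenotype labels per
frame.  These are merged into a 13-behavior ethogram by a configurable
surjective map, then refined by five kinematic rules (jumping, the
climbing/rising/rearing split, grooming, pausing) whose thresholds live in
:class:`~etho3d.io_core.RuleConfig`.  Finally the 13 behaviors roll up into
four functional clusters (Locomotion, Exploration, Maintenance, Nap).

Rule order is fixed: merge -> jumping -> vertical postures -> grooming ->
pausing.  Grooming must see the post-split Rearing/Climbing/Rising labels,
and pausing's source set includes Grooming, so pausing runs last.  All
threshold comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_core import ArenaGeometry, KeypointTrajectory, LabelSequence, RuleConfig
from .kinematics import compute_speed_series
from .segments import SegmentList, segments_from_labels
from .vocab import BEHAVIOR_TO_CLUSTER, BEHAVIORS_13, CLUSTERS_4, RAW40

__all__ = [
    "BehaviorTaxonomy",
    "default_taxonomy",
    "merge_raw_phenotypes",
    "revise_jumping",
    "revise_vertical_postures",
    "revise_grooming",
    "revise_pausing",
    "run_relabel_pipeline",
    "map_to_clusters",
    "segments_from_labels",
    "SegmentList",
]

# Labels eligible for each revision rule.
GROOM_SOURCE = {"Rearing", "Climbing_up", "Rising", "Right_turning", "Left_turning"}
PAUSE_SOURCE = {
    "Sniffing",
    "Stepping",
    "Grooming",
    "Right_turning",
    "Left_turning",
    "Rising",
    "Trotting",
}
VERTICAL_SOURCE = {"Rising", "Climbing_up"}


@dataclass
class BehaviorTaxonomy:
    """Maps raw phenotype ids to the 13 behaviors and behaviors to clusters."""

    raw_to_behavior: dict[str, str]
    behavior_to_cluster: dict[str, str] = field(
        default_factory=lambda: dict(BEHAVIOR_TO_CLUSTER)
    )

    def __post_init__(self) -> None:
        missing = set(RAW40) - set(self.raw_to_behavior)
        if missing:
            raise ValueError(f"raw_to_behavior missing ids: {sorted(missing)[:5]}")
        bad = set(self.raw_to_behavior.values()) - set(BEHAVIORS_13)
        if bad:
            raise ValueError(f"unknown behavior targets: {sorted(bad)}")
        if set(self.behavior_to_cluster) != set(BEHAVIORS_13):
            raise ValueError("behavior_to_cluster must cover exactly the 13 behaviors")
        if set(self.behavior_to_cluster.values()) - set(CLUSTERS_4):
            raise ValueError("cluster targets must be within the 4 clusters")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "raw_to_behavior": self.raw_to_behavior,
                    "behavior_to_cluster": self.behavior_to_cluster,
                },
                sort_keys=True,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "BehaviorTaxonomy":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            raw_to_behavior=d["raw_to_behavior"],
            behavior_to_cluster=d["behavior_to_cluster"],
        )


def default_taxonomy() -> BehaviorTaxonomy:
    """Canonical surjective raw40 -> behavior13 map used for synthetic cohorts.

    Raw ids are assigned in contiguous blocks following the canonical
    behavior order (Running receives four ids, every other behavior three),
    so all 40 ids are used and the map is surjective.
    """
    sizes = [4] + [3] * 12
    mapping: dict[str, str] = {}
    i = 0
    for behavior, size in zip(BEHAVIORS_13, sizes):
        for _ in range(size):
            mapping[RAW40[i]] = behavior
            i += 1
    return BehaviorTaxonomy(raw_to_behavior=mapping)


def merge_raw_phenotypes(
    labels: LabelSequence, taxonomy: BehaviorTaxonomy
) -> LabelSequence:
    """Collapse raw 40-phenotype labels onto the 13-behavior vocabulary."""
    if labels.vocabulary != "raw40":
        raise ValueError("merge_raw_phenotypes expects raw40 labels")
    merged = np.array(
        [taxonomy.raw_to_behavior[t] for t in labels.labels], dtype=object
    )
    return LabelSequence(labels=merged, vocabulary="behavior13")


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal (start, end_exclusive) runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e)) for s, e in zip(idx[::2], idx[1::2])]


def revise_jumping(
    traj: KeypointTrajectory, labels: LabelSequence, rules: RuleConfig
) -> LabelSequence:
    """Label as Jumping every run of frames with back height strictly above
    the jump threshold lasting at least ``jump_min_frames``."""
    _check_aligned(traj, labels)
    back_z = traj.keypoint("back")[:, 2]
    out = labels.labels.copy()
    for start, end in _runs_of(back_z > rules.jump_back_z_mm):
        if end - start >= rules.jump_min_frames:
            out[start:end] = "Jumping"
    return LabelSequence(labels=out, vocabulary=labels.vocabulary)


def revise_vertical_postures(
    traj: KeypointTrajectory,
    labels: LabelSequence,
    rules: RuleConfig,
    arena: ArenaGeometry,
) -> LabelSequence:
    """Split the vertical-posture family into Climbing_up / Rearing / Rising.

    Segments labeled Rising or Climbing_up are re-differentiated: if the
    segment-median radial distance of the front limbs (mean of left/right
    keypoints) exceeds ``climb_radius_fraction`` x arena radius and the
    segment-median back height exceeds ``climb_back_z_mm``, the segment is
    Climbing_up, otherwise Rising.  Segments then labeled Rising whose neck
    height stays above ``rear_neck_z_mm`` for at least ``rear_min_frames``
    consecutive frames become Rearing.
    """
    _check_aligned(traj, labels)
    front_xy = 0.5 * (
        traj.keypoint("left_front_limb")[:, :2]
        + traj.keypoint("right_front_limb")[:, :2]
    )
    front_radial = np.linalg.norm(front_xy, axis=1)
    back_z = traj.keypoint("back")[:, 2]
    neck_z = traj.keypoint("neck")[:, 2]
    out = labels.labels.copy()

    for start, end, label in segments_from_labels(labels):
        if label not in VERTICAL_SOURCE:
            continue
        is_climb = (
            np.median(front_radial[start:end])
            > rules.climb_radius_fraction * arena.radius
        ) and np.median(back_z[start:end]) > rules.climb_back_z_mm
        if is_climb:
            out[start:end] = "Climbing_up"
            continue
        out[start:end] = "Rising"
        high_neck = neck_z[start:end] > rules.rear_neck_z_mm
        if any(
            e - s >= rules.rear_min_frames for s, e in _runs_of(high_neck)
        ):
            out[start:end] = "Rearing"
    return LabelSequence(labels=out, vocabulary=labels.vocabulary)


def revise_grooming(labels: LabelSequence, rules: RuleConfig) -> LabelSequence:
    """Relabel long vertical-posture or turning segments as Grooming.

    Segments labeled Rearing, Climbing_up, Rising or either Turning that
    last strictly more than ``groom_min_frames`` frames become Grooming.
    """
    out = labels.labels.copy()
    for start, end, label in segments_from_labels(labels):
        if label in GROOM_SOURCE and (end - start) > rules.groom_min_frames:
            out[start:end] = "Grooming"
    return LabelSequence(labels=out, vocabulary=labels.vocabulary)


def revise_pausing(
    traj: KeypointTrajectory, labels: LabelSequence, rules: RuleConfig
) -> LabelSequence:
    """Relabel near-motionless frames inside slow behaviors as Pausing.

    Within segments labeled Sniffing, Stepping, Grooming, Turning, Rising or
    Trotting, frames where the median-filtered speeds of both the nose tip
    and the back are strictly below ``pause_speed_mm_s`` become Pausing.
    """
    _check_aligned(traj, labels)
    nose_speed = compute_speed_series(traj, "nose", rules)
    back_speed = compute_speed_series(traj, "back", rules)
    slow = (nose_speed < rules.pause_speed_mm_s) & (
        back_speed < rules.pause_speed_mm_s
    )
    in_source = np.isin(labels.labels.astype(str), sorted(PAUSE_SOURCE))
    out = labels.labels.copy()
    out[slow & in_source] = "Pausing"
    return LabelSequence(labels=out, vocabulary=labels.vocabulary)


def run_relabel_pipeline(
    traj: KeypointTrajectory,
    raw_labels: LabelSequence,
    taxonomy: BehaviorTaxonomy,
    rules: RuleConfig | None = None,
    arena: ArenaGeometry | None = None,
) -> LabelSequence:
    """Full relabeling: merge then the four revisions, in the fixed order."""
    rules = rules or RuleConfig()
    arena = arena or ArenaGeometry()
    labels = merge_raw_phenotypes(raw_labels, taxonomy)
    labels = revise_jumping(traj, labels, rules)
    labels = revise_vertical_postures(traj, labels, rules, arena)
    labels = revise_grooming(labels, rules)
    labels = revise_pausing(traj, labels, rules)
    return labels


def map_to_clusters(
    labels: LabelSequence, taxonomy: BehaviorTaxonomy | None = None
) -> LabelSequence:
    """Map 13-behavior labels onto the four functional clusters."""
    mapping = (taxonomy.behavior_to_cluster if taxonomy else BEHAVIOR_TO_CLUSTER)
    if labels.vocabulary != "behavior13":
        raise ValueError("map_to_clusters expects behavior13 labels")
    out = np.array([mapping[t] for t in labels.labels], dtype=object)
    return LabelSequence(labels=out, vocabulary="cluster4")


def _check_aligned(traj: KeypointTrajectory, labels: LabelSequence) -> None:
    if traj.frames != len(labels):
        raise ValueError(
            f"trajectory has {traj.frames} frames but labels has {len(labels)}"
        )
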