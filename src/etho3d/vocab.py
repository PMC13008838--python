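"""Shared vocabularies: keypoints, behaviors, clusters, raw phenotype ids.

These tuples are the single source of truth for ordering throughout the
package; every module imports them from here rather than redefining them.
"""

from __future__ import annotations

# Canonical keypoint order of the frames x 48 trajectory matrix
# (16 keypoints x (x, y, z), millimetres; z is height above the arena floor).
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_ear",
    "right_ear",
    "neck",
    "left_front_limb",
    "right_front_limb",
    "left_hind_limb",
    "right_hind_limb",
    "left_front_claw",
    "right_front_claw",
    "left_hind_claw",
    "right_hind_claw",
    "back",
    "root_tail",
    "middle_tail",
    "tip_tail",
)

N_KEYPOINTS = len(KEYPOINT_NAMES)
ROW_WIDTH = 3 * N_KEYPOINTS  # 48 flattened columns

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

# The 13-behavior ethogram obtained after merging the raw unsupervised
# phenotypes and applying the rule-based revisions.
BEHAVIORS_13: tuple[str, ...] = (
    "Running",
    "Trotting",
    "Walking",
    "Stepping",
    "Right_turning",
    "Left_turning",
    "Sniffing",
    "Rising",
    "Rearing",
    "Climbing_up",
    "Jumping",
    "Grooming",
    "Pausing",
)

# Four functional super-categories grouping the 13 behaviors.
CLUSTERS_4: tuple[str, ...] = ("Locomotion", "Exploration", "Maintenance", "Nap")

BEHAVIOR_TO_CLUSTER: dict[str, str] = {
    "Stepping": "Locomotion",
    "Walking": "Locomotion",
    "Trotting": "Locomotion",
    "Running": "Locomotion",
    "Right_turning": "Locomotion",
    "Left_turning": "Locomotion",
    "Rising": "Exploration",
    "Climbing_up": "Exploration",
    "Rearing": "Exploration",
    "Sniffing": "Exploration",
    "Jumping": "Exploration",
    "Grooming": "Maintenance",
    "Pausing": "Nap",
}

LOCOMOTOR_BEHAVIORS: tuple[str, ...] = ("Running", "Trotting", "Walking", "Stepping")

# Raw unsupervised phenotype vocabulary (40 anonymous cluster ids).
RAW40: tuple[str, ...] = tuple(f"c{i:02d}" for i in range(40))

VOCABULARIES: dict[str, tuple[str, ...]] = {
    "raw40": RAW40,
    "behavior13": BEHAVIORS_13,
    "cluster4": CLUSTERS_4,
}
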