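"""End-to-end cohort analysis: from trajectories and raw labels to the
per-animal metric tables, transition models, group statistics and
classifier inputs that the individual modules define.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ArenaGeometry, KeypointTrajectory, LabelSequence, RuleConfig
from .kinematics import (
    compute_speed_series,
    compute_stride_metrics,
    compute_path_length,
)
from .metrics import (
    behavior_count_matrix,
    compute_fractions,
    compute_frequencies,
    window_slices,
    zone_summaries,
)
from .segments import SegmentList, segments_from_labels
from .stats import GroupComparison, compare_groups
from .taxonomy import (
    BehaviorTaxonomy,
    default_taxonomy,
    map_to_clusters,
    run_relabel_pipeline,
)
from .transitions import TransitionModel, count_transitions, transition_entropy
from .vocab import BEHAVIORS_13, CLUSTERS_4, LOCOMOTOR_BEHAVIORS

HEADLINE_METRICS = (
    "locomotion_fraction",
    "pausing_fraction",
    "locomotor_speed_mm_s",
    "stride_length_mm",
    "peripheral_dwell_min",
    "transition_entropy_bits",
)


@dataclass
class RecordingAnalysis:
    """All per-animal quantities derived from one recording."""

    animal_id: str
    group: str
    labels: LabelSequence
    segments: SegmentList
    fraction_frames: pd.Series
    fraction_segments: pd.Series
    counts: pd.Series
    frequency_per_min: pd.Series
    cluster_fraction_frames: pd.Series
    zone_dwell_s: pd.Series
    transition_model: TransitionModel
    scalars: dict[str, float]
    window_counts: pd.DataFrame  # windows x 13 segment counts (6-min windows)


def analyze_recording(
    traj: KeypointTrajectory,
    raw_labels: LabelSequence,
    taxonomy: BehaviorTaxonomy | None = None,
    rules: RuleConfig | None = None,
    arena: ArenaGeometry | None = None,
    animal_id: str = "animal",
    group: str = "",
    similarity_window_min: float = 6.0,
) -> RecordingAnalysis:
    taxonomy = taxonomy or default_taxonomy()
    rules = rules or RuleConfig()
    arena = arena or ArenaGeometry()

    labels = run_relabel_pipeline(traj, raw_labels, taxonomy, rules, arena)
    segments = segments_from_labels(labels)
    duration_min = traj.duration_s / 60.0

    fraction_frames = compute_fractions(segments, mode="frames")
    fraction_segments = compute_fractions(segments, mode="segments")
    frequency = compute_frequencies(segments, duration_min)
    counts = (frequency * duration_min).round().astype(int)

    cluster_labels = map_to_clusters(labels, taxonomy)
    cluster_fraction = compute_fractions(
        segments_from_labels(cluster_labels), mode="frames"
    )

    back_speed = compute_speed_series(traj, "back", rules)
    loco_mask = np.isin(labels.labels.astype(str), LOCOMOTOR_BEHAVIORS)
    loco_speed = float(back_speed[loco_mask].mean()) if loco_mask.any() else np.nan

    gait = compute_stride_metrics(traj, segments, rules)
    defined = [g for g in gait if g.defined]
    stride_length = float(np.mean([g.stride_length_mm for g in defined])) if defined else np.nan
    stride_freq = float(np.mean([g.stride_frequency_hz for g in defined])) if defined else np.nan

    dwell, _zone_frac = zone_summaries(traj, labels, arena)
    model = count_transitions(segments)

    windows = window_slices(labels, similarity_window_min, traj.fps)
    window_counts = behavior_count_matrix(windows, vocabulary="behavior13")

    scalars = {
        "locomotion_fraction": float(cluster_fraction["Locomotion"]),
        "pausing_fraction": float(fraction_frames["Pausing"]),
        "locomotor_speed_mm_s": loco_speed,
        "stride_length_mm": stride_length,
        "stride_frequency_hz": stride_freq,
        "peripheral_dwell_min": float(dwell["peripheral"] / 60.0),
        "transition_entropy_bits": transition_entropy(model),
        "path_length_mm": compute_path_length(traj, rules),
        "n_segments": float(len(segments)),
    }
    return RecordingAnalysis(
        animal_id=animal_id,
        group=group,
        labels=labels,
        segments=segments,
        fraction_frames=fraction_frames,
        fraction_segments=fraction_segments,
        counts=counts,
        frequency_per_min=frequency,
        cluster_fraction_frames=cluster_fraction,
        zone_dwell_s=dwell,
        transition_model=model,
        scalars=scalars,
        window_counts=window_counts,
    )


@dataclass
class CohortResult:
    """Stacked per-animal tables for a two-group cohort."""

    animals: list[str]
    groups: np.ndarray
    scalars: pd.DataFrame          # animals x headline scalar metrics
    counts13: pd.DataFrame         # animals x 13 segment counts
    fraction_frames13: pd.DataFrame
    frequency13: pd.DataFrame
    cluster_fractions: pd.DataFrame
    models: list[TransitionModel] = field(default_factory=list)
    window_counts: dict[str, list[pd.DataFrame]] = field(default_factory=dict)

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def by_group(self, table: pd.DataFrame, group: str) -> pd.DataFrame:
        return table.loc[self.group_mask(group)]


def collect_cohort(analyses: list[RecordingAnalysis]) -> CohortResult:
    animals = [a.animal_id for a in analyses]
    groups = np.array([a.group for a in analyses], dtype=object)
    scalars = pd.DataFrame([a.scalars for a in analyses])
    counts13 = pd.DataFrame([a.counts for a in analyses]).reindex(
        columns=list(BEHAVIORS_13), fill_value=0
    )
    fracs = pd.DataFrame([a.fraction_frames for a in analyses]).reindex(
        columns=list(BEHAVIORS_13), fill_value=0.0
    )
    freqs = pd.DataFrame([a.frequency_per_min for a in analyses]).reindex(
        columns=list(BEHAVIORS_13), fill_value=0.0
    )
    cluster = pd.DataFrame([a.cluster_fraction_frames for a in analyses]).reindex(
        columns=list(CLUSTERS_4), fill_value=0.0
    )
    for df in (scalars, counts13, fracs, freqs, cluster):
        df.index = animals

    # per-group stacks of windows x 13 count matrices, reshaped to
    # per-window animals x 13 for similarity analysis
    window_counts: dict[str, list[pd.DataFrame]] = {}
    for group in dict.fromkeys(groups):
        members = [a for a in analyses if a.group == group]
        if not members:
            continue
        n_windows = min(len(m.window_counts) for m in members)
        window_counts[str(group)] = [
            pd.DataFrame(
                [m.window_counts.iloc[w] for m in members],
                index=[m.animal_id for m in members],
            )
            for w in range(n_windows)
        ]
    return CohortResult(
        animals=animals,
        groups=groups,
        scalars=scalars,
        counts13=counts13,
        fraction_frames13=fracs,
        frequency13=freqs,
        cluster_fractions=cluster,
        models=[a.transition_model for a in analyses],
        window_counts=window_counts,
    )


def analyze_cohort(recordings, **kwargs) -> CohortResult:
    """Run the full per-recording analysis over an iterable of synthetic
    Recording objects (or any object with the same attributes)."""
    analyses = [
        analyze_recording(
            rec.trajectory, rec.raw_labels,
            animal_id=rec.animal_id, group=rec.group, **kwargs,
        )
        for rec in recordings
    ]
    return collect_cohort(analyses)


def headline_comparisons(
    cohort: CohortResult,
    group_a: str = "affected",
    group_b: str = "control",
) -> dict[str, GroupComparison]:
    """Gated two-group tests on the six headline phenotypes, corrected for
    the family of six."""
    out = {}
    for metric in HEADLINE_METRICS:
        a = cohort.by_group(cohort.scalars, group_a)[metric].to_numpy()
        b = cohort.by_group(cohort.scalars, group_b)[metric].to_numpy()
        out[metric] = compare_groups(
            a[~np.isnan(a)], b[~np.isnan(b)],
            n_comparisons=len(HEADLINE_METRICS), metric_name=metric,
        )
    return out
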