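"""First-order Markov transition analysis of behavior sequences.

Transitions are counted between consecutive *segments* (occurrences), so
the diagonal is structurally zero at the behavior level.  The transition
probability P(j|i) is the count N(i->j) divided by the total number of
transitions out of i.  Derived quantities: hub nodes (network degree),
occupancy-weighted transition entropy (bits), and group difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segments import SegmentList
from .taxonomy import BehaviorTaxonomy
from .vocab import BEHAVIOR_TO_CLUSTER, VOCABULARIES


@dataclass
class TransitionModel:
    """Counts N(i->j) and row-stochastic probabilities over K states."""

    counts: np.ndarray
    state_names: tuple[str, ...]
    occupancy: np.ndarray  # per-state segment visit counts

    probs: np.ndarray = field(init=False)
    visited: np.ndarray = field(init=False)  # rows with outgoing transitions

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.state_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        self.visited = row_sums > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self.probs = np.where(
                self.visited[:, None], self.counts / np.maximum(row_sums, 1)[:, None], 0.0
            )

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, what: str = "probs") -> pd.DataFrame:
        data = getattr(self, what)
        return pd.DataFrame(data, index=list(self.state_names),
                            columns=list(self.state_names))


def count_transitions(segments: SegmentList) -> TransitionModel:
    """Count consecutive-segment transitions; fewer than 2 segments yields
    an all-zero model."""
    names = VOCABULARIES[segments.vocabulary]
    index = {n: i for i, n in enumerate(names)}
    k = len(names)
    counts = np.zeros((k, k))
    occupancy = np.zeros(k)
    labels = segments.labels
    for label in labels:
        occupancy[index[label]] += 1
    for a, b in zip(labels, labels[1:]):
        counts[index[a], index[b]] += 1
    return TransitionModel(counts=counts, state_names=tuple(names), occupancy=occupancy)


def collapse_to_clusters(
    segments: SegmentList, taxonomy: BehaviorTaxonomy | None = None
) -> SegmentList:
    """Map behavior segments to clusters and merge consecutive same-cluster runs."""
    mapping = taxonomy.behavior_to_cluster if taxonomy else BEHAVIOR_TO_CLUSTER
    merged: list[tuple[int, int, str]] = []
    for start, end, label in segments:
        cl = mapping[label]
        if merged and merged[-1][2] == cl:
            merged[-1] = (merged[-1][0], end, cl)
        else:
            merged.append((start, end, cl))
    return SegmentList(segments=merged, frames=segments.frames, vocabulary="cluster4")


def cluster_transition_model(
    segments: SegmentList, taxonomy: BehaviorTaxonomy | None = None,
    keep_self_loops: bool = False,
) -> TransitionModel:
    """4x4 cluster-level transition model.

    By default consecutive same-cluster segments are collapsed first, so the
    diagonal is zero; ``keep_self_loops`` instead counts behavior-level
    transitions that stay within a cluster as self-loops.
    """
    mapping = taxonomy.behavior_to_cluster if taxonomy else BEHAVIOR_TO_CLUSTER
    if keep_self_loops:
        cl_segments = [
            (s, e, mapping[label]) for s, e, label in segments
        ]
        names = VOCABULARIES["cluster4"]
        index = {n: i for i, n in enumerate(names)}
        counts = np.zeros((4, 4))
        occupancy = np.zeros(4)
        labels = [label for _, _, label in cl_segments]
        for label in labels:
            occupancy[index[label]] += 1
        for a, b in zip(labels, labels[1:]):
            counts[index[a], index[b]] += 1
        return TransitionModel(counts=counts, state_names=tuple(names),
                               occupancy=occupancy)
    return count_transitions(collapse_to_clusters(segments, taxonomy))


def hub_nodes(
    model: TransitionModel, top_k: int = 4, min_prob: float = 0.0
) -> list[tuple[str, int]]:
    """Top-k states by network degree.

    Degree of v counts distinct other states u with P(v->u) > min_prob or
    P(u->v) > min_prob.  Ties break by total occupancy, then lexicographic
    state name.
    """
    p = model.probs
    k = len(model.state_names)
    connected = (p > min_prob) | (p.T > min_prob)
    np.fill_diagonal(connected, False)
    degrees = connected.sum(axis=1)
    order = sorted(
        range(k),
        key=lambda i: (-degrees[i], -model.occupancy[i], model.state_names[i]),
    )
    return [(model.state_names[i], int(degrees[i])) for i in order[:top_k]]


def transition_entropy(model: TransitionModel) -> float:
    """Occupancy-weighted transition entropy rate, in bits.

    H = -sum_i w_i sum_j P(j|i) log2 P(j|i), with w_i the share of all
    transitions that leave state i.  Rows without outgoing transitions
    contribute nothing.  Lower values mean more stereotyped switching.
    """
    total = model.counts.sum()
    if total == 0:
        return 0.0
    w = model.counts.sum(axis=1) / total
    p = model.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    row_h = -(p * logp).sum(axis=1)
    return float((w * row_h).sum())


def group_difference(
    models_a: list[TransitionModel], models_b: list[TransitionModel]
) -> pd.DataFrame:
    """Mean per-animal P(i->j) of group A minus group B, cell-wise.

    Each animal contributes only the rows its data define (rows without
    outgoing transitions are excluded from that cell's mean).
    """
    names = models_a[0].state_names
    if any(m.state_names != names for m in models_a + models_b):
        raise ValueError("all models must share the same state space")

    def mean_probs(models: list[TransitionModel]) -> np.ndarray:
        stack = np.stack(
            [np.where(m.visited[:, None], m.probs, np.nan) for m in models]
        )
        with np.errstate(invalid="ignore"):
            return np.nanmean(stack, axis=0)

    diff = mean_probs(models_a) - mean_probs(models_b)
    return pd.DataFrame(diff, index=list(names), columns=list(names))
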