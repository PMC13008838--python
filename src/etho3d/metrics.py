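"""Ethogram summary metrics: fractions, frequencies, time windows, zones,
and cross-window behavioral similarity.

Fractions come in two modes because both are in routine use: segment-count
fractions (occurrences of a behavior over total occurrences) and
frame fractions (time share).  Time-window slicing splits segments at
window boundaries so that windowed counts conserve whole-session counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ArenaGeometry, KeypointTrajectory, LabelSequence
from .segments import SegmentList, segments_from_labels
from .vocab import VOCABULARIES

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Windows x windows mean Pearson correlation of per-animal count vectors."""

    values: np.ndarray
    window_edges_min: list[float]
    n_undefined_pairs: int = 0


def compute_fractions(
    segments: SegmentList, mode: str = "frames"
) -> pd.Series:
    """Per-behavior fraction of the recording, by frames or by segment count."""
    vocab = VOCABULARIES[segments.vocabulary]
    counts = pd.Series(0.0, index=list(vocab))
    if mode == "segments":
        if len(segments) == 0:
            raise ValueError("no segments")
        for _, _, label in segments:
            counts[label] += 1
        return counts / len(segments)
    if mode == "frames":
        if segments.frames == 0:
            raise ValueError("no frames")
        for start, end, label in segments:
            counts[label] += end - start
        return counts / segments.frames
    raise ValueError(f"unknown mode {mode!r}")


def compute_frequencies(segments: SegmentList, duration_min: float) -> pd.Series:
    """Per-behavior occurrences (segments) per minute of session."""
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    vocab = VOCABULARIES[segments.vocabulary]
    counts = pd.Series(0.0, index=list(vocab))
    for _, _, label in segments:
        counts[label] += 1
    return counts / duration_min


def window_slices(
    labels: LabelSequence, window_min: float, fps: float
) -> list[LabelSequence]:
    """Cut a session into consecutive equal time windows.

    Segments straddling a boundary are split at the boundary, each part
    counting toward its own window (this conserves total frame counts and
    total segment counts after boundary-split accounting).
    """
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    window_frames = int(round(window_min * 60 * fps))
    n = len(labels)
    out = []
    for start in range(0, n, window_frames):
        out.append(
            LabelSequence(
                labels=labels.labels[start : start + window_frames],
                vocabulary=labels.vocabulary,
            )
        )
    return out


def assign_zones(
    traj: KeypointTrajectory, arena: ArenaGeometry
) -> tuple[np.ndarray, int]:
    """Per-frame arena zone of the back keypoint, by radial distance.

    Zone intervals are half-open [lo, hi) except the outermost, which is
    closed at the arena radius.  Frames beyond the radius clamp to the
    outermost zone; their count is returned alongside the labels.
    """
    r = np.linalg.norm(traj.keypoint("back")[:, :2], axis=1)
    bounds = np.asarray(arena.zone_bounds)
    zone_idx = np.searchsorted(bounds, r, side="right")
    n_clamped = int((r > arena.radius).sum())
    if n_clamped:
        logger.warning("%d frames beyond the arena radius clamped to %s",
                       n_clamped, arena.zone_names[-1])
    zone_idx = np.minimum(zone_idx, len(bounds) - 1)
    zones = np.array(arena.zone_names, dtype=object)[zone_idx]
    return zones, n_clamped


def zone_summaries(
    traj: KeypointTrajectory,
    labels: LabelSequence,
    arena: ArenaGeometry,
) -> tuple[pd.Series, pd.DataFrame]:
    """Dwell time per zone (seconds) and per-zone behavior frame fractions.

    Dwell times sum exactly to the session duration; each occupied zone's
    behavior fractions sum to 1.
    """
    if traj.frames != len(labels):
        raise ValueError("trajectory and labels must be aligned")
    zones, _ = assign_zones(traj, arena)
    vocab = list(VOCABULARIES[labels.vocabulary])
    dwell = pd.Series(0.0, index=list(arena.zone_names))
    frac = pd.DataFrame(0.0, index=list(arena.zone_names), columns=vocab)
    for zone in arena.zone_names:
        mask = zones == zone
        n_zone = int(mask.sum())
        dwell[zone] = n_zone / traj.fps
        if n_zone:
            vals, counts = np.unique(labels.labels[mask].astype(str), return_counts=True)
            for v, c in zip(vals, counts):
                frac.loc[zone, v] = c / n_zone
    return dwell, frac


def behavior_count_matrix(
    label_sequences: list[LabelSequence], vocabulary: str | None = None
) -> pd.DataFrame:
    """Animals x behaviors matrix of segment (occurrence) counts."""
    vocab = list(VOCABULARIES[vocabulary or label_sequences[0].vocabulary])
    rows = []
    for seq in label_sequences:
        counts = dict.fromkeys(vocab, 0)
        for _, _, label in segments_from_labels(seq):
            counts[label] += 1
        rows.append(counts)
    return pd.DataFrame(rows, columns=vocab)


def similarity_matrices(
    count_matrices: list[np.ndarray | pd.DataFrame],
    window_edges_min: list[float] | None = None,
) -> SimilarityMatrix:
    """Population behavioral similarity between time windows.

    For a window pair (a, b) the entry is the mean, over all ordered animal
    pairs (i, j) including i = j, of the Pearson correlation between animal
    i's per-behavior count vector in window a and animal j's in window b.
    Zero-variance vectors yield undefined correlations, which are excluded
    from the mean (their count is logged and reported).  Diagonal entries
    are within-window population similarity and need not equal 1.
    """
    mats = [np.asarray(m, dtype=float) for m in count_matrices]
    n_animals, n_feats = mats[0].shape
    if any(m.shape != (n_animals, n_feats) for m in mats):
        raise ValueError("all windows must have the same animals x behaviors shape")
    # standardize each animal's count vector; zero-variance rows become NaN
    zs = []
    for m in mats:
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zs.append(np.where(sd > 0, (m - mu) / sd, np.nan))
    w = len(mats)
    values = np.full((w, w), np.nan)
    n_undefined = 0
    for a in range(w):
        for b in range(a, w):
            r = zs[a] @ zs[b].T / n_feats  # pairwise Pearson r
            n_undefined += int(np.isnan(r).sum()) if a <= b else 0
            values[a, b] = values[b, a] = float(np.nanmean(r)) if not np.isnan(r).all() else np.nan
    if n_undefined:
        logger.warning("%d undefined correlation pairs excluded", n_undefined)
    return SimilarityMatrix(
        values=values,
        window_edges_min=window_edges_min or list(range(w + 1)),
        n_undefined_pairs=n_undefined,
    )
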