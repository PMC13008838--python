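"""Maximal-run segmentation of per-frame label sequences.

A *segment* is one occurrence of a behavior: a maximal run of consecutive
frames carrying the same label.  Segments tile the recording without gaps or
overlap, and consecutive segments always carry different labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import LabelSequence


@dataclass
class SegmentList:
    """Ordered (start_frame, end_frame_exclusive, label) triples."""

    segments: list[tuple[int, int, str]]
    frames: int
    vocabulary: str

    def __post_init__(self) -> None:
        prev_end = 0
        prev_label = None
        for start, end, label in self.segments:
            if start != prev_end or end <= start:
                raise ValueError("segments must tile [0, frames) without gaps")
            if label == prev_label:
                raise ValueError("consecutive segments must carry different labels")
            prev_end, prev_label = end, label
        if prev_end != self.frames:
            raise ValueError("segments must cover all frames")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def labels(self) -> list[str]:
        return [label for _, _, label in self.segments]

    def durations(self) -> np.ndarray:
        return np.array([end - start for start, end, _ in self.segments], dtype=int)

    def to_label_sequence(self) -> LabelSequence:
        """Tile the segments back into a per-frame label sequence."""
        out = np.empty(self.frames, dtype=object)
        for start, end, label in self.segments:
            out[start:end] = label
        return LabelSequence(labels=out, vocabulary=self.vocabulary)


def segments_from_labels(labels: LabelSequence) -> SegmentList:
    """Split a per-frame sequence into maximal runs of identical labels."""
    arr = labels.labels
    n = len(arr)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    segs = [(int(s), int(e), str(arr[s])) for s, e in zip(starts, ends)]
    return SegmentList(segments=segs, frames=n, vocabulary=labels.vocabulary)
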