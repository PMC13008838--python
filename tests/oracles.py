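"""Independent brute-force oracles for the relabeling rules.

Everything here is written with plain Python loops and explicit index
arithmetic — no segment machinery, no numpy vectorization — so it can serve
as an independent reference for the pipeline implementation.
"""

from __future__ import annotations

import math
import statistics


def oracle_speed(positions_xy, fps: float, window: int = 5) -> list[float]:
    """Median-filtered instantaneous XY speed, edge-replicated window."""
    n = len(positions_xy)
    raw = [0.0] * n
    for t in range(1, n):
        dx = positions_xy[t][0] - positions_xy[t - 1][0]
        dy = positions_xy[t][1] - positions_xy[t - 1][1]
        raw[t] = math.hypot(dx, dy) * fps
    raw[0] = raw[1]
    half = window // 2
    out = []
    for t in range(n):
        vals = [raw[min(max(i, 0), n - 1)] for i in range(t - half, t + half + 1)]
        out.append(statistics.median(vals))
    return out


def _runs(labels) -> list[tuple[int, int, str]]:
    out = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append((start, t, labels[start]))
            start = t
    return out


def oracle_relabel(coords, raw_labels, raw_to_behavior, fps=30.0,
                   arena_radius=250.0,
                   jump_z=100.0, jump_min=2, pause_speed=15.0,
                   climb_frac=0.8, climb_z=40.0, rear_z=50.0, rear_min=15,
                   groom_min=300) -> list[str]:
    """Full merge + revision pipeline evaluated frame by frame.

    ``coords`` is a (frames, 16, 3) array-like indexed with the canonical
    keypoint order (nose=0, neck=3, front limbs=4/5, back=12).
    """
    n = len(coords)
    labels = [raw_to_behavior[t] for t in raw_labels]

    # jumping: runs of back z strictly above threshold
    back_z = [coords[t][12][2] for t in range(n)]
    t = 0
    while t < n:
        if back_z[t] > jump_z:
            s = t
            while t < n and back_z[t] > jump_z:
                t += 1
            if t - s >= jump_min:
                for i in range(s, t):
                    labels[i] = "Jumping"
        else:
            t += 1

    # vertical postures
    neck_z = [coords[t][3][2] for t in range(n)]
    front_r = [
        math.hypot(
            (coords[t][4][0] + coords[t][5][0]) / 2.0,
            (coords[t][4][1] + coords[t][5][1]) / 2.0,
        )
        for t in range(n)
    ]
    for s, e, label in _runs(labels):
        if label not in ("Rising", "Climbing_up"):
            continue
        med_r = statistics.median(front_r[s:e])
        med_bz = statistics.median(back_z[s:e])
        if med_r > climb_frac * arena_radius and med_bz > climb_z:
            for i in range(s, e):
                labels[i] = "Climbing_up"
            continue
        for i in range(s, e):
            labels[i] = "Rising"
        run = 0
        is_rear = False
        for i in range(s, e):
            run = run + 1 if neck_z[i] > rear_z else 0
            if run >= rear_min:
                is_rear = True
        if is_rear:
            for i in range(s, e):
                labels[i] = "Rearing"

    # grooming
    groom_src = {"Rearing", "Climbing_up", "Rising", "Right_turning", "Left_turning"}
    for s, e, label in _runs(labels):
        if label in groom_src and (e - s) > groom_min:
            for i in range(s, e):
                labels[i] = "Grooming"

    # pausing
    pause_src = {"Sniffing", "Stepping", "Grooming", "Right_turning",
                 "Left_turning", "Rising", "Trotting"}
    nose_speed = oracle_speed([coords[t][0][:2] for t in range(n)], fps)
    back_speed = oracle_speed([coords[t][12][:2] for t in range(n)], fps)
    for t in range(n):
        if (labels[t] in pause_src and nose_speed[t] < pause_speed
                and back_speed[t] < pause_speed):
            labels[t] = "Pausing"
    return labels


def oracle_extrema(series) -> tuple[list[int], list[int]]:
    """Strict local maxima and minima by exhaustive neighbour comparison."""
    peaks, valleys = [], []
    for i in range(1, len(series) - 1):
        if series[i] > series[i - 1] and series[i] > series[i + 1]:
            peaks.append(i)
        if series[i] < series[i - 1] and series[i] < series[i + 1]:
            valleys.append(i)
    return peaks, valleys
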