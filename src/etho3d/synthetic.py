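"""Synthetic two-group cohorts of labeled 3D keypoint trajectories.

The generator emulates 30-minute open-field sessions of a control and an
affected group.  Behavior is a semi-Markov chain over the 13-behavior
ethogram (next behavior from per-behavior transition weights, dwell times
geometric), realized as a 16-keypoint skeleton whose body centre follows a
bounded, steerable random walk inside the cylindrical arena.  Kinematic
semantics respect the revision-rule thresholds by construction (jumps lift
the back above the jump threshold, rearing raises the neck, climbing pushes
the body to the wall), so the relabeling pipeline recovers the programmed
labels from coordinates alone.

The affected profile programs the effect *directions* of an early
neurodegeneration phenotype: lower locomotion fraction, more pausing,
slower locomotion, longer stride, peripheral-zone preference, and lower
transition entropy (more stereotyped switching).  Only directions are
contractual; absolute sizes are documented defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .io_core import (
    ArenaGeometry,
    KeypointTrajectory,
    LabelSequence,
    RuleConfig,
    write_labels,
    write_trajectory,
)
from .segments import SegmentList
from .taxonomy import BehaviorTaxonomy, default_taxonomy
from .vocab import BEHAVIORS_13, LOCOMOTOR_BEHAVIORS

# ---------------------------------------------------------------------------
# profiles


def _control_dwell() -> dict[str, float]:
    # mean segment durations in frames at 30 fps
    return {
        "Running": 25, "Trotting": 30, "Walking": 35, "Stepping": 30,
        "Right_turning": 20, "Left_turning": 20, "Sniffing": 40,
        "Rising": 30, "Rearing": 45, "Climbing_up": 40, "Jumping": 8,
        "Grooming": 350, "Pausing": 60,
    }


def _control_preference() -> dict[str, float]:
    # relative attractiveness of each behavior as a transition target
    return {
        "Running": 1.2, "Trotting": 1.2, "Walking": 1.2, "Stepping": 1.0,
        "Right_turning": 1.0, "Left_turning": 1.0, "Sniffing": 1.3,
        "Rising": 0.8, "Rearing": 0.5, "Climbing_up": 0.5, "Jumping": 0.15,
        "Grooming": 0.25, "Pausing": 0.8,
    }


def _control_speed() -> dict[str, tuple[float, float]]:
    # body-centre speed (mean, sd) in mm/s per behavior
    return {
        "Running": (250, 25), "Trotting": (150, 15), "Walking": (80, 8),
        "Stepping": (40, 5), "Right_turning": (30, 5), "Left_turning": (30, 5),
        "Sniffing": (45, 6), "Rising": (30, 5), "Rearing": (20, 4),
        "Climbing_up": (30, 5), "Jumping": (60, 10), "Grooming": (28, 4),
        "Pausing": (3, 1),
    }


@dataclass
class GenotypeProfile:
    """Generative parameters of one group.

    Dwell means are frames; speeds mm/s; stride amplitude mm (peak limb
    extension, so the peak-to-valley stride reads roughly twice this before
    smoothing attenuation); preferred radius mm steers the walk toward a
    home ring inside the 250 mm arena.
    """

    name: str = "control"
    behavior_dwell_mean_frames: dict[str, float] = field(default_factory=_control_dwell)
    behavior_preference: dict[str, float] = field(default_factory=_control_preference)
    speed_mm_s: dict[str, tuple[float, float]] = field(default_factory=_control_speed)
    stride_amplitude_mm: float = 5.0
    stride_rate_hz: float = 3.5
    preferred_radius_mm: float = 120.0
    steer_gain: float = 0.12
    body_length_mm: float = 70.0
    body_scale: dict[str, float] = field(
        default_factory=lambda: {"Grooming": 0.80, "Pausing": 0.75}
    )
    noise_sd_mm: float = 0.3
    animal_cv: float = 0.08  # between-animal lognormal variation of parameters
    changepoint_min: float | None = None
    changepoint_pause_factor: float = 1.0

    # behavior-specific skeleton heights (mm), chosen to respect the
    # revision-rule thresholds with margin
    back_z: dict[str, float] = field(
        default_factory=lambda: {
            "default": 25.0, "Rearing": 35.0, "Climbing_up": 55.0, "Jumping": 120.0,
        }
    )
    neck_z: dict[str, float] = field(
        default_factory=lambda: {
            "default": 30.0, "Rising": 45.0, "Rearing": 65.0, "Climbing_up": 60.0,
        }
    )

    def transition_weights(self) -> np.ndarray:
        """13 x 13 non-negative weights with zero diagonal, rows from the
        per-behavior target preferences."""
        u = np.array([self.behavior_preference[b] for b in BEHAVIORS_13])
        w = np.tile(u, (len(BEHAVIORS_13), 1))
        np.fill_diagonal(w, 0.0)
        return w


def control_profile() -> GenotypeProfile:
    return GenotypeProfile(name="control")


def affected_profile() -> GenotypeProfile:
    """Affected-group profile: programmed effect directions.

    Locomotor speeds scaled by 0.72 (bradykinesia), transition preference
    shifted from locomotion toward pausing (fraction/frequency/entropy),
    longer and slower stride, preferred radius moved to the peripheral
    zone, and a mid-session changepoint that further boosts pausing.
    """
    p = GenotypeProfile(name="affected")
    pref = dict(p.behavior_preference)
    pref.update(
        Running=0.45, Trotting=0.45, Walking=0.6, Stepping=0.8,
        Sniffing=0.9, Pausing=3.0,
    )
    dwell = dict(p.behavior_dwell_mean_frames)
    dwell.update(Pausing=150, Running=20, Trotting=24, Walking=28)
    speed = dict(p.speed_mm_s)
    for b in LOCOMOTOR_BEHAVIORS:
        m, s = speed[b]
        speed[b] = (0.72 * m, 0.72 * s)
    return replace(
        p,
        behavior_preference=pref,
        behavior_dwell_mean_frames=dwell,
        speed_mm_s=speed,
        stride_amplitude_mm=8.0,
        stride_rate_hz=2.5,
        preferred_radius_mm=225.0,
        changepoint_min=12.0,
        changepoint_pause_factor=3.0,
    )


@dataclass
class CohortManifest:
    """Everything needed to regenerate a cohort byte-for-byte."""

    n_per_group: int = 19
    seed: int = 0
    control: GenotypeProfile = field(default_factory=control_profile)
    affected: GenotypeProfile = field(default_factory=affected_profile)
    session_min: float = 30.0
    fps: float = 30.0
    raw_label_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.raw_label_map:
            self.raw_label_map = _invert_taxonomy(default_taxonomy())
        used = [rid for ids in self.raw_label_map.values() for rid in ids]
        if len(used) != len(set(used)):
            raise ValueError("raw ids may be used by at most one behavior")
        if set(self.raw_label_map) != set(BEHAVIORS_13):
            raise ValueError("raw_label_map must cover all 13 behaviors")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(manifest_to_dict(self), sort_keys=True))


def _invert_taxonomy(tax: BehaviorTaxonomy) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {b: [] for b in BEHAVIORS_13}
    for raw, behavior in sorted(tax.raw_to_behavior.items()):
        out[behavior].append(raw)
    return out


def effect_manifest(seed: int = 0, n_per_group: int = 19,
                    session_min: float = 30.0) -> CohortManifest:
    """Default cohort: two groups of 19, 30-minute sessions, programmed
    affected-group effect directions."""
    return CohortManifest(n_per_group=n_per_group, seed=seed,
                          session_min=session_min)


def null_manifest(seed: int = 0, n_per_group: int = 19,
                  session_min: float = 30.0) -> CohortManifest:
    """Null cohort: both groups generated from the control profile."""
    return CohortManifest(
        n_per_group=n_per_group, seed=seed,
        control=control_profile(),
        affected=replace(control_profile(), name="affected"),
        session_min=session_min,
    )


def manifest_to_dict(m: CohortManifest) -> dict:
    from dataclasses import asdict

    d = asdict(m)
    for key in ("control", "affected"):
        prof = d[key]
        prof["speed_mm_s"] = {k: list(v) for k, v in prof["speed_mm_s"].items()}
    return d


def manifest_from_dict(d: dict) -> CohortManifest:
    d = dict(d)
    for key in ("control", "affected"):
        prof = dict(d[key])
        prof["speed_mm_s"] = {k: tuple(v) for k, v in prof["speed_mm_s"].items()}
        d[key] = GenotypeProfile(**prof)
    return CohortManifest(**d)


def load_manifest(path: str | Path) -> CohortManifest:
    return manifest_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# behavior sequence


def generate_behavior_sequence(
    profile: GenotypeProfile,
    session_min: float,
    fps: float,
    seed: int | np.random.SeedSequence,
) -> SegmentList:
    """Semi-Markov behavior sequence filling the session exactly.

    The next behavior is drawn from the profile's transition weights
    (renormalized without the current behavior); dwell times are geometric
    with the behavior's mean.  After an optional changepoint minute the
    pausing preference and dwell are multiplied by
    ``changepoint_pause_factor`` while the locomotor preferences are divided
    by it, emulating within-session motor fatigue: the behavior distribution
    drifts toward rest and away from locomotion.
    """
    rng = np.random.default_rng(seed)
    total = int(round(session_min * 60 * fps))
    weights = profile.transition_weights()
    pause_idx = BEHAVIORS_13.index("Pausing")
    loco_idx = [BEHAVIORS_13.index(b) for b in LOCOMOTOR_BEHAVIORS]
    cp_frame = (
        int(profile.changepoint_min * 60 * fps)
        if profile.changepoint_min is not None
        else None
    )

    dwell_means = np.array(
        [profile.behavior_dwell_mean_frames[b] for b in BEHAVIORS_13]
    )
    start_w = weights.sum(axis=0)
    state = int(rng.choice(len(BEHAVIORS_13), p=start_w / start_w.sum()))
    segs: list[tuple[int, int, str]] = []
    t = 0
    while t < total:
        boosted = cp_frame is not None and t >= cp_frame
        mean = dwell_means[state]
        if boosted and state == pause_idx:
            mean *= profile.changepoint_pause_factor
        dwell = int(rng.geometric(1.0 / max(mean, 1.0)))
        end = min(t + dwell, total)
        segs.append((t, end, BEHAVIORS_13[state]))
        t = end
        if t >= total:
            break
        row = weights[state].copy()
        if boosted:
            row[pause_idx] *= profile.changepoint_pause_factor
            row[loco_idx] /= profile.changepoint_pause_factor
        if row.sum() <= 0:
            raise ValueError(
                f"no transition weight out of {BEHAVIORS_13[state]}"
            )
        state = int(rng.choice(len(BEHAVIORS_13), p=row / row.sum()))
    return SegmentList(segments=segs, frames=total, vocabulary="behavior13")


# ---------------------------------------------------------------------------
# keypoint realization


def realize_keypoints(
    segments: SegmentList,
    profile: GenotypeProfile,
    arena: ArenaGeometry | None = None,
    rules: RuleConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    fps: float = 30.0,
    raw_label_map: dict[str, list[str]] | None = None,
) -> tuple[KeypointTrajectory, LabelSequence]:
    """Render a behavior sequence as a 16-keypoint trajectory plus raw labels.

    The body centre performs a heading random walk at each behavior's speed,
    steered toward the profile's preferred radius and reflected at the wall;
    climbing segments dash to the wall so the front limbs pass the climbing
    radius; vertical behaviors set the back/neck heights demanded by the
    revision rules; the left fore/hind limbs oscillate at the stride rate
    during locomotion.  Raw labels are emitted per segment by deterministic
    round-robin over each behavior's mapped raw ids, so the whole raw
    vocabulary is exercised.
    """
    arena = arena or ArenaGeometry()
    rules = rules or RuleConfig()
    raw_label_map = raw_label_map or _invert_taxonomy(default_taxonomy())
    rng = np.random.default_rng(seed)
    n = segments.frames
    margin = 20.0
    r_max = arena.radius - margin
    if profile.body_length_mm >= arena.radius:
        raise ValueError("arena too small for body length")

    # --- per-frame behavior codes and per-segment speed draws
    behavior = np.empty(n, dtype=object)
    speed = np.empty(n)
    climbing = np.zeros(n, dtype=bool)
    raw_labels = np.empty(n, dtype=object)
    rr_counter: dict[str, int] = {b: 0 for b in BEHAVIORS_13}
    for start, end, label in segments:
        behavior[start:end] = label
        m, s = profile.speed_mm_s[label]
        speed[start:end] = max(0.0, rng.normal(m, s))
        if label == "Climbing_up":
            climbing[start:end] = True
        ids = raw_label_map[label]
        raw_labels[start:end] = ids[rr_counter[label] % len(ids)]
        rr_counter[label] += 1

    step = speed / fps
    dtheta = rng.normal(0.0, 0.08, size=n)
    is_right = behavior == "Right_turning"
    is_left = behavior == "Left_turning"
    dtheta[is_right] -= 0.12
    dtheta[is_left] += 0.12

    # --- body-centre walk (scalar loop; steering and reflection are stateful)
    x = np.empty(n)
    y = np.empty(n)
    theta = float(rng.uniform(0, 2 * math.pi))
    r0 = float(rng.uniform(0.3, 0.8) * r_max)
    phi0 = float(rng.uniform(0, 2 * math.pi))
    cx, cy = r0 * math.cos(phi0), r0 * math.sin(phi0)
    r_pref = profile.preferred_radius_mm
    gain = profile.steer_gain
    dash_step = 300.0 / fps
    for t in range(n):
        r = math.hypot(cx, cy)
        if climbing[t]:
            # dash radially to the wall, then hold position there
            if r < r_max - 5.0:
                phi = math.atan2(cy, cx) if r > 1e-9 else 0.0
                theta = phi
                cx += min(dash_step, r_max - r) * math.cos(phi)
                cy += min(dash_step, r_max - r) * math.sin(phi)
        else:
            phi = math.atan2(cy, cx) if r > 1e-9 else 0.0
            target = phi if r < r_pref else phi + math.pi
            theta += dtheta[t] + gain * math.sin(target - theta)
            cx += step[t] * math.cos(theta)
            cy += step[t] * math.sin(theta)
            r = math.hypot(cx, cy)
            if r > r_max:  # reflect inward at the wall
                cx *= r_max / r
                cy *= r_max / r
                theta = math.atan2(cy, cx) + math.pi
        x[t] = cx
        y[t] = cy

    # --- heading unit vectors (recomputed from the walked path for realism)
    dx = np.diff(x, prepend=x[0])
    dy = np.diff(y, prepend=y[0])
    head = np.arctan2(dy, dx)
    still = np.hypot(dx, dy) < 1e-6
    # carry the last moving heading through still frames
    idx = np.where(~still, np.arange(n), 0)
    np.maximum.accumulate(idx, out=idx)
    head = head[idx]
    ux, uy = np.cos(head), np.sin(head)
    vx, vy = -uy, ux

    scale = np.ones(n)
    for b, s in profile.body_scale.items():
        scale[behavior == b] = s
    L = profile.body_length_mm * scale

    back_z = np.full(n, profile.back_z["default"])
    neck_z = np.full(n, profile.neck_z["default"])
    for b, z in profile.back_z.items():
        if b != "default":
            back_z[behavior == b] = z
    for b, z in profile.neck_z.items():
        if b != "default":
            neck_z[behavior == b] = z
    nose_z = neck_z + 5.0

    # stride oscillation of the left limb pair during locomotion
    osc = profile.stride_amplitude_mm * np.sin(
        2 * math.pi * profile.stride_rate_hz * np.arange(n) / fps
    )
    osc[~np.isin(behavior.astype(str), LOCOMOTOR_BEHAVIORS)] = 0.0

    def place(fwd: np.ndarray, lat: float | np.ndarray, z: np.ndarray | float) -> np.ndarray:
        return np.column_stack(
            (x + fwd * ux + lat * vx, y + fwd * uy + lat * vy,
             np.broadcast_to(z, n))
        )

    coords = np.empty((n, 16, 3))
    coords[:, 0] = place(0.55 * L, 0.0, nose_z)                      # nose
    coords[:, 1] = place(0.45 * L, 8.0, nose_z - 3.0)                # left_ear
    coords[:, 2] = place(0.45 * L, -8.0, nose_z - 3.0)               # right_ear
    coords[:, 3] = place(0.35 * L, 0.0, neck_z)                      # neck
    coords[:, 4] = place(0.25 * L + 0.5 * osc, 12.0, 5.0)            # left_front_limb
    coords[:, 5] = place(0.25 * L, -12.0, 5.0)                       # right_front_limb
    coords[:, 6] = place(-0.15 * L - 0.5 * osc, 14.0, 5.0)           # left_hind_limb
    coords[:, 7] = place(-0.15 * L, -14.0, 5.0)                      # right_hind_limb
    coords[:, 8] = place(0.28 * L + 0.5 * osc, 13.0, 2.0)            # left_front_claw
    coords[:, 9] = place(0.28 * L, -13.0, 2.0)                       # right_front_claw
    coords[:, 10] = place(-0.18 * L - 0.5 * osc, 15.0, 2.0)          # left_hind_claw
    coords[:, 11] = place(-0.18 * L, -15.0, 2.0)                     # right_hind_claw
    coords[:, 12] = place(0.0, 0.0, back_z)                          # back
    coords[:, 13] = place(-0.35 * L, 0.0, back_z * 0.6)              # root_tail
    coords[:, 14] = place(-0.55 * L, 0.0, 8.0)                       # middle_tail
    coords[:, 15] = place(-0.75 * L, 0.0, 4.0)                       # tip_tail

    if profile.noise_sd_mm > 0:
        coords += rng.normal(0.0, profile.noise_sd_mm, size=coords.shape)
    coords[:, :, 2] = np.maximum(coords[:, :, 2], 0.0)

    traj = KeypointTrajectory(coords=coords, fps=fps)
    return traj, LabelSequence(labels=raw_labels, vocabulary="raw40")


# ---------------------------------------------------------------------------
# cohort assembly


def _perturb(profile: GenotypeProfile, rng: np.random.Generator) -> GenotypeProfile:
    """Between-animal variation: lognormal jitter on dwell, preference,
    speed and stride parameters with the profile's coefficient of variation."""
    cv = profile.animal_cv
    if cv <= 0:
        return profile

    def jit() -> float:
        return float(rng.lognormal(0.0, cv))

    return replace(
        profile,
        behavior_dwell_mean_frames={
            k: v * jit() for k, v in profile.behavior_dwell_mean_frames.items()
        },
        behavior_preference={
            k: v * jit() for k, v in profile.behavior_preference.items()
        },
        speed_mm_s={k: (m * jit(), s) for k, (m, s) in profile.speed_mm_s.items()},
        stride_amplitude_mm=profile.stride_amplitude_mm * jit(),
        preferred_radius_mm=float(
            np.clip(profile.preferred_radius_mm + rng.normal(0, 10), 30, 235)
        ),
    )


@dataclass
class Recording:
    animal_id: str
    group: str
    trajectory: KeypointTrajectory
    raw_labels: LabelSequence
    programmed_segments: SegmentList


def iter_cohort(manifest: CohortManifest, arena: ArenaGeometry | None = None,
                rules: RuleConfig | None = None):
    """Yield one Recording per animal, fully determined by the manifest seed.

    Per-animal randomness derives from ``SeedSequence(manifest.seed)`` spawned
    once per animal in a fixed order (all controls, then all affected), so
    any single animal can be regenerated independently.
    """
    root = np.random.SeedSequence(manifest.seed)
    children = root.spawn(2 * manifest.n_per_group)
    i = 0
    for group, profile in (("control", manifest.control),
                           ("affected", manifest.affected)):
        for k in range(manifest.n_per_group):
            ss = children[i]
            i += 1
            sub = ss.spawn(3)
            animal_profile = _perturb(profile, np.random.default_rng(sub[0]))
            segs = generate_behavior_sequence(
                animal_profile, manifest.session_min, manifest.fps, sub[1]
            )
            traj, raw = realize_keypoints(
                segs, animal_profile, arena, rules, seed=sub[2], fps=manifest.fps,
                raw_label_map=manifest.raw_label_map,
            )
            yield Recording(
                animal_id=f"{group}_{k:02d}", group=group,
                trajectory=traj, raw_labels=raw, programmed_segments=segs,
            )


def generate_cohort(manifest: CohortManifest, out_dir: str | Path) -> list[dict]:
    """Write the cohort to disk: per-animal trajectory .h5 and raw-label .csv
    plus a manifest copy; returns the file index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.save(out / "manifest.yaml")
    index = []
    for rec in iter_cohort(manifest):
        traj_path = out / f"{rec.animal_id}_traj.h5"
        label_path = out / f"{rec.animal_id}_raw_labels.csv"
        write_trajectory(rec.trajectory, traj_path)
        write_labels(rec.raw_labels, label_path)
        index.append(
            {"animal_id": rec.animal_id, "group": rec.group,
             "trajectory": traj_path.name, "raw_labels": label_path.name}
        )
    return index
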