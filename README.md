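# etho3d

Fine-grained behavioral phenotyping of freely moving mice from 3D pose
data. The package takes per-frame 3D keypoint trajectories (16 body
keypoints × x, y, z at 30 fps, recorded in a cylindrical open field of
radius 25 cm) together with the raw per-frame labels of an upstream
unsupervised behavior classifier (40 phenotype categories), and turns them
into:

- a revised 13-behavior ethogram (Running, Trotting, Walking, Stepping,
  Right/Left turning, Sniffing, Rising, Rearing, Climbing up, Jumping,
  Grooming, Pausing), grouped into 4 functional clusters (Locomotion,
  Exploration, Maintenance, Nap);
- kinematic parameters: median-filtered movement speed, stride
  length/frequency from peak–valley detection on the left fore–hind limb
  distance, upper/lower posture angles, body stretch ratio, path length;
- spatial and temporal metrics: behavior fractions and frequencies, radial
  zone occupancy (center / middle / peripheral), time-window dynamics, and
  cross-window behavioral similarity matrices;
- first-order Markov transition models with hub-node and entropy analysis;
- group statistics (normality-gated t-test / Mann–Whitney U with
  Bonferroni–Dunn correction) and an LDA genotype classifier evaluated by
  leave-one-out cross-validation (macro-F1, confusion matrix, ROC-AUC).

It is aimed at behavioral neuroscientists quantifying subtle, premanifest
motor phenotypes in rodent disease models, where coarse assays (rotarod,
balance beam) are insensitive.

Because such recordings are rarely public, the package ships a synthetic
cohort generator (`etho3d.synthetic`) that produces two-group cohorts of
labeled 3D trajectories with programmable effect *directions* — lower
locomotion, more pausing, slower gait with longer stride, peripheral-zone
preference, lower transition entropy — so every pipeline stage is testable
end to end without any download.

## Core definitions

Behavior segments are maximal runs of identical per-frame labels; one
segment is one occurrence. Raw labels are merged onto the 13 behaviors and
then revised by kinematic rules (strict inequalities, units mm / mm·s⁻¹ /
frames):

| Rule | Condition |
|---|---|
| Jumping | back height > 100 for ≥ 2 consecutive frames |
| Climbing up vs Rising | front-paw radius > 0.8 × arena radius and back height > 40 → Climbing up, else Rising |
| Rearing | among Rising: neck height > 50 for ≥ 15 consecutive frames |
| Grooming | Rearing/Climbing/Rising/Turning segments lasting > 300 frames (10 s) |
| Pausing | nose **and** back speed < 15 mm/s inside slow behaviors |

The transition probability between behaviors i and j is
P(j|i) = N(i→j) / Σₖ N(i→k), counted over consecutive segments. Transition
entropy is the occupancy-weighted entropy rate
H = −Σᵢ wᵢ Σⱼ P(j|i) log₂ P(j|i), with wᵢ the share of transitions leaving
state i; lower H means more stereotyped switching.

## Worked example

```python
from etho3d import (
    effect_manifest, iter_cohort, analyze_cohort,
    headline_comparisons, classify_presets,
)

manifest = effect_manifest(seed=1, n_per_group=6, session_min=10)
cohort = analyze_cohort(iter_cohort(manifest))
print(cohort.scalars.groupby(cohort.groups).mean().round(2).T)
for name, c in headline_comparisons(cohort).items():
    print(f"{name:26s} {c.test_used:15s} p_adj={c.p_adjusted:.2e}")
reports = classify_presets(cohort.counts13, cohort.fraction_frames13,
                           cohort.groups)
print("fractions4 AUC:", reports["fractions4"].auc)
```

prints

```
                         affected   control
locomotion_fraction          0.15      0.42
pausing_fraction             0.53      0.11
locomotor_speed_mm_s        76.06    114.64
stride_length_mm            11.84      5.18
stride_frequency_hz          1.75      2.50
peripheral_dwell_min         9.87      2.65
transition_entropy_bits      2.76      3.15
path_length_mm           16799.51  35330.72
n_segments                 259.00    462.83
locomotion_fraction        t_test          p_adj=1.14e-05
pausing_fraction           mann_whitney_u  p_adj=1.30e-02
locomotor_speed_mm_s       t_test          p_adj=2.13e-05
stride_length_mm           t_test          p_adj=4.99e-11
peripheral_dwell_min       t_test          p_adj=3.29e-07
transition_entropy_bits    mann_whitney_u  p_adj=1.30e-02
fractions4 AUC: 1.0
```

Each row of the first table is a group mean over animals: the affected
group spends less of the session in Locomotion-cluster behaviors (0.15 vs
0.42 of frames), pauses far more, moves more slowly during locomotor bouts
(76 vs 115 mm/s), takes longer strides at lower cadence, dwells almost
entirely in the peripheral zone, and switches between behaviors more
stereotypically (lower entropy). All six contrasts survive the six-fold
Bonferroni–Dunn correction, and the four-behavior fraction classifier
(Running, Trotting, Walking, Pausing) separates the groups perfectly at
this programmed effect size.

The same pipeline is available from the shell:

```bash
etho3d simulate --preset effect --seed 1 --n-per-group 6 \
    --session-min 10 --out cohort/
etho3d validate cohort/control_00_traj.h5 cohort/control_00_raw_labels.csv
etho3d relabel --traj cohort/control_00_traj.h5 \
    --raw-labels cohort/control_00_raw_labels.csv --out behavior.csv
etho3d kinematics --traj cohort/control_00_traj.h5 --labels behavior.csv
etho3d analyze --cohort cohort/ --out-prefix report
```

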