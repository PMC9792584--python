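# sesc — subject-specific whole-body center-of-mass estimation

Estimating where a person's center of mass (CoM) sits is central to balance
assessment, yet the standard *segmental analysis* approach — locate each body
segment, weight it by a population-table mass fraction, sum — degrades badly
on bodies whose mass distribution the table does not describe (obesity being
the clinically important case). This package implements the **statically
equivalent serial chain (SESC)** alternative: the CoM of a branched
rigid-body model is rewritten as the end-effector of a virtual *serial*
chain whose constant link vectors absorb all segment masses and geometry,

```
CoM = d₁ + R₁v₁ + R₁R₂v₂ + … = [I  R̂] [d₁; V]
```

where `d₁, R₁` are the root (pelvis) pose, `R̂` stacks the cumulative joint
rotations along each root-to-segment path, and `V = (v₁ … vₙ)` is a
3n-vector of **subject-specific** parameters. Because the model is linear in
`V`, a one-off identification session — a set of static postures with
force-platform center-of-pressure (CoP) readings, which in static
equilibrium are the horizontal projection of the CoM — determines `V` by
Moore–Penrose pseudoinverse least squares. Each posture contributes two
horizontal equations, so at least ⌈3n/2⌉ postures are needed (14 for the
default nine-body humanoid). After identification, the full 3-D CoM follows
from joint angles alone: no anthropometric table, no force platform.

The package provides, for researchers in biomechanics and movement science:

- `sesc.kinematics` — branched rigid-body trees (spherical and hinge
  joints), rotation/transform composition, posture CSV and tree JSON I/O;
- `sesc.core` — the weighted-sum CoM oracle, the closed-form serial-chain
  links `vⱼ = (mⱼCⱼ + Σ_c M_subtree(c)·d_c)/M`, regressor assembly, and the
  SESC forward model;
- `sesc.identification` — stacked least squares with rank/conditioning
  diagnostics, posture-count rule, and seeded 75/25
  identification/evaluation splits;
- `sesc.detection` — static-posture selection from raw 60 Hz streams
  (1 s windows, angle SD < 1.5°, CoP SD < 6 mm);
- `sesc.segmental` — the table-driven comparator (generic, pluggable
  anthropometric tables);
- `sesc.evaluation` — RMSE, group summaries (mean/SD/CV), correlation,
  Bland–Altman agreement with fixed and proportional bias, normality-gated
  group tests;
- `sesc.synthetic` — a nine-body synthetic humanoid generator with `fit`
  and `obese` (trunk-dominant) mass-distribution presets, noisy trials and
  plateau/transition time series, so the whole pipeline runs without any
  recorded data.

## Worked example

```python
import numpy as np
from sesc import (make_subject, sample_static_postures, simulate_trial,
                  NoiseModel, split_postures, identify_from_observations,
                  build_regressor_row, estimate_com, rmse_per_axis)

subject = make_subject("obese", seed=7)          # ground truth fully known
postures = sample_static_postures(subject, 120, seed=8)
obs, truth = simulate_trial(subject, postures, NoiseModel(2.0, 0.5, seed=9))

ident, evalu = split_postures(obs, 0.75, seed=10, min_identify=14)
result = identify_from_observations(subject.tree, ident)

est = np.array([estimate_com(build_regressor_row(subject.tree, o.posture),
                             o.posture.root_position, result.V)[:2]
                for o in evalu])
ref = np.array([o.cop for o in evalu])
print(rmse_per_axis(est * 1000, ref * 1000))
```

prints (rank and conditioning of the identification stack are reported on
`result`):

```
RmseResult(rmse_ap=3.02420258412894, rmse_ml=3.0694048544583805, n=30)
```

— held-out horizontal CoM error of ~3 mm per axis under 2 mm CoP and
0.5° joint-angle sensor noise, for an obese-preset subject no population
table describes. Running the segmental comparator with a lean-population
table on the same postures gives roughly triple the error and, unlike the
identified chain, a systematic anteroposterior bias.

A console script mirrors the workflow (`sesc simulate`, `sesc detect`,
`sesc identify`, `sesc segmental`, `sesc evaluate`); see `sesc --help`.

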