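# Methods

## Model

The body is a tree of `n` rigid segments. Segment 1 (the pelvis) is the
root and carries a free pose `(R₁, d₁)`; every other segment is attached to
its parent by a spherical (3-DoF) or hinge (1-DoF) joint, with a constant
origin offset `dᵢ` expressed in the parent frame and a constant local CoM
`Cᵢ`. The default humanoid has nine segments: pelvis; two legs as
three-link chains (spherical hip, hinge knee, hinge ankle, hinge axes along
the mediolateral direction); and two single-segment branches off the pelvis
for trunk+head and for the combined upper limbs. The tree is fully
configurable via JSON — the published nine-segment/nineteen-DoF figure the
default emulates does not pin down a unique joint-to-segment correspondence,
so the default follows the product structure of the expanded weighted-sum
equation literally (two 3-link chains plus two direct branches), which gives
spherical joints at the two root branches.

Global axes are fixed as x = anteroposterior (anterior positive),
y = mediolateral, z = vertical up. Internal units are meters; reported
errors are millimeters. Rotations are stored as matrices; quaternion and
intrinsic Z-X-Y Euler constructors are provided at the I/O boundary.

**Weighted sum (oracle).** `CoM = Σ mᵢ pᵢ / M` with `pᵢ` the globally
transformed segment CoM obtained by composing `[Rⱼ, dⱼ]` transforms along
the root-to-segment path. This is the ground-truth forward model.

**Serial-chain form.** Collecting, for each segment `j`, the coefficient of
its cumulative path rotation `R_path(j)` in the expanded weighted sum gives

```
CoM = d₁ + Σⱼ R_path(j) · vⱼ,    vⱼ = ( mⱼCⱼ + Σ_{c ∈ children(j)} M_subtree(c) · d_c ) / M
```

with `M_subtree(c)` the mass of the subtree rooted at `c`. This closed form
is not given in the source literature (which only states that the links
collect the constant parameters); it is derived here and verified against
the brute-force oracle at 1e-12 m over random subjects and postures, both in
the unit tests and in the acceptance script. Stacked as
`CoM = [I | R̂][d₁; V]`, the model is linear in the 3n-vector `V`.

## Identification

In static equilibrium the force-platform CoP is the horizontal projection
of the CoM, so each static posture yields the two horizontal rows of the
model: `R̂'ₖ V = CoPₖ − d₁ₖ` (AP and ML components). The printed form of the
stacked system repeats the x-subscript on both rows of each pair; the
left-hand side forces alternating x/y rows, which is what is implemented.
With 2 equations per posture and 3n unknowns, at least `⌈3n/2⌉` postures
are required (14 for n = 9). The solve is an SVD pseudoinverse with a
relative singular-value cutoff of 1e-10; rank, condition number and residual
RMS are reported.

**Structural rank deficiency.** Under the generator's study conditions the
27-column stack has rank 22–23, for two faithful physical reasons: (i) a
hinge rotation fixes its own axis, so the mediolateral components of the
knee- and ankle-link vectors are identifiable only through their sums along
each leg chain; (ii) while the root never tilts, the vertical component of
the root link never enters the horizontal rows. The solver warns and returns
the minimum-norm solution. Held-out *prediction* is unaffected, because
evaluation postures share the same structural null space — noiseless
held-out error is at numerical precision (~1e-13 mm).

Postures are split 75%/25% into identification and evaluation sets,
randomly under a recorded seed (sequential mode by flag), identify-set size
rounded half away from zero. RMSE is computed against the CoP readings,
which is how the reference protocol scores estimates; the error against the
noise-free CoM is retained as a diagnostic.

## Static-posture detection

A window of 1 s at 60 Hz is static when every joint-angle channel has
SD < 1.5° and both CoP axes have SD < 6 mm. Angle SDs use differences
wrapped to (−180°, 180°] so a steady channel at the Euler seam is not
rejected; each channel must pass individually (the strictest reading — a
moving limb cannot hide in an aggregate). The CoP criterion is per axis by
default, with a resultant-displacement mode behind a flag, since the source
protocol does not disambiguate. Windows tile the stream without overlap
(a sliding, stride-1 mode with greedy non-overlap resolution is available);
consecutive static windows merge into maximal regions, one representative
posture (per-channel mean) per region.

## Segmental comparator

The comparator instantiates segment parameters from a population table:
`mᵢ = fractionᵢ·M`, `Cᵢ = com_ratioᵢ·lengthᵢ` along the segment's
longitudinal axis, and the CoM is the weighted sum. Because a branched root
attaches legs below and trunk above, a single "parent longitudinal axis"
rule cannot place all children; the table therefore carries an explicit
per-segment attachment direction and ratio in the parent frame, which
reduces to the axis rule for serial chains. The proprietary 23-segment
regression model used by commercial motion-capture software is out of
scope; the comparator is the generic table-driven estimator over the same
nine-segment tree. A table inverted from a subject's true parameters
reproduces the oracle exactly (self-consistency test); a mismatched table
produces the analytic error `Σ Δfᵢ·pᵢ` (sum-zero fraction perturbation),
which the tests verify term by term and for linearity.

## Agreement statistics

Differences are `estimate − reference` throughout. Group summaries use the
sample (n−1) SD — this choice reproduces the published summary rows from
their printed per-subject values, whereas the population formula does not —
and CV = 100·SD/mean. Bland–Altman: fixed bias = mean difference,
LoA = bias ± 1.96·SD, bias CI = ±1.96·SD/√n (normal approximation;
t-based by flag). Proportional bias regresses the difference on the
pairwise mean; with repeated measures per subject the default is OLS with
cluster-robust (by subject) standard errors, with plain-OLS and
per-subject-mean modes as alternatives, since the exact longitudinal
procedure in the source literature is not specified. Group comparisons gate
on Shapiro–Wilk at α = 0.05: both groups normal → Student's/paired t,
otherwise Mann–Whitney/Wilcoxon; the report records which branch fired.

The per-subject RMSE values of the two published cohorts (11 fit, 14 obese)
are bundled as `sesc/data/tables_1_2_rmse.csv`; their summary rows are
reproduced within ±0.02 (the inputs are themselves printed rounded to two
decimals).

## Synthetic data: what it emulates, and what it does not

The generator emulates an identification session: a subject with known
segment masses and geometry, ~120 uniformly sampled static postures, CoP =
horizontal true CoM + Gaussian noise, and small rotational noise on measured
joint orientations (tangent-space perturbation, so perturbed matrices remain
rotations; hinge joints are perturbed only about their axis).

Study conditions (defaults, chosen once):

- **Baseline anthropometry** — mass fractions (pelvis 0.142, thigh 0.100,
  shank 0.0465, foot 0.0145 per side, trunk+head 0.437, upper limbs 0.099)
  and segment geometry shaped like standard adult tables at 1.75 m stature,
  scaled by stature. These are generator configuration, not assertions about
  any real cohort.
- **Individual variation** — ±5% uniform jitter on fractions (renormalized)
  and segment dimensions; stature 1.60–1.90 m; total mass 55–80 kg (fit) or
  85–125 kg (obese).
- **Obese preset** — trunk-branch fractions (pelvis, trunk+head, upper
  limbs) ×1.4 before renormalization: a trunk-dominant redistribution large
  enough to be clearly detectable by the comparator study at the configured
  noise, and configurable.
- **Joint ranges** — spherical ±30° per Euler axis, knees 0–60° flexion
  (one-sided, as knees are), ankles ±20°; root upright at a fixed position.
  The one-sided knee range is what gives a mis-weighted table a *mean*
  (fixed) anteroposterior error rather than a sign-cancelling one.
- **Sensor noise** — CoP SD 2 mm, angle SD 0.5°: instrument-grade values;
  the source studies do not print their sensor noise, so all stochastic
  bounds are stated relative to these configured levels.
- **Time series** — 60 Hz; each posture held 2 s with sub-threshold jitter
  (0.2°, 1 mm), joined by 1 s transitions carrying a large sinusoidal
  excursion so no window straddling a transition passes. With hold and
  transition durations at integer multiples of the window, detected regions
  align exactly with plateaus and the detector recovers exactly one posture
  per observation.

Not emulated: physiologically validated obesity geometry, balance-constrained
posture sampling (static equilibrium is already encoded by projecting the
CoM), soft-tissue artifact, sensor-to-segment calibration error, and any
dynamic motion. Passing tests therefore demonstrate the estimator's
statistical behavior under the stated noise model, not its accuracy on real
recordings.

## Problem sizes used in tests and the acceptance script

Oracle equivalence uses 100 random nine-body instances; noiseless recovery
uses 40 identification + 20 held-out postures; the noisy band uses 50
replicates of 100 postures at 2 mm CoP noise; the comparator study uses 50
per-run obese trials (120 postures each), a pooled 14-subject cohort for
Table-style fixed biases, and 25 + 25 fit/obese trials for the location
test; the detector round trip uses 1, 10 and 50 postures. These sizes give
stable statistics at desk scale and are the package's chosen defaults.

## Known limitations

- Only the horizontal CoM components are identifiable from CoP; the
  vertical estimate inherits whatever the minimum-norm solution assigns to
  structurally unobservable directions and should not be used unless the
  identification postures tilt the root.
- The identified vector is valid for one subject and one segment
  definition; re-identification is needed after any model change.
- The comparator's accuracy statements concern the generic table-driven
  method, not any specific commercial implementation.
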