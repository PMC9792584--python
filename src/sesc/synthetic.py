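"""Synthetic humanoid subjects, static-posture trials and sensor streams.

Emulates the data a motion-capture suit plus force platform would produce
during a static-posture identification session: subjects with known segment
masses and geometry (so every estimator can be scored against exact ground
truth), uniformly sampled physiological joint configurations, CoP readings
equal to the horizontal projection of the true CoM plus Gaussian sensor
noise, small rotational noise on the measured joint orientations, and 60 Hz
plateau/transition time series for exercising the static-posture detector.

Two mass-distribution presets are provided: ``fit`` draws mild individual
variation around a standard anthropometric baseline, while ``obese``
additionally inflates the trunk-branch mass fractions (pelvis, trunk+head,
upper limbs) by a configurable factor before renormalizing — a trunk-dominant
redistribution that population tables calibrated on lean cohorts do not
capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import SegmentParameters, brute_force_com
from .detection import DetectedPosture, StaticPostureCriteria
from .identification import StaticObservation
from .kinematics import (
    KinematicTree,
    PostureFrame,
    default_humanoid_tree,
    euler_zxy_deg_from_rotation,
    hinge_rotation,
    rotation_from_euler_zxy_deg,
)

__all__ = [
    "SyntheticSubject",
    "NoiseModel",
    "JointRanges",
    "TimeSeriesTrial",
    "make_subject",
    "sample_static_postures",
    "simulate_trial",
    "expand_to_time_series",
    "observation_from_detection",
    "BASELINE_MASS_FRACTIONS",
    "BASELINE_GEOMETRY",
]

# Baseline mass fractions for the 9-body model, shaped like standard
# anthropometry (pelvis, thighs, shanks, feet, trunk+head, both upper limbs).
BASELINE_MASS_FRACTIONS: dict[int, float] = {
    1: 0.142,
    2: 0.100, 3: 0.0465, 4: 0.0145,
    5: 0.100, 6: 0.0465, 7: 0.0145,
    8: 0.437,
    9: 0.099,
}

# Baseline geometry at 1.75 m stature: per-body origin offset in the parent
# frame (d_i, meters) and local CoM (C_i, meters).  x = AP, y = ML, z = up.
BASELINE_GEOMETRY: dict[int, dict[str, tuple[float, float, float]]] = {
    1: {"d": (0.0, 0.0, 0.0), "com": (0.0, 0.0, 0.05)},
    2: {"d": (0.0, -0.09, -0.05), "com": (0.0, 0.0, -0.18)},
    3: {"d": (0.0, 0.0, -0.41), "com": (0.0, 0.0, -0.17)},
    4: {"d": (0.0, 0.0, -0.40), "com": (0.07, 0.0, -0.03)},
    5: {"d": (0.0, 0.09, -0.05), "com": (0.0, 0.0, -0.18)},
    6: {"d": (0.0, 0.0, -0.41), "com": (0.0, 0.0, -0.17)},
    7: {"d": (0.0, 0.0, -0.40), "com": (0.07, 0.0, -0.03)},
    8: {"d": (0.0, 0.0, 0.10), "com": (0.0, 0.0, 0.32)},
    9: {"d": (0.0, 0.0, 0.45), "com": (0.0, 0.0, -0.25)},
}

TRUNK_BRANCH_BODIES = (1, 8, 9)
DEFAULT_ROOT_POSITION = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class SyntheticSubject:
    tree: KinematicTree
    params: SegmentParameters
    preset: str
    stature: float  # m
    total_mass: float  # kg
    seed: int


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: CoP position SD (mm) and per-joint angle SD (degrees)."""

    cop_sd_mm: float = 2.0
    angle_sd_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cop_sd_mm < 0 or self.angle_sd_deg < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class JointRanges:
    """Uniform sampling ranges (degrees): spherical per Euler axis, knees
    one-sided flexion, ankles symmetric."""

    spherical_deg: float = 30.0
    knee_flexion_deg: tuple[float, float] = (0.0, 60.0)
    ankle_deg: float = 20.0


def make_subject(
    preset: str,
    seed: int,
    obese_trunk_factor: float = 1.4,
    fraction_jitter: float = 0.05,
    length_jitter: float = 0.05,
) -> SyntheticSubject:
    """Draw one synthetic subject with fully recorded ground-truth parameters.

    ``fit`` subjects jitter the baseline mass fractions and geometry by the
    given relative amounts (then renormalize fractions to 1); ``obese``
    subjects additionally multiply the trunk-branch fractions by
    ``obese_trunk_factor`` before renormalizing, and draw heavier total
    masses.
    """
    if preset not in ("fit", "obese"):
        raise ValueError(f"unknown preset {preset!r} (expected 'fit' or 'obese')")
    rng = np.random.default_rng(seed)
    tree = default_humanoid_tree()

    fractions = {
        b: f * rng.uniform(1 - fraction_jitter, 1 + fraction_jitter)
        for b, f in BASELINE_MASS_FRACTIONS.items()
    }
    if preset == "obese":
        for b in TRUNK_BRANCH_BODIES:
            fractions[b] *= obese_trunk_factor
    total_fraction = sum(fractions.values())
    fractions = {b: f / total_fraction for b, f in fractions.items()}

    stature = rng.uniform(1.60, 1.90)
    scale = stature / 1.75
    if preset == "fit":
        total_mass = rng.uniform(55.0, 80.0)
    else:
        total_mass = rng.uniform(85.0, 125.0)

    mass = {b: fractions[b] * total_mass for b in fractions}
    local_com, displacement = {}, {}
    for b, geo in BASELINE_GEOMETRY.items():
        jitter = rng.uniform(1 - length_jitter, 1 + length_jitter)
        local_com[b] = np.asarray(geo["com"]) * scale * jitter
        displacement[b] = (
            np.asarray(geo["d"]) * scale
            * rng.uniform(1 - length_jitter, 1 + length_jitter)
        )
    params = SegmentParameters(mass, local_com, displacement)
    return SyntheticSubject(tree, params, preset, stature, total_mass, seed)


def _random_spherical(rng, half_range_deg: float) -> np.ndarray:
    z, x, y = rng.uniform(-half_range_deg, half_range_deg, size=3)
    return rotation_from_euler_zxy_deg(z, x, y)


def sample_static_postures(
    subject: SyntheticSubject,
    m: int,
    seed: int,
    ranges: JointRanges = JointRanges(),
    root_position: Sequence[float] = DEFAULT_ROOT_POSITION,
) -> list[PostureFrame]:
    """Uniformly sampled joint configurations with a fixed upright root."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    tree = subject.tree
    root = tree.root
    knees = {b for b in tree.joint_type
             if tree.joint_type[b] == "hinge" and tree.joint_type[tree.parent[b]] == "spherical"}
    postures = []
    for _ in range(m):
        rot: dict[int, np.ndarray] = {}
        for b in tree.body_order:
            if b == root:
                continue
            jt = tree.joint_type[b]
            if jt == "spherical":
                rot[b] = _random_spherical(rng, ranges.spherical_deg)
            else:  # hinge: knee (one-sided flexion) or ankle (symmetric)
                if b in knees:
                    lo, hi = ranges.knee_flexion_deg
                else:
                    lo, hi = -ranges.ankle_deg, ranges.ankle_deg
                angle = np.deg2rad(rng.uniform(lo, hi))
                rot[b] = hinge_rotation(tree.hinge_axis[b], angle)
        postures.append(
            PostureFrame(np.eye(3), np.asarray(root_position, dtype=float), rot)
        )
    return postures


def _perturb_posture(
    posture: PostureFrame, tree: KinematicTree, angle_sd_deg: float, rng
) -> PostureFrame:
    """Rotational measurement noise: tangent-space perturbation per joint.

    Spherical joints get a random 3-axis rotation-vector perturbation; hinge
    joints are perturbed only about their hinge axis so the perturbed posture
    remains kinematically admissible.
    """
    if angle_sd_deg == 0:
        return posture
    sd = np.deg2rad(angle_sd_deg)
    rot = {}
    for b, R in posture.joint_rotation.items():
        if tree.joint_type[b] == "hinge":
            delta = hinge_rotation(tree.hinge_axis[b], rng.normal(0.0, sd))
        else:
            delta = Rotation.from_rotvec(rng.normal(0.0, sd, size=3)).as_matrix()
        rot[b] = R @ delta
    root_delta = Rotation.from_rotvec(rng.normal(0.0, sd, size=3)).as_matrix()
    return PostureFrame(posture.root_rotation @ root_delta, posture.root_position, rot)


def simulate_trial(
    subject: SyntheticSubject,
    postures: Sequence[PostureFrame],
    noise: NoiseModel = NoiseModel(),
) -> tuple[list[StaticObservation], list[np.ndarray]]:
    """Turn true postures into noisy (posture, CoP) observations.

    The CoP is the horizontal (AP, ML) projection of the true CoM plus
    Gaussian noise; the observed postures carry rotational measurement noise.
    The exact CoM of every true posture is returned alongside for scoring.
    """
    rng = np.random.default_rng(noise.seed)
    observations, truth = [], []
    for p in postures:
        com = brute_force_com(subject.tree, subject.params, p)
        cop = com[:2] + rng.normal(0.0, noise.cop_sd_mm * 1e-3, size=2)
        observed = _perturb_posture(p, subject.tree, noise.angle_sd_deg, rng)
        observations.append(StaticObservation(observed, cop))
        truth.append(com)
    return observations, truth


# -- time-series expansion ----------------------------------------------------

@dataclass(frozen=True)
class TimeSeriesTrial:
    """Raw 60 Hz-style streams: joint-angle channels (deg) and CoP (mm)."""

    time_s: np.ndarray
    angles_deg: np.ndarray  # (T, n_channels)
    cop_mm: np.ndarray  # (T, 2)
    channel_names: tuple[str, ...]
    root_position: np.ndarray
    body_order: tuple[int, ...] = field(default_factory=tuple)


def _posture_channels(tree: KinematicTree, posture: PostureFrame) -> np.ndarray:
    vals = []
    for b in tree.body_order:
        vals.extend(euler_zxy_deg_from_rotation(posture.rotation_of(b, tree)))
    return np.asarray(vals)


def expand_to_time_series(
    tree: KinematicTree,
    observations: Sequence[StaticObservation],
    criteria: StaticPostureCriteria = StaticPostureCriteria(),
    hold_s: float = 2.0,
    transition_s: float = 1.0,
    seed: int = 0,
    angle_jitter_deg: float = 0.2,
    cop_jitter_mm: float = 1.0,
    transition_amp_deg: float = 25.0,
    transition_amp_mm: float = 30.0,
) -> TimeSeriesTrial:
    """Expand discrete observations into plateau/transition raw streams.

    Each observation becomes a plateau of ``hold_s`` with sub-threshold
    jitter; consecutive plateaus are joined by ``transition_s`` of
    interpolated motion carrying a large sinusoidal excursion, so that any
    analysis window touching a transition fails the stillness criteria.  With
    the defaults (hold and transition both integer multiples of the window)
    the detector recovers exactly one posture per observation.
    """
    if hold_s < criteria.window_s:
        raise ValueError("hold_s must be at least one detection window")
    if len(observations) == 0:
        raise ValueError("no observations to expand")
    rate = criteria.sample_rate_hz
    n_hold = int(round(hold_s * rate))
    n_trans = int(round(transition_s * rate))
    rng = np.random.default_rng(seed)

    channels = [_posture_channels(tree, o.posture) for o in observations]
    cops = [o.cop * 1000.0 for o in observations]  # m -> mm
    names = tuple(
        f"b{b}_euler_{axis}_deg" for b in tree.body_order for axis in ("z", "x", "y")
    )

    ang_blocks, cop_blocks = [], []
    for k, (ch, cp) in enumerate(zip(channels, cops)):
        plateau = np.tile(ch, (n_hold, 1))
        plateau_cop = np.tile(cp, (n_hold, 1))
        if angle_jitter_deg > 0:
            plateau = plateau + rng.normal(0, angle_jitter_deg, plateau.shape)
        if cop_jitter_mm > 0:
            plateau_cop = plateau_cop + rng.normal(0, cop_jitter_mm, plateau_cop.shape)
        ang_blocks.append(plateau)
        cop_blocks.append(plateau_cop)
        if k + 1 < len(channels) and n_trans > 0:
            frac = np.linspace(0, 1, n_trans, endpoint=False)[:, None]
            ramp = ch[None, :] * (1 - frac) + channels[k + 1][None, :] * frac
            bump = transition_amp_deg * np.sin(np.pi * frac)
            ang_blocks.append(ramp + bump)
            cop_ramp = cp[None, :] * (1 - frac) + cops[k + 1][None, :] * frac
            cop_blocks.append(cop_ramp + transition_amp_mm * np.sin(np.pi * frac))

    angles = np.vstack(ang_blocks)
    cop = np.vstack(cop_blocks)
    t = np.arange(angles.shape[0]) / rate
    return TimeSeriesTrial(
        t, angles, cop, names,
        observations[0].posture.root_position.copy(), tree.body_order,
    )


def baseline_fit_table():
    """Anthropometric table calibrated on the synthetic fit population.

    Mass fractions, CoM ratios and attachment ratios are taken from the
    unjittered fit baseline; they are scale-invariant, so the table applies
    to any stature.  Deliberately mismatched to obese-preset subjects, whose
    trunk-dominant redistribution no lean-population table captures.
    """
    from .segmental import table_from_parameters

    subj = make_subject("fit", seed=0, fraction_jitter=0.0, length_jitter=0.0)
    table, _ = table_from_parameters(
        subj.tree, subj.params, label="synthetic fit-population baseline"
    )
    return table


def observation_from_detection(
    det: DetectedPosture, tree: KinematicTree, root_position: Sequence[float]
) -> StaticObservation:
    """Rebuild a static observation from a detected region's channel means."""
    vals = np.asarray(det.mean_angles_deg).reshape(len(tree.body_order), 3)
    rot = {}
    root_R = np.eye(3)
    for b, (z, x, y) in zip(tree.body_order, vals):
        R = rotation_from_euler_zxy_deg(z, x, y)
        if b == tree.root:
            root_R = R
        else:
            rot[b] = R
    posture = PostureFrame(root_R, np.asarray(root_position, dtype=float), rot)
    return StaticObservation(posture, np.asarray(det.mean_cop_mm) / 1000.0)
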