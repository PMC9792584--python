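"""Table-driven segmental-analysis CoM estimation.

The comparator method: segment masses are total body mass times tabulated
mass fractions, each segment's CoM sits a tabulated fraction of the way along
its longitudinal axis, and the whole-body CoM is the classical weighted sum.
Accuracy is entirely at the mercy of how well the population table matches
the individual — which is exactly what the serial-chain identification is
designed to sidestep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import SegmentParameters, brute_force_com
from .kinematics import KinematicTree, PostureFrame

__all__ = [
    "AnthropometricTable",
    "SubjectMeasurements",
    "params_from_table",
    "segmental_com",
    "table_from_parameters",
]

_FRACTION_TOL = 1e-6


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class AnthropometricTable:
    """Per-segment mass fractions and CoM placement rules.

    ``axis`` is each segment's longitudinal direction in its own frame;
    ``com_ratio`` locates the segment CoM that fraction of the segment length
    along it from the proximal joint.  ``attach_dir``/``attach_ratio`` place a
    segment's origin in its parent frame: the parent's length times the
    attachment ratio along the attachment direction.  A branched root (legs
    below, trunk above) needs per-child directions, which is why attachment is
    tabulated rather than inferred from the parent axis alone.
    """

    mass_fraction: Mapping[int, float]
    com_ratio: Mapping[int, float]
    axis: Mapping[int, np.ndarray]
    attach_dir: Mapping[int, np.ndarray] = field(default_factory=dict)
    attach_ratio: Mapping[int, float] = field(default_factory=dict)
    source_label: str = "unlabeled"

    def __post_init__(self) -> None:
        total = sum(self.mass_fraction.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"mass fractions must sum to 1, got {total:.8f}")
        for b, r in self.com_ratio.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"com_ratio for segment {b} outside [0, 1]: {r}")
        object.__setattr__(self, "axis", {b: _unit(a) for b, a in self.axis.items()})
        object.__setattr__(
            self, "attach_dir", {b: _unit(a) for b, a in self.attach_dir.items()}
        )

    def to_dict(self) -> dict:
        segs = []
        for b in sorted(self.mass_fraction):
            entry = {
                "id": int(b),
                "mass_fraction": float(self.mass_fraction[b]),
                "com_ratio": float(self.com_ratio[b]),
                "axis": [float(x) for x in self.axis[b]],
            }
            if b in self.attach_dir:
                entry["attach_dir"] = [float(x) for x in self.attach_dir[b]]
                entry["attach_ratio"] = float(self.attach_ratio[b])
            segs.append(entry)
        return {"source_label": self.source_label, "segments": segs}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnthropometricTable":
        mf, cr, ax, ad, ar = {}, {}, {}, {}, {}
        for s in d["segments"]:
            b = int(s["id"])
            mf[b] = float(s["mass_fraction"])
            cr[b] = float(s["com_ratio"])
            ax[b] = np.asarray(s["axis"], dtype=float)
            if "attach_dir" in s:
                ad[b] = np.asarray(s["attach_dir"], dtype=float)
                ar[b] = float(s["attach_ratio"])
        return cls(mf, cr, ax, ad, ar, d.get("source_label", "unlabeled"))

    @classmethod
    def from_json(cls, path) -> "AnthropometricTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SubjectMeasurements:
    """What is actually measured on the subject: total mass and segment lengths."""

    total_mass: float
    segment_length: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.total_mass <= 0:
            raise ValueError("total_mass must be positive")
        if any(l <= 0 for l in self.segment_length.values()):
            raise ValueError("all segment lengths must be positive")


def params_from_table(
    tree: KinematicTree,
    table: AnthropometricTable,
    meas: SubjectMeasurements,
) -> SegmentParameters:
    """Instantiate segment parameters for one subject from a population table.

    mass_i = fraction_i * total mass; C_i = com_ratio_i * length_i along the
    segment's axis; d_i = attach_ratio_i * parent length along the tabulated
    attachment direction.
    """
    for b in tree.joint_type:
        if b not in table.mass_fraction or b not in meas.segment_length:
            raise ValueError(f"table/measurements do not cover body {b}")
    mass = {b: table.mass_fraction[b] * meas.total_mass for b in tree.joint_type}
    local_com = {
        b: table.com_ratio[b] * meas.segment_length[b] * table.axis[b]
        for b in tree.joint_type
    }
    displacement = {}
    for b in tree.joint_type:
        if b == tree.root:
            continue
        p = tree.parent[b]
        direction = table.attach_dir.get(b, table.axis[p])
        ratio = table.attach_ratio.get(b, 1.0)
        displacement[b] = ratio * meas.segment_length[p] * direction
    return SegmentParameters(mass, local_com, displacement)


def segmental_com(
    tree: KinematicTree,
    table: AnthropometricTable,
    meas: SubjectMeasurements,
    posture: PostureFrame,
) -> np.ndarray:
    """Whole-body CoM by the segmental method (meters, global frame)."""
    return brute_force_com(tree, params_from_table(tree, table, meas), posture)


def measurements_from_parameters(
    tree: KinematicTree, params: SegmentParameters
) -> SubjectMeasurements:
    """Segment lengths and total mass as a tape measure would record them.

    Uses the same length convention as :func:`table_from_parameters`
    (segment CoM at half length), so a table built from one subject can be
    applied to another subject's measurements.
    """
    lengths = {}
    for b in tree.joint_type:
        norm = float(np.linalg.norm(params.local_com[b]))
        lengths[b] = norm / 0.5 if norm > 0 else 1.0
    return SubjectMeasurements(params.total_mass, lengths)


def table_from_parameters(
    tree: KinematicTree, params: SegmentParameters, label: str = "exact"
) -> tuple[AnthropometricTable, SubjectMeasurements]:
    """Invert a subject's true parameters into an exactly matching table.

    Used to verify self-consistency (an exact table reproduces the weighted
    sum) and to build 'calibrated on population X' tables for mismatch
    studies.  Segment length is defined as |C_i| / com_ratio with com_ratio
    fixed at 0.5 where the CoM is off-origin, and 1.0 with a zero C_i.
    """
    M = params.total_mass
    mf = {b: params.mass[b] / M for b in tree.joint_type}
    cr, ax, lengths, ad, ar = {}, {}, {}, {}, {}
    for b in tree.joint_type:
        C = params.local_com[b]
        norm = float(np.linalg.norm(C))
        if norm > 0:
            cr[b] = 0.5
            ax[b] = C / norm
            lengths[b] = norm / 0.5
        else:
            cr[b] = 0.0
            ax[b] = np.array([0.0, 0.0, 1.0])
            lengths[b] = 1.0
    for b in tree.joint_type:
        if b == tree.root:
            continue
        p = tree.parent[b]
        d = params.displacement[b]
        norm = float(np.linalg.norm(d))
        if norm > 0:
            ad[b] = d / norm
            ar[b] = norm / lengths[p]
        else:
            ad[b] = np.array([0.0, 0.0, 1.0])
            ar[b] = 0.0
    table = AnthropometricTable(mf, cr, ax, ad, ar, source_label=label)
    meas = SubjectMeasurements(M, lengths)
    return table, meas
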