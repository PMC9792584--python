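"""Forward models of the whole-body center of mass.

Two equivalent forms are implemented:

* the classical segmental weighted sum ``CoM = Σ m_i p_i / M`` where ``p_i``
  is segment i's CoM transformed to the global frame — used throughout as the
  ground-truth oracle;
* the statically equivalent serial chain (SESC) form
  ``CoM = d_1 + Σ_j R_path(j) v_j`` where the constant link vectors ``v_j``
  absorb all masses and geometry.  Stacked as ``CoM = [I R̂][d_1; V]`` this is
  linear in the subject-specific vector ``V``, which is what makes the
  identification problem a least-squares one.

The closed form of the virtual links, obtained by collecting the coefficient
of each path rotation in the expanded weighted sum, is

    v_j = ( m_j C_j  +  Σ_{c ∈ children(j)}  M_subtree(c) · d_c ) / M

with ``M_subtree(c)`` the total mass hanging below (and including) body c.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .kinematics import (
    AXIS_AP,
    AXIS_ML,
    KinematicTree,
    PostureFrame,
    forward_body_transforms,
    path_rotation,
)

__all__ = [
    "SegmentParameters",
    "SESCVector",
    "RegressorRow",
    "brute_force_com",
    "sesc_vector_from_parameters",
    "build_regressor_row",
    "estimate_com",
]


@dataclass(frozen=True)
class SegmentParameters:
    """Ground-truth inertial and geometric parameters of one subject.

    ``mass`` in kg, ``local_com`` (C_i) in the body frame and ``displacement``
    (d_i, offset of body i's origin in its parent frame) in meters.  The root's
    displacement entry, if present, is ignored in favor of the posture's root
    position.
    """

    mass: Mapping[int, float]
    local_com: Mapping[int, np.ndarray]
    displacement: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mass.values()):
            raise ValueError("all segment masses must be positive")
        object.__setattr__(
            self, "local_com",
            {b: np.asarray(v, dtype=float).reshape(3) for b, v in self.local_com.items()},
        )
        object.__setattr__(
            self, "displacement",
            {b: np.asarray(v, dtype=float).reshape(3) for b, v in self.displacement.items()},
        )

    @property
    def total_mass(self) -> float:
        return float(sum(self.mass.values()))

    def validate_for(self, tree: KinematicTree) -> None:
        for b in tree.joint_type:
            if b not in self.mass or b not in self.local_com:
                raise ValueError(f"mass/CoM parameters missing for body {b}")
            if b != tree.root and b not in self.displacement:
                raise ValueError(f"displacement missing for body {b}")


@dataclass(frozen=True)
class SESCVector:
    """The subject-specific vector of virtual serial-chain links (meters).

    ``stacked`` concatenates the per-body 3-vectors in the tree's declared
    body order, giving the 3n-vector the identification stage solves for.
    """

    links: Mapping[int, np.ndarray]
    body_order: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "links",
            {b: np.asarray(v, dtype=float).reshape(3) for b, v in self.links.items()},
        )
        object.__setattr__(self, "body_order", tuple(self.body_order))
        if set(self.links) != set(self.body_order):
            raise ValueError("links must cover exactly the declared body order")

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.links[b] for b in self.body_order])

    @classmethod
    def from_stacked(cls, stacked: np.ndarray, body_order) -> "SESCVector":
        stacked = np.asarray(stacked, dtype=float).reshape(-1)
        order = tuple(body_order)
        if stacked.size != 3 * len(order):
            raise ValueError(
                f"stacked length {stacked.size} != 3 x {len(order)} bodies"
            )
        links = {b: stacked[3 * i: 3 * i + 3] for i, b in enumerate(order)}
        return cls(links, order)

    def to_dict(self) -> dict:
        return {
            "body_order": [int(b) for b in self.body_order],
            "v": [[float(x) for x in self.links[b]] for b in self.body_order],
            "units": "m",
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SESCVector":
        with open(path) as fh:
            d = json.load(fh)
        order = tuple(int(b) for b in d["body_order"])
        return cls({b: np.asarray(v) for b, v in zip(order, d["v"])}, order)


@dataclass(frozen=True)
class RegressorRow:
    """Regressor of one posture: ``full`` is 3×(3+3n) = [I | R_path(1) | ...].

    ``horizontal`` keeps only the AP and ML rows of the 3×3n rotation part —
    the rows a force platform constrains, since the vertical CoM component has
    no static ground-reaction counterpart.
    """

    full: np.ndarray
    body_order: tuple[int, ...]

    @property
    def rotation_part(self) -> np.ndarray:
        return self.full[:, 3:]

    @property
    def horizontal(self) -> np.ndarray:
        return self.rotation_part[[AXIS_AP, AXIS_ML], :]


def brute_force_com(
    tree: KinematicTree, params: SegmentParameters, posture: PostureFrame
) -> np.ndarray:
    """Mass-weighted mean of the globally transformed segment CoMs (meters)."""
    params.validate_for(tree)
    transforms = forward_body_transforms(tree, posture, params.displacement)
    M = params.total_mass
    com = np.zeros(3)
    for b in tree.joint_type:
        com += params.mass[b] * transforms[b].apply(params.local_com[b])
    return com / M


def sesc_vector_from_parameters(
    tree: KinematicTree, params: SegmentParameters
) -> SESCVector:
    """Virtual-chain links from true parameters (subtree-mass closed form)."""
    params.validate_for(tree)
    M = params.total_mass
    subtree_mass = {
        b: sum(params.mass[c] for c in tree.subtree(b)) for b in tree.joint_type
    }
    links = {}
    for b in tree.joint_type:
        v = params.mass[b] * params.local_com[b]
        for c in tree.children(b):
            v = v + subtree_mass[c] * params.displacement[c]
        links[b] = v / M
    return SESCVector(links, tree.body_order)


def build_regressor_row(tree: KinematicTree, posture: PostureFrame) -> RegressorRow:
    """Assemble [I | R_path(1) | ... | R_path(n)] for one posture."""
    posture.validate_for(tree, hinge_tol=None)
    n = tree.n_bodies
    full = np.zeros((3, 3 + 3 * n))
    full[:, :3] = np.eye(3)
    for i, b in enumerate(tree.body_order):
        full[:, 3 + 3 * i: 6 + 3 * i] = path_rotation(tree, posture, b)
    return RegressorRow(full, tree.body_order)


def estimate_com(row: RegressorRow, d1: np.ndarray, V: SESCVector) -> np.ndarray:
    """SESC forward model: ``CoM = d_1 + Σ_j R_path(j) v_j`` (meters)."""
    if tuple(V.body_order) != tuple(row.body_order):
        raise ValueError("regressor row and SESC vector use different body orders")
    stacked = V.stacked
    if row.rotation_part.shape[1] != stacked.size:
        raise ValueError(
            f"regressor width {row.rotation_part.shape[1]} != |V| {stacked.size}"
        )
    d1 = np.asarray(d1, dtype=float).reshape(3)
    return d1 + row.rotation_part @ stacked
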