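"""Branched rigid-body kinematics for whole-body center-of-mass models.

The human body is represented as a tree of rigid segments connected by
spherical (3-DoF) or hinge (1-DoF) joints, rooted at a free-floating segment
(the pelvis) whose pose is given directly.  Orientation of any segment in the
global frame is the product of the joint rotations along the root-to-segment
path; its origin follows from composing the homogeneous transforms
``[R_i, d_i; 0, 1]`` along the same path.

The default humanoid tree has nine bodies: a pelvis root, two three-link leg
chains (hip-spherical, knee-hinge, ankle-hinge) and two single-link branches
off the root for the trunk/head and the upper limbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "KinematicTree",
    "PostureFrame",
    "HomogeneousTransform",
    "validate_rotation",
    "hinge_rotation",
    "rotation_from_quat",
    "rotation_from_euler_zxy_deg",
    "euler_zxy_deg_from_rotation",
    "path_rotation",
    "forward_body_transforms",
    "default_humanoid_tree",
    "read_posture_csv",
    "write_posture_csv",
]

# Global frame convention: x = anteroposterior (anterior +), y = mediolateral,
# z = vertical up.  "Horizontal" throughout the package means the (x, y) rows.
AXIS_AP, AXIS_ML, AXIS_VERT = 0, 1, 2

_ROT_TOL = 1e-8


def validate_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check that ``R`` is a proper rotation (orthonormal, det +1)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("matrix determinant is not +1 (improper rotation)")
    return R


def hinge_rotation(axis: Sequence[float], angle: float) -> np.ndarray:
    """Rotation about a fixed unit ``axis`` by ``angle`` radians (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if abs(nrm - 1.0) > _ROT_TOL:
        raise ValueError(f"hinge axis must have unit norm, got |axis| = {nrm:.3g}")
    return Rotation.from_rotvec(axis * angle).as_matrix()


def rotation_from_quat(w: float, x: float, y: float, z: float) -> np.ndarray:
    """Rotation matrix from a (w, x, y, z) quaternion (normalized internally)."""
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def rotation_from_euler_zxy_deg(z: float, x: float, y: float) -> np.ndarray:
    """Rotation from intrinsic Z-X-Y Euler angles in degrees."""
    return Rotation.from_euler("ZXY", [z, x, y], degrees=True).as_matrix()


def euler_zxy_deg_from_rotation(R: np.ndarray) -> np.ndarray:
    """Intrinsic Z-X-Y Euler angles (degrees) of a rotation matrix."""
    return Rotation.from_matrix(R).as_euler("ZXY", degrees=True)


@dataclass(frozen=True)
class HomogeneousTransform:
    """Rigid transform (R, t): maps local points p to global R @ p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", validate_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "HomogeneousTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        """self ∘ other: apply ``other`` first in its parent (= self) frame."""
        return HomogeneousTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, point: Sequence[float]) -> np.ndarray:
        return self.rotation @ np.asarray(point, dtype=float).reshape(3) + self.translation

    def as_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H


JOINT_TYPES = ("root", "spherical", "hinge")


@dataclass(frozen=True)
class KinematicTree:
    """Topology of the branched body model.

    Parameters
    ----------
    parent
        Maps each non-root body id to its parent id.  Exactly one body (the
        root) must be absent from this map.
    joint_type
        Per-body joint type: ``"root"`` (free pose), ``"spherical"`` or
        ``"hinge"``.
    hinge_axis
        Unit rotation axis, in the parent frame, for each hinge body.
    body_order
        Declared enumeration order of the bodies; fixes the stacking order of
        the serial-chain parameter vector.  Defaults to sorted ids.
    """

    parent: Mapping[int, int]
    joint_type: Mapping[int, str]
    hinge_axis: Mapping[int, np.ndarray] = field(default_factory=dict)
    body_order: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bodies = set(self.joint_type)
        roots = [b for b in bodies if self.joint_type[b] == "root"]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        root = roots[0]
        if root in self.parent:
            raise ValueError("root body must not have a parent")
        for b in bodies - {root}:
            if b not in self.parent:
                raise ValueError(f"non-root body {b} has no parent")
            if self.parent[b] not in bodies:
                raise ValueError(f"body {b} has unknown parent {self.parent[b]}")
        for b, jt in self.joint_type.items():
            if jt not in JOINT_TYPES:
                raise ValueError(f"unknown joint type {jt!r} for body {b}")
            if jt == "hinge":
                axis = np.asarray(self.hinge_axis.get(b), dtype=float)
                if axis.shape != (3,) or abs(np.linalg.norm(axis) - 1.0) > _ROT_TOL:
                    raise ValueError(f"hinge body {b} needs a unit hinge_axis")
        # acyclicity: every body must reach the root
        for b in bodies:
            seen, cur = set(), b
            while self.joint_type[cur] != "root":
                if cur in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(cur)
                cur = self.parent[cur]
        order = tuple(self.body_order) if self.body_order else tuple(sorted(bodies))
        if set(order) != bodies:
            raise ValueError("body_order must enumerate every body exactly once")
        object.__setattr__(self, "body_order", order)
        object.__setattr__(
            self, "hinge_axis",
            {b: np.asarray(a, dtype=float).reshape(3) for b, a in self.hinge_axis.items()},
        )

    @property
    def n_bodies(self) -> int:
        return len(self.joint_type)

    @property
    def root(self) -> int:
        return next(b for b, jt in self.joint_type.items() if jt == "root")

    def children(self, body: int) -> list[int]:
        return [b for b, p in self.parent.items() if p == body]

    def path_from_root(self, body: int) -> list[int]:
        """Body ids from the root down to ``body`` (inclusive)."""
        if body not in self.joint_type:
            raise KeyError(f"unknown body id {body}")
        path = [body]
        while self.joint_type[path[-1]] != "root":
            path.append(self.parent[path[-1]])
        return path[::-1]

    def subtree(self, body: int) -> list[int]:
        """Bodies in the subtree rooted at ``body`` (inclusive)."""
        out, stack = [], [body]
        while stack:
            b = stack.pop()
            out.append(b)
            stack.extend(self.children(b))
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        bodies = []
        for b in self.body_order:
            entry: dict = {"id": int(b), "joint": self.joint_type[b]}
            if b in self.parent:
                entry["parent"] = int(self.parent[b])
            if b in self.hinge_axis:
                entry["axis"] = [float(v) for v in self.hinge_axis[b]]
            bodies.append(entry)
        return {"bodies": bodies}

    @classmethod
    def from_dict(cls, d: Mapping) -> "KinematicTree":
        parent, joint_type, hinge_axis, order = {}, {}, {}, []
        for entry in d["bodies"]:
            b = int(entry["id"])
            order.append(b)
            joint_type[b] = entry["joint"]
            if "parent" in entry:
                parent[b] = int(entry["parent"])
            if "axis" in entry:
                hinge_axis[b] = np.asarray(entry["axis"], dtype=float)
        return cls(parent, joint_type, hinge_axis, tuple(order))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KinematicTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_humanoid_tree() -> KinematicTree:
    """Nine-body humanoid: pelvis root, two legs, trunk and upper-limb branches.

    Bodies 1 (root pelvis); 1→2→3→4 and 1→5→6→7 the legs (spherical hip,
    hinge knee, hinge ankle, hinge axes along ML); 1→8 trunk+head and 1→9
    upper limbs, both spherical at the root.
    """
    ml = np.array([0.0, 1.0, 0.0])
    parent = {2: 1, 3: 2, 4: 3, 5: 1, 6: 5, 7: 6, 8: 1, 9: 1}
    joint_type = {
        1: "root",
        2: "spherical", 3: "hinge", 4: "hinge",
        5: "spherical", 6: "hinge", 7: "hinge",
        8: "spherical", 9: "spherical",
    }
    hinge_axis = {3: ml, 4: ml, 6: ml, 7: ml}
    return KinematicTree(parent, joint_type, hinge_axis, tuple(range(1, 10)))


@dataclass(frozen=True)
class PostureFrame:
    """One static configuration: root pose plus per-body relative rotations."""

    root_rotation: np.ndarray
    root_position: np.ndarray
    joint_rotation: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "root_rotation", validate_rotation(self.root_rotation))
        object.__setattr__(
            self, "root_position", np.asarray(self.root_position, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "joint_rotation",
            {b: validate_rotation(R) for b, R in self.joint_rotation.items()},
        )

    def validate_for(self, tree: KinematicTree, hinge_tol: float | None = 1e-8) -> None:
        """Check coverage of every non-root body and hinge-axis consistency.

        ``hinge_tol=None`` skips the hinge-axis check; measured orientations
        carry sensor noise that need not respect the ideal 1-DoF constraint.
        """
        root = tree.root
        for b in tree.joint_type:
            if b == root:
                continue
            if b not in self.joint_rotation:
                raise ValueError(f"posture lacks a rotation for body {b}")
            if hinge_tol is not None and tree.joint_type[b] == "hinge":
                axis = tree.hinge_axis[b]
                R = self.joint_rotation[b]
                if np.linalg.norm(R @ axis - axis) > hinge_tol:
                    raise ValueError(f"body {b}: rotation does not fix its hinge axis")

    def rotation_of(self, body: int, tree: KinematicTree) -> np.ndarray:
        if body == tree.root:
            return self.root_rotation
        return self.joint_rotation[body]

    @classmethod
    def identity(cls, tree: KinematicTree) -> "PostureFrame":
        root = tree.root
        return cls(
            np.eye(3), np.zeros(3),
            {b: np.eye(3) for b in tree.joint_type if b != root},
        )


def path_rotation(tree: KinematicTree, posture: PostureFrame, body: int) -> np.ndarray:
    """Cumulative rotation from the global frame to ``body``'s frame.

    The product runs root-first along the root-to-body path, e.g. ``R_1 R_9``
    for a direct child 9 of the root.
    """
    R = np.eye(3)
    for b in tree.path_from_root(body):
        R = R @ posture.rotation_of(b, tree)
    return R


def forward_body_transforms(
    tree: KinematicTree,
    posture: PostureFrame,
    displacement: Mapping[int, np.ndarray],
) -> dict[int, HomogeneousTransform]:
    """Global pose of every body by composing [R_i, d_i] down the tree.

    ``displacement[b]`` is body ``b``'s origin offset in its parent frame; the
    root's displacement is its global position (overridden by the posture's
    ``root_position``).
    """
    for b in tree.joint_type:
        if b != tree.root and b not in displacement:
            raise ValueError(f"missing displacement for body {b}")
    root = tree.root
    out: dict[int, HomogeneousTransform] = {
        root: HomogeneousTransform(posture.root_rotation, posture.root_position)
    }
    # walk in an order that guarantees parents first
    pending = [b for b in tree.body_order if b != root]
    while pending:
        remaining = []
        for b in pending:
            p = tree.parent[b]
            if p in out:
                local = HomogeneousTransform(
                    posture.joint_rotation[b], np.asarray(displacement[b], dtype=float)
                )
                out[b] = out[p].compose(local)
            else:
                remaining.append(b)
        pending = remaining
    return out


# -- posture stream I/O -------------------------------------------------------

def write_posture_csv(path, tree: KinematicTree, postures: Iterable[PostureFrame],
                      times: Sequence[float] | None = None) -> None:
    """Write postures as one row per frame with per-body Z-X-Y Euler columns."""
    rows = []
    postures = list(postures)
    if times is None:
        times = np.arange(len(postures), dtype=float)
    root = tree.root
    for i, (t, p) in enumerate(zip(times, postures)):
        row: dict = {"frame_index": i, "time_s": t}
        for b in tree.body_order:
            z, x, y = euler_zxy_deg_from_rotation(p.rotation_of(b, tree))
            row[f"b{b}_euler_z_deg"] = z
            row[f"b{b}_euler_x_deg"] = x
            row[f"b{b}_euler_y_deg"] = y
        row["root_px_m"], row["root_py_m"], row["root_pz_m"] = p.root_position
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_posture_csv(path, tree: KinematicTree) -> list[PostureFrame]:
    """Read a posture stream written by :func:`write_posture_csv`.

    Accepts either ``b<k>_euler_{z,x,y}_deg`` or ``b<k>_quat_{w,x,y,z}``
    column groups per body.
    """
    df = pd.read_csv(path)
    root = tree.root
    postures = []
    for _, row in df.iterrows():
        rot: dict[int, np.ndarray] = {}
        for b in tree.body_order:
            if f"b{b}_quat_w" in df.columns:
                R = rotation_from_quat(
                    row[f"b{b}_quat_w"], row[f"b{b}_quat_x"],
                    row[f"b{b}_quat_y"], row[f"b{b}_quat_z"],
                )
            else:
                R = rotation_from_euler_zxy_deg(
                    row[f"b{b}_euler_z_deg"], row[f"b{b}_euler_x_deg"],
                    row[f"b{b}_euler_y_deg"],
                )
            rot[b] = R
        pos = np.array([row["root_px_m"], row["root_py_m"], row["root_pz_m"]])
        postures.append(PostureFrame(rot.pop(root), pos, rot))
    return postures
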