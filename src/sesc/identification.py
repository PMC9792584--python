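"""Least-squares identification of the subject-specific serial-chain vector.

During static stance the center of pressure measured by a force platform is
the ground projection of the center of mass, so each recorded static posture
contributes two linear equations (the AP and ML rows of the SESC forward
model) in the 3n unknowns of the link vector V.  Stacking m postures gives

    [R̂'_1; ...; R̂'_m] V = [CoP_1 - d_1,xy; ...; CoP_m - d_m,xy]

solved by the Moore–Penrose pseudoinverse.  Since each posture yields two
equations, at least ceil(3n/2) postures are required for the stack to have
full column rank at all.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import RegressorRow, SESCVector, build_regressor_row
from .kinematics import AXIS_AP, AXIS_ML, KinematicTree, PostureFrame

__all__ = [
    "StaticObservation",
    "IdentificationResult",
    "InsufficientPosturesError",
    "minimum_postures",
    "stack_system",
    "identify_sesc",
    "identify_from_observations",
    "split_postures",
]

# relative SVD cutoff for the pseudoinverse rank decision
_RCOND = 1e-10


class InsufficientPosturesError(ValueError):
    """Fewer static postures than the identification problem requires."""


@dataclass(frozen=True)
class StaticObservation:
    """One static posture paired with its force-platform CoP reading.

    ``cop`` is (AP, ML) in meters, in the global frame.
    """

    posture: PostureFrame
    cop: np.ndarray

    def __post_init__(self) -> None:
        cop = np.asarray(self.cop, dtype=float).reshape(2)
        if not np.all(np.isfinite(cop)):
            raise ValueError("CoP components must be finite")
        object.__setattr__(self, "cop", cop)


@dataclass(frozen=True)
class IdentificationResult:
    V: SESCVector
    n_postures_used: int
    rank: int
    condition_number: float
    residual_rms: float  # meters, over the stacked identification equations

    def to_dict(self) -> dict:
        return {
            "V": self.V.to_dict(),
            "n_postures_used": self.n_postures_used,
            "rank": self.rank,
            "condition_number": self.condition_number,
            "residual_rms_m": self.residual_rms,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def minimum_postures(n_bodies: int) -> int:
    """Smallest posture count m with 2m >= 3n (two equations per posture)."""
    if n_bodies < 1:
        raise ValueError("n_bodies must be >= 1")
    return math.ceil(3 * n_bodies / 2)


def stack_system(
    tree: KinematicTree, observations: Sequence[StaticObservation]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the horizontal regressor rows and CoP right-hand sides.

    Returns (A, b) with A of shape (2m, 3n) and b of length 2m; row pair k is
    posture k's AP and ML equations with right-hand side CoP_k − d_1,k
    restricted to the horizontal plane.
    """
    if len(observations) == 0:
        raise ValueError("observation list is empty")
    rows, rhs = [], []
    for obs in observations:
        row = build_regressor_row(tree, obs.posture)
        rows.append(row.horizontal)
        d1_xy = obs.posture.root_position[[AXIS_AP, AXIS_ML]]
        rhs.append(obs.cop - d1_xy)
    return np.vstack(rows), np.concatenate(rhs)


def identify_sesc(
    system: tuple[np.ndarray, np.ndarray],
    body_order: Sequence[int],
    min_m: int | None = None,
) -> IdentificationResult:
    """Minimum-norm least-squares solve of the stacked identification system.

    Uses the SVD pseudoinverse with a relative singular-value cutoff; a
    rank-deficient stack (fewer independent equations than unknowns) raises a
    warning, not an error, and the minimum-norm solution is still returned.
    """
    A, b = system
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).reshape(-1)
    if A.ndim != 2 or A.shape[0] != b.size:
        raise ValueError("inconsistent system dimensions")
    m = A.shape[0] // 2
    if min_m is not None and m < min_m:
        raise InsufficientPosturesError(
            f"{m} postures provided but at least {min_m} are required"
        )
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    cutoff = _RCOND * s[0] if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > cutoff))
    cond = float(s[0] / s[rank - 1]) if rank > 0 else np.inf
    s_inv = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    x = Vt.T @ (s_inv * (U.T @ b))
    if rank < A.shape[1]:
        warnings.warn(
            f"identification stack is rank deficient (rank {rank} < {A.shape[1]}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    residual = A @ x - b
    return IdentificationResult(
        V=SESCVector.from_stacked(x, body_order),
        n_postures_used=m,
        rank=rank,
        condition_number=cond,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
    )


def identify_from_observations(
    tree: KinematicTree,
    observations: Sequence[StaticObservation],
    enforce_minimum: bool = True,
) -> IdentificationResult:
    """Convenience wrapper: stack the observations and solve."""
    min_m = minimum_postures(tree.n_bodies) if enforce_minimum else None
    return identify_sesc(stack_system(tree, observations), tree.body_order, min_m)


def split_postures(
    observations: Sequence,
    fraction_identify: float = 0.75,
    seed: int | None = None,
    min_identify: int | None = None,
    sequential: bool = False,
):
    """Partition observations into identification and evaluation sets.

    The identification set receives round(fraction * m) observations (half
    away from zero), drawn at random under ``seed`` unless ``sequential`` is
    set, in which case the first block is used.
    """
    if not 0 < fraction_identify < 1:
        raise ValueError("fraction_identify must lie in (0, 1)")
    m = len(observations)
    if m == 0:
        raise ValueError("observation list is empty")
    n_id = int(math.floor(fraction_identify * m + 0.5))  # round half away from zero
    if min_identify is not None and n_id < min_identify:
        raise InsufficientPosturesError(
            f"identification split of {n_id} postures is below the required {min_identify}"
        )
    idx = np.arange(m)
    if not sequential:
        rng = np.random.default_rng(seed)
        rng.shuffle(idx)
    id_idx, ev_idx = np.sort(idx[:n_id]), np.sort(idx[n_id:])
    pick = lambda ix: [observations[i] for i in ix]
    return pick(id_idx), pick(ev_idx)
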