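"""Rigid-body mathematics: Kabsch superposition, RMSD, rotation extraction.

All angles are in degrees, all lengths in Å.  Superposition uses the SVD
form of the Kabsch algorithm with determinant sign correction, so proper
rotations only (no reflections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure

_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}


class DegenerateGeometryError(ValueError):
    """Point sets too degenerate (collinear/coincident) to superpose."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        point: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation by `angle_deg` about the line through `point` along `axis`."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        point = np.asarray(point, float)
        return cls(R, point - R @ point)

    @classmethod
    def translation_by(cls, shift: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(shift, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply `other` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of `mobile` onto `reference` (Kabsch/SVD).

    Returns the optimal proper rigid transform and the post-fit RMSD.
    Point sets must be equal-length with >= 3 non-collinear points.
    """
    P = np.asarray(mobile, dtype=float).reshape(-1, 3)
    Q = np.asarray(reference, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape[0]} vs {Q.shape[0]} points")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.ones(P.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (P.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, same length, not all zero")
    w = w / w.sum()

    cP = w @ P
    cQ = w @ Q
    P0 = P - cP
    Q0 = Q - cQ
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear or coincident sets leave the fit underdetermined
    if S[1] < 1e-9 * max(S[0], 1e-12) or S[0] < 1e-12:
        raise DegenerateGeometryError("point set is (near-)collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return transform, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between two matched point sets."""
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_angle(t: RigidTransform) -> tuple[float, np.ndarray]:
    """Rotation magnitude in degrees (in [0, 180]) and unit axis.

    The angle comes from the clamped-trace formula
    θ = arccos((tr R − 1)/2); the axis from the rotation vector.  For
    near-identity rotations the axis is reported as +z by convention.
    """
    tr = float(np.trace(t.rotation))
    angle = float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    norm = np.linalg.norm(rotvec)
    axis = rotvec / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    return angle, axis


def center_of_mass(
    selection: "Structure | np.ndarray | Sequence",
    mass_weighted: bool = False,
) -> np.ndarray:
    """Mean (optionally mass-weighted) position of a heavy-atom selection.

    Accepts a Structure, an iterable of residues, or an (n, 3) array
    (arrays cannot be mass-weighted).
    """
    if isinstance(selection, Structure):
        pairs = list(selection.atoms())
        coords = np.array([a.coord for _, a in pairs]).reshape(-1, 3)
        elements = [a.element for _, a in pairs]
    elif isinstance(selection, np.ndarray):
        coords = selection.reshape(-1, 3)
        elements = None
    else:
        residues = list(selection)
        coords = np.array(
            [a.coord for r in residues for a in r.atoms]
        ).reshape(-1, 3)
        elements = [a.element for r in residues for a in r.atoms]
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    if not mass_weighted:
        return coords.mean(axis=0)
    if elements is None:
        raise ValueError("mass weighting needs element information")
    masses = np.array([_ATOMIC_MASS.get(e, 12.011) for e in elements])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()
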