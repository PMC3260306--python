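"""Least-squares rigid-body superposition (Kabsch) and RMSD.

The geometric kernel behind the spin angle and the steering potential:
an SVD-based solution of the orthogonal Procrustes problem restricted to
proper rotations (no mirroring), unweighted over all points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConditioningError, ShapeError

__all__ = ["RigidTransform", "superpose", "rmsd_to", "apply_rigid"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation, x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + translation


def _check_pair(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3 or reference.ndim != 2 or reference.shape[1] != 3:
        raise ShapeError("coordinate sets must be (n, 3) arrays")
    if mobile.shape[0] != reference.shape[0]:
        raise ShapeError(
            f"point counts differ: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    if mobile.shape[0] < 3:
        raise ShapeError("need at least 3 points for a rigid superposition")
    return mobile, reference


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Find the proper rigid transform minimizing RMSD of mobile onto reference.

    Returns the transform and the minimized RMSD (Å).  Reflections are
    excluded by the usual determinant sign correction; near-collinear
    point sets, for which the in-plane rotation is ill-determined, raise
    :class:`ConditioningError`.
    """
    mobile, reference = _check_pair(mobile, reference)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr

    # collinearity check on both sets: a line has rank-1 scatter
    for pts, tag in ((x, "mobile"), (y, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[0] > 0 and s[1] / s[0] < 1e-9:
            raise ConditioningError(
                f"{tag} points are (nearly) collinear; rotation is ill-defined"
            )

    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    transform = RigidTransform(rotation=rotation, translation=translation)
    diff = transform.apply(mobile) - reference
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return transform, rmsd


def rmsd_to(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Best-fit RMSD (Å) of mobile onto reference (never negative)."""
    return superpose(mobile, reference)[1]
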