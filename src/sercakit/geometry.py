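"""Rigid-body geometry primitives: Kabsch superposition and rotation decomposition.

All coordinates are in Angstrom. Rotation operators are proper (det = +1);
reflections are suppressed, as required when superposing chiral molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "rotation_angle_axis",
    "rotation_about_axis",
    "apply_transform",
    "rmsd",
]

#: Angstrom per nanometre, for reporting RMSD in the nm convention.
ANGSTROM_PER_NM = 10.0


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too small or collinear for superposition."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of a mobile point set onto a target.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Proper orthonormal rotation operator (det = +1).
    translation : (3,) ndarray
        Translation in Angstrom, applied after rotation:
        ``x_fit = rotation @ x + translation``.
    rmsd : float
        Post-fit root-mean-square deviation in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    @property
    def rmsd_nm(self) -> float:
        """Post-fit RMSD in nanometres."""
        return self.rmsd / ANGSTROM_PER_NM

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to an (n, 3) coordinate array."""
        return apply_transform(coords, self.rotation, self.translation)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords @ np.asarray(rotation).T + np.asarray(translation)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two matched (n, 3) sets, Angstrom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _validate_point_set(coords: np.ndarray, name: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got {coords.shape}")
    if not np.isfinite(coords).all():
        raise ValueError(f"{name} contains non-finite coordinates")
    return coords


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Finds the proper rotation ``R`` and translation ``t`` minimising
    ``sum_i |R x_i + t - y_i|^2`` over matched points ``x`` (mobile) and
    ``y`` (target), via SVD of the cross-covariance matrix with the
    determinant sign correction that forbids reflections.

    Parameters
    ----------
    mobile, target : (n, 3) arrays
        Order-matched coordinate sets, n >= 3, not collinear.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are given or the points are (near-)collinear,
        in which case the rotation is not uniquely determined.
    """
    mobile = _validate_point_set(mobile, "mobile")
    target = _validate_point_set(target, "target")
    if mobile.shape != target.shape:
        raise ValueError(
            f"mobile and target must match in length: {mobile.shape[0]} vs {target.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for superposition, got {n}")

    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    x = mobile - mob_c
    y = target - tgt_c

    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # Collinear sets leave the rotation about the line undetermined: the two
    # smallest singular values vanish together.
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("point set is collinear; rotation is underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = tgt_c - rotation @ mob_c

    fitted = apply_transform(mobile, rotation, translation)
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd(fitted, target))


def rotation_angle_axis(rotation: np.ndarray) -> tuple[float, np.ndarray]:
    """Decompose a proper rotation into (angle in degrees, unit axis).

    The angle is ``arccos((trace(R) - 1) / 2)`` folded into [0, 180] degrees.
    For angles away from 0 and 180 the axis comes from the skew-symmetric
    part of ``R``; the 180-degree case falls back to the eigenvector of the
    +1 eigenvalue. The identity returns angle 0 with a conventional z axis.
    """
    rotation = np.asarray(rotation, dtype=float)
    tr = np.clip((np.trace(rotation) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(tr)))

    skew = np.array(
        [
            rotation[2, 1] - rotation[1, 2],
            rotation[0, 2] - rotation[2, 0],
            rotation[1, 0] - rotation[0, 1],
        ]
    )
    norm = np.linalg.norm(skew)
    if norm > 1e-12:
        axis = skew / norm
    elif angle < 90.0:  # identity (angle ~ 0): axis is conventional
        axis = np.array([0.0, 0.0, 1.0])
    else:  # angle ~ 180: axis from the +1 eigenvector of R
        w, v = np.linalg.eigh((rotation + rotation.T) / 2.0)
        axis = v[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
    return angle, axis


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation operator for a right-handed turn of ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    ux, uy, uz = axis / norm
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    cc = 1.0 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )
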