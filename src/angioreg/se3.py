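"""Rigid-body (SE(3)) poses, the exp/log chart used for optimization, and
geodesic pose losses.

A :class:`RigidTransform` maps points from volume world coordinates (mm) into
the C-arm frame: ``x_carm = R @ x_world + t``.  Poses are optimized and
regressed through a 6-parameter chart: the first three components are an
axis-angle rotation vector (radians), the last three the translation (mm).
``exp`` maps the chart to a transform via the Rodrigues formula, with the
translation entering directly; ``log`` is its inverse on the principal branch
(rotation angle < pi).

Two scalar distances between poses are provided as training losses:

* ``geodesic_loss(a, b)   = sqrt(theta^2 + ||t_a - t_b||^2)`` with ``theta``
  the relative rotation angle in radians, and
* ``double_geodesic_loss(a, b; f) = sqrt((f*theta)^2 + ||t_a - t_b||^2)``
  which converts the angular term to millimetres through the C-arm
  source-to-detector distance ``f``, so that rotation and translation errors
  share one unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RigidTransform",
    "TangentVector",
    "InvalidTransformError",
    "identity",
    "compose",
    "invert",
    "exp",
    "log",
    "geodesic_loss",
    "double_geodesic_loss",
    "rotation_jacobian",
    "save_transform",
    "load_transform",
]

_ORTHO_TOL = 1e-9


class InvalidTransformError(ValueError):
    """Raised when a matrix does not describe a proper rigid transform."""


def _check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.abs(rotation.T @ rotation - np.eye(3)).max()
    if err > tol:
        raise InvalidTransformError(f"rotation is not orthonormal (|R^T R - I| = {err:.3g})")
    if np.linalg.det(rotation) < 0:
        raise InvalidTransformError("rotation has negative determinant (improper rotation)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: 3x3 rotation and translation in mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points (or a single 3-vector)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {m.shape}")
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    def __repr__(self):  # pragma: no cover - cosmetic
        v = log(self)
        return (
            f"RigidTransform(angle={np.linalg.norm(v.rotation_part):.4f} rad, "
            f"t={np.round(self.translation, 3).tolist()} mm)"
        )


@dataclass(frozen=True)
class TangentVector:
    """Chart coordinates of a pose: axis-angle rotation (rad) + translation (mm)."""

    rotation_part: np.ndarray
    translation_part: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation_part", np.asarray(self.rotation_part, float).reshape(3))
        object.__setattr__(self, "translation_part", np.asarray(self.translation_part, float).reshape(3))

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.rotation_part, self.translation_part])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "TangentVector":
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(rotation_part=v[:3], translation_part=v[3:])


def identity() -> RigidTransform:
    return RigidTransform()


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform applying ``b`` first, then ``a`` (homogeneous product a @ b)."""
    return RigidTransform(
        rotation=a.rotation @ b.rotation,
        translation=a.rotation @ b.translation + a.translation,
    )


def invert(t: RigidTransform) -> RigidTransform:
    rt = t.rotation.T
    return RigidTransform(rotation=rt, translation=-rt @ t.translation)


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array([
        [0.0, -w[2], w[1]],
        [w[2], 0.0, -w[0]],
        [-w[1], w[0], 0.0],
    ])


def rotation_matrix(omega: np.ndarray) -> np.ndarray:
    """Rodrigues formula: rotation matrix of an axis-angle vector (radians)."""
    omega = np.asarray(omega, dtype=float).reshape(3)
    theta = np.linalg.norm(omega)
    K = _hat(omega)
    if theta < 1e-12:
        # second-order Taylor keeps exp smooth through zero
        return np.eye(3) + K + 0.5 * (K @ K)
    a = np.sin(theta) / theta
    b = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + a * K + b * (K @ K)


def rotation_log(rotation: np.ndarray) -> np.ndarray:
    """Axis-angle vector of a rotation matrix (principal branch, angle < pi)."""
    rotation = np.asarray(rotation, dtype=float)
    cos_theta = np.clip((np.trace(rotation) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-8:
        # first-order: R ~ I + hat(w)
        return 0.5 * np.array([
            rotation[2, 1] - rotation[1, 2],
            rotation[0, 2] - rotation[2, 0],
            rotation[1, 0] - rotation[0, 1],
        ])
    if np.pi - theta < 1e-6:
        raise ValueError(
            "rotation angle at or near pi: axis-angle branch is ambiguous; "
            "perturb the pose or handle the half-turn explicitly"
        )
    axis = (
        np.array([
            rotation[2, 1] - rotation[1, 2],
            rotation[0, 2] - rotation[2, 0],
            rotation[1, 0] - rotation[0, 1],
        ])
        / (2.0 * np.sin(theta))
    )
    return theta * axis


def exp(v: TangentVector | np.ndarray) -> RigidTransform:
    """Map chart coordinates to a pose."""
    if not isinstance(v, TangentVector):
        v = TangentVector.from_array(v)
    return RigidTransform(rotation=rotation_matrix(v.rotation_part), translation=v.translation_part)


def log(t: RigidTransform) -> TangentVector:
    """Chart coordinates of a pose (inverse of :func:`exp`)."""
    return TangentVector(rotation_part=rotation_log(t.rotation), translation_part=t.translation)


def rotation_angle(a: RigidTransform, b: RigidTransform) -> float:
    """Relative rotation angle arccos((trace(Ra^T Rb) - 1)/2), radians."""
    cos_theta = np.clip((np.trace(a.rotation.T @ b.rotation) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.arccos(cos_theta))


def geodesic_loss(a: RigidTransform, b: RigidTransform) -> float:
    """sqrt(theta^2 + ||t_a - t_b||^2); radians and mm mixed deliberately."""
    theta = rotation_angle(a, b)
    dt = a.translation - b.translation
    return float(np.sqrt(theta**2 + dt @ dt))


def double_geodesic_loss(a: RigidTransform, b: RigidTransform, f: float) -> float:
    """sqrt((f*theta)^2 + ||t_a - t_b||^2); angle converted to mm by ``f``."""
    if f <= 0:
        raise ValueError(f"source-to-detector distance must be positive, got {f}")
    theta = rotation_angle(a, b)
    dt = a.translation - b.translation
    return float(np.sqrt((f * theta) ** 2 + dt @ dt))


def rotation_jacobian(omega: np.ndarray) -> np.ndarray:
    """Derivative of the Rodrigues rotation w.r.t. its axis-angle vector.

    Returns a (3, 3, 3) array J with J[k] = dR/d omega_k, using the closed
    form of Gallego & Yezzi.  Needed for analytic pose gradients of the DRR
    renderer.
    """
    omega = np.asarray(omega, dtype=float).reshape(3)
    theta = np.linalg.norm(omega)
    R = rotation_matrix(omega)
    J = np.empty((3, 3, 3))
    if theta < 1e-8:
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            J[k] = _hat(e)
        return J
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        term = omega[k] * _hat(omega) + _hat(np.cross(omega, (np.eye(3) - R) @ e))
        J[k] = (term / theta**2) @ R
    return J


# -- serialization ------------------------------------------------------------

def save_transform(t: RigidTransform, path: str | Path) -> None:
    """Write a pose as a 4x4 homogeneous matrix.

    ``.json`` files get ``{"matrix": [[...], ...]}``; any other suffix gets
    four lines of four floats.
    """
    path = Path(path)
    m = t.matrix()
    if path.suffix == ".json":
        path.write_text(json.dumps({"matrix": m.tolist()}, indent=2) + "\n")
    else:
        np.savetxt(path, m, fmt="%.12g")


def load_transform(path: str | Path) -> RigidTransform:
    """Read a pose saved by :func:`save_transform` (text or JSON)."""
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith("{"):
        m = np.asarray(json.loads(text)["matrix"], dtype=float)
    else:
        m = np.loadtxt(path)
    return RigidTransform.from_matrix(m)
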