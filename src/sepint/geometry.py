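"""Rigid poses, pose families, and axis-angle rotations.

Conventions
-----------
Body ``P`` is held fixed and the reference frame is attached to it.  A pose
carries body ``Q`` from its reference placement to the current one: first a
right-handed rotation by ``angle`` (radians, counterclockwise when viewed
from the +axis direction) about an axis through the origin of P's frame,
then a translation.  The reference pose is the identity.  Length units are
arbitrary but must be consistent across particle files and pose sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import UnsupportedFamilyError

__all__ = [
    "FamilyKind",
    "Pose",
    "PoseFamily",
    "axis_angle_matrix",
    "apply_pose",
    "make_pose",
]

_AXIS_TOL = 1e-9


class FamilyKind(str, Enum):
    """Supported families of rigid motion with a reduced parameter count."""

    TRANSLATION_X1 = "translation_x1"  # Q slides along the x1 axis
    ROTATION_X3 = "rotation_x3"        # Q spins about the x3 axis
    GENERAL_SE3 = "general_se3"        # full 6-parameter rigid motion


_FREE_PARAMS: dict[FamilyKind, tuple[str, ...]] = {
    FamilyKind.TRANSLATION_X1: ("x1",),
    FamilyKind.ROTATION_X3: ("theta",),
    # rotation vector (axis * angle) followed by translation
    FamilyKind.GENERAL_SE3: ("r1", "r2", "r3", "x1", "x2", "x3"),
}

_FIXABLE: dict[FamilyKind, frozenset[str]] = {
    FamilyKind.TRANSLATION_X1: frozenset({"x2", "x3"}),
    FamilyKind.ROTATION_X3: frozenset({"x1", "x2", "x3"}),
    FamilyKind.GENERAL_SE3: frozenset(),
}


@dataclass(frozen=True)
class Pose:
    """A rigid transformation: rotation about ``axis`` by ``angle`` then a
    translation.

    The axis is normalized at construction; a vector further than ``1e-9``
    from unit norm (with a non-zero angle) is rejected rather than silently
    rescaled.
    """

    axis: np.ndarray = (0.0, 0.0, 1.0)
    angle: float = 0.0
    translation: np.ndarray = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if axis.shape != (3,) or trans.shape != (3,):
            raise ValueError("axis and translation must be 3-vectors")
        if not math.isfinite(self.angle):
            raise ValueError("pose angle must be finite")
        if not (np.isfinite(axis).all() and np.isfinite(trans).all()):
            raise ValueError("pose parameters must be finite")
        if self.angle != 0.0:
            nrm = float(np.linalg.norm(axis))
            if abs(nrm - 1.0) > _AXIS_TOL:
                raise ValueError(
                    f"rotation axis must be a unit vector (|axis| = {nrm:.3g})"
                )
            axis = axis / nrm
        axis.setflags(write=False)
        trans.setflags(write=False)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    def rotation_matrix(self) -> np.ndarray:
        if self.angle == 0.0:
            return np.eye(3)
        return axis_angle_matrix(self.axis, self.angle)


@dataclass(frozen=True)
class PoseFamily:
    """Which of the six rigid-motion parameters vary.

    ``fixed_values`` freezes the remaining parameters at non-default values,
    e.g. a constant lateral offset ``{"x2": 1.0}`` for a translation family.
    """

    kind: FamilyKind
    fixed_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kind = FamilyKind(self.kind)
        object.__setattr__(self, "kind", kind)
        bad = set(self.fixed_values) - _FIXABLE[kind]
        if bad:
            raise ValueError(
                f"parameters {sorted(bad)} cannot be frozen for family "
                f"{kind.value}"
            )
        object.__setattr__(self, "fixed_values", dict(self.fixed_values))

    @property
    def variable_names(self) -> tuple[str, ...]:
        return _FREE_PARAMS[self.kind]

    @property
    def n_free(self) -> int:
        return len(self.variable_names)

    def fixed_translation(self) -> np.ndarray:
        """The frozen translation offset (zero for unfrozen components)."""
        fv = self.fixed_values
        return np.array(
            [fv.get("x1", 0.0), fv.get("x2", 0.0), fv.get("x3", 0.0)]
        )


def axis_angle_matrix(axis: Sequence[float], angle: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``angle`` radians about the unit
    vector ``axis`` (Rodrigues form).

    Entry (1,1) is ``cos t + u1^2 (1 - cos t)``, entry (1,2) is
    ``u1 u2 (1 - cos t) - u3 sin t``, and so on; the matrix is orthogonal
    with determinant +1.
    """
    u = np.asarray(axis, dtype=float)
    if u.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    nrm = float(np.linalg.norm(u))
    if abs(nrm - 1.0) > _AXIS_TOL:
        raise ValueError(f"axis must have unit norm (got |axis| = {nrm:.6g})")
    u = u / nrm
    c, s = math.cos(angle), math.sin(angle)
    ux = np.array(
        [[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]]
    )
    return c * np.eye(3) + (1.0 - c) * np.outer(u, u) + s * ux


def apply_pose(pose: Pose, points: Sequence[Sequence[float]]) -> np.ndarray:
    """Apply ``pose`` to one or more points: ``R @ p + x`` for each point.

    Returns an ``(n, 3)`` array (or ``(3,)`` for a single point).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must be 3-vectors")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    out = pts @ pose.rotation_matrix().T + pose.translation
    return out[0] if single else out


def make_pose(family: PoseFamily, values: Sequence[float]) -> Pose:
    """Build a concrete :class:`Pose` from a family's free-parameter vector.

    ``translation_x1`` takes ``[x1]``; ``rotation_x3`` takes ``[theta]``
    (axis fixed to (0,0,1)); ``general_se3`` takes a rotation vector
    ``(r1, r2, r3)`` (axis*angle) followed by the translation
    ``(x1, x2, x3)``.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size != family.n_free:
        raise ValueError(
            f"family {family.kind.value} expects {family.n_free} "
            f"parameter(s), got {vals.size}"
        )
    fixed = family.fixed_translation()
    if family.kind is FamilyKind.TRANSLATION_X1:
        return Pose(translation=fixed + np.array([vals[0], 0.0, 0.0]))
    if family.kind is FamilyKind.ROTATION_X3:
        return Pose(axis=(0.0, 0.0, 1.0), angle=float(vals[0]),
                    translation=fixed)
    if family.kind is FamilyKind.GENERAL_SE3:
        rvec = vals[:3]
        theta = float(np.linalg.norm(rvec))
        axis = rvec / theta if theta > 0.0 else np.array([0.0, 0.0, 1.0])
        return Pose(axis=axis, angle=theta, translation=vals[3:])
    raise UnsupportedFamilyError(str(family.kind))
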