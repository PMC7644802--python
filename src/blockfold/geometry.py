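"""Rigid-body transform algebra and point-set superposition.

All placement math in the package reduces to composing proper rigid
transforms (rotation + translation, no scaling, no reflection) and to
least-squares superposition of labelled point sets.  Lengths are Angstrom
everywhere inside the package; unit conversion happens only at file
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InvalidTransformError

#: numerical tolerance for orthonormality / identity checks
TOL = 1e-9


def _as_rotation(m) -> np.ndarray:
    r = np.asarray(m, dtype=float)
    if r.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got shape {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=TOL, rtol=0.0):
        raise InvalidTransformError("rotation matrix is not orthonormal")
    if np.linalg.det(r) < 0:
        raise InvalidTransformError(
            "rotation has negative determinant (reflection); "
            "reflected placements are not valid"
        )
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: ``p -> rotation @ p + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", _as_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float)
        if t.shape != (3,):
            raise InvalidTransformError(f"translation must be 3-vector, got {t.shape}")
        object.__setattr__(self, "translation", t)
        self.rotation.setflags(write=False)
        self.translation.setflags(write=False)

    # -- algebra ---------------------------------------------------------

    def apply_points(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.size == 0:
            return coords.reshape(0, 3)
        return coords @ self.rotation.T + self.translation

    def apply_vector(self, v) -> np.ndarray:
        return self.rotation @ np.asarray(v, dtype=float) + self.translation

    def is_identity(self, tol: float = TOL) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol, rtol=0.0)
            and np.allclose(self.translation, 0.0, atol=tol, rtol=0.0)
        )

    def allclose(self, other: "RigidTransform", tol: float = TOL) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol, rtol=0.0)
            and np.allclose(self.translation, other.translation, atol=tol, rtol=0.0)
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rot": [[float(x) for x in row] for row in self.rotation],
            "tran": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(rotation=d["rot"], translation=d["tran"])


IDENTITY = RigidTransform()


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Return the transform equivalent to applying ``inner`` then ``outer``."""
    return RigidTransform(
        rotation=outer.rotation @ inner.rotation,
        translation=outer.rotation @ inner.translation + outer.translation,
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: ``compose(t, invert(t))`` is the identity."""
    rt = t.rotation.T
    return RigidTransform(rotation=rt, translation=-(rt @ t.translation))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * k + (1.0 - c) * np.outer(axis, axis)


def rotation_about_point(point, rotation: np.ndarray) -> RigidTransform:
    """Rigid transform rotating space about a fixed ``point``."""
    point = np.asarray(point, dtype=float)
    r = np.asarray(rotation, dtype=float)
    return RigidTransform(rotation=r, translation=point - r @ point)


@dataclass
class PointSet:
    """Ordered coordinates with optional per-point string labels."""

    coords: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.coords):
                raise ValueError(
                    f"labels ({len(self.labels)}) and coords ({len(self.coords)}) "
                    "length mismatch"
                )

    def __len__(self) -> int:
        return len(self.coords)


def apply(t: RigidTransform, pts: PointSet) -> PointSet:
    """Apply a rigid transform to a point set; labels are preserved."""
    return PointSet(
        coords=t.apply_points(pts.coords),
        labels=None if pts.labels is None else list(pts.labels),
    )


def superpose(mobile: PointSet, target: PointSet) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    Returns the optimal proper rigid transform ``t`` and the residual RMSD
    after applying ``t`` to ``mobile``.
    """
    a = np.asarray(mobile.coords, dtype=float)
    b = np.asarray(target.coords, dtype=float)
    if a.shape != b.shape:
        raise DegenerateGeometryError(
            f"point count mismatch: mobile {a.shape[0]} vs target {b.shape[0]}"
        )
    n = a.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear configurations leave a free rotation about the common axis
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise DegenerateGeometryError("mobile points are collinear")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = RigidTransform(rotation=r, translation=cb - r @ ca)
    rmsd = float(np.sqrt(np.mean(np.sum((t.apply_points(a) - b) ** 2, axis=1))))
    return t, rmsd
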