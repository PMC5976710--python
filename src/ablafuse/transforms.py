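"""Spatial transforms used by the registration pipeline.

Every transform maps **fixed-space world points to moving-space world
points** (the pull-back / resampling convention): to paint the moving CECT
onto the fixed CBCT grid, each fixed voxel centre is pushed through the
chain and the moving image is interpolated there.  A ``TransformChain``
applies its members in list order; the empty chain is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "BSplineTransform",
    "TransformChain",
    "bspline_weights_1d",
    "invert_chain_at_points",
]


@dataclass
class RigidTransform:
    """6-DOF rigid map: x -> R x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation matrix must have det = +1 (no reflection)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def to_dict(self):
        return {
            "type": "rigid",
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AffineTransform:
    """Centered affine map: x -> M (x - c) + c + t."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.center is None:
            self.center = np.zeros(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "AffineTransform":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform(minv, -minv @ self.translation, self.center)

    def to_dict(self):
        return {
            "type": "affine",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))


def bspline_weights_1d(f: np.ndarray):
    """Cubic B-spline basis values at fractional offsets ``f`` in [0, 1).

    Returns the four weights for control points i-1, i, i+1, i+2.
    """
    f2 = f * f
    f3 = f2 * f
    w0 = (1.0 - 3.0 * f + 3.0 * f2 - f3) / 6.0
    w1 = (3.0 * f3 - 6.0 * f2 + 4.0) / 6.0
    w2 = (-3.0 * f3 + 3.0 * f2 + 3.0 * f + 1.0) / 6.0
    w3 = f3 / 6.0
    return w0, w1, w2, w3


@dataclass
class BSplineTransform:
    """Free-form deformation: x -> x + u(x), with u a cubic-B-spline field.

    The displacement (mm) is a tensor-product cubic B-spline over a regular
    control-point lattice with ``grid_origin``/``grid_spacing`` (world mm)
    and ``coefficients`` of shape (nx, ny, nz, 3).
    """

    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(3)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(self.grid_spacing <= 0):
            raise ValueError("control grid spacing must be strictly positive")
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if any(n < 4 for n in self.coefficients.shape[:3]):
            raise ValueError("control grid needs >= 4 points per axis (cubic support)")

    @property
    def grid_shape(self):
        return self.coefficients.shape[:3]

    def support_indices_and_weights(self, pts: np.ndarray):
        """Flat control indices (N, 64) and weights (N, 64) for each point."""
        pts = np.asarray(pts, dtype=float)
        s = (pts - self.grid_origin) / self.grid_spacing
        nx, ny, nz = self.grid_shape
        base = np.floor(s).astype(np.int64)
        f = s - base
        # clip so the 4-point support stays inside the lattice; the lattice is
        # built with a margin so interior points are unaffected
        base[:, 0] = np.clip(base[:, 0], 1, nx - 3)
        base[:, 1] = np.clip(base[:, 1], 1, ny - 3)
        base[:, 2] = np.clip(base[:, 2], 1, nz - 3)
        f = s - base
        wx = np.stack(bspline_weights_1d(f[:, 0]), axis=1)  # (N, 4)
        wy = np.stack(bspline_weights_1d(f[:, 1]), axis=1)
        wz = np.stack(bspline_weights_1d(f[:, 2]), axis=1)
        offs = np.array([-1, 0, 1, 2], dtype=np.int64)
        ix = base[:, 0:1] + offs  # (N, 4)
        iy = base[:, 1:2] + offs
        iz = base[:, 2:3] + offs
        # tensor products -> (N, 4, 4, 4) flattened to (N, 64)
        w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
        flat = (
            ix[:, :, None, None] * (ny * nz)
            + iy[:, None, :, None] * nz
            + iz[:, None, None, :]
        ).reshape(-1, 64)
        return flat, w

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        flat, w = self.support_indices_and_weights(pts)
        cflat = self.coefficients.reshape(-1, 3)
        return np.einsum("nk,nkd->nd", w, cflat[flat])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts + self.displacement(pts)

    def to_dict(self):
        return {
            "type": "bspline",
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing.tolist(),
            "grid_shape": list(self.grid_shape),
            "coefficients": self.coefficients.reshape(-1).tolist(),
        }


_TYPE_TAGS = {"rigid": RigidTransform, "affine": AffineTransform, "bspline": BSplineTransform}


def _transform_from_dict(d: dict):
    tag = d.get("type")
    if tag == "rigid":
        return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))
    if tag == "affine":
        return AffineTransform(np.asarray(d["matrix"]), np.asarray(d["translation"]),
                               np.asarray(d["center"]))
    if tag == "bspline":
        shape = tuple(d["grid_shape"]) + (3,)
        return BSplineTransform(np.asarray(d["grid_origin"]), np.asarray(d["grid_spacing"]),
                                np.asarray(d["coefficients"]).reshape(shape))
    raise ValueError(f"unknown transform type tag {tag!r}")


@dataclass
class TransformChain:
    """Ordered composition of transforms, applied in list order.

    ``chain.apply(x)`` with members [t1, t2, t3] computes t3(t2(t1(x)));
    the empty chain is the identity.
    """

    transforms: list = field(default_factory=list)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        for t in self.transforms:
            pts = t.apply(pts)
        return pts

    def extended(self, t) -> "TransformChain":
        return TransformChain(list(self.transforms) + [t])

    def __len__(self):
        return len(self.transforms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "convention": "fixed_to_moving",
                "transforms": [t.to_dict() for t in self.transforms],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TransformChain":
        d = json.loads(s)
        conv = d.get("convention", "fixed_to_moving")
        if conv != "fixed_to_moving":
            raise ValueError(f"unsupported transform convention {conv!r}")
        return cls([_transform_from_dict(t) for t in d["transforms"]])


def invert_chain_at_points(chain: TransformChain, targets: np.ndarray,
                           x0: np.ndarray | None = None, tol: float = 1e-12,
                           max_iter: int = 100) -> np.ndarray:
    """Numerically invert ``chain`` at each target point (Newton iteration).

    Finds x such that chain(x) == target; used to pull moving-space landmark
    positions back into fixed space for ground-truth generation.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    x = targets.copy() if x0 is None else np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    eps = 1e-3
    for _ in range(max_iter):
        r = chain.apply(x) - targets
        if np.max(np.linalg.norm(r, axis=1)) < tol:
            break
        # per-point 3x3 Jacobian by central differences
        jac = np.empty((x.shape[0], 3, 3))
        for a in range(3):
            dx = np.zeros(3)
            dx[a] = eps
            jac[:, :, a] = (chain.apply(x + dx) - chain.apply(x - dx)) / (2 * eps)
        x -= np.linalg.solve(jac, r[:, :, None])[:, :, 0]
    return x
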