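"""Volume data model, file I/O and geometric resampling.

World coordinates are LPS millimetres (the DICOM/ITK convention, natural for
CT input); voxel indices are 0-based and a voxel's world position is the
centre of its cell::

    world = origin + direction @ (spacing * index)

Supported on-disk formats are NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel,
whose RAS affine is converted to LPS on read and back on write) and MetaImage
(``.mha`` / ``.mhd``, via SimpleITK, which already speaks LPS).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "GridSpec",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "clamp_window",
]

_INTERP_ORDERS = {"nearest": 0, "linear": 1, "bspline3": 3}

#: maps RAS homogeneous coordinates (NIfTI) to LPS (DICOM/ITK)
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _validate_geometry(shape, spacing, origin, direction):
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError(f"non-3D payload: shape {shape}")
    if any(s < 2 for s in shape):
        raise ValueError(f"each axis needs >= 2 voxels, got shape {shape}")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    origin = np.asarray(origin, dtype=float).reshape(3)
    direction = np.asarray(direction, dtype=float).reshape(3, 3)
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-4):
        raise ValueError("direction matrix is not orthonormal")
    if abs(abs(np.linalg.det(direction)) - 1.0) > 1e-4:
        raise ValueError("direction matrix must have |det| = 1")
    return shape, spacing, origin, direction


@dataclass
class GridSpec:
    """Geometry of a 3D sampling grid: shape, spacing (mm/voxel), origin
    (mm) and a 3x3 orthonormal direction matrix whose columns are the world
    directions of the voxel axes."""

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray = None
    direction: np.ndarray = None

    def __post_init__(self):
        if self.origin is None:
            self.origin = np.zeros(3)
        if self.direction is None:
            self.direction = np.eye(3)
        self.shape, self.spacing, self.origin, self.direction = _validate_geometry(
            self.shape, self.spacing, self.origin, self.direction
        )

    # -- coordinate maps ---------------------------------------------------
    @property
    def index_to_world_matrix(self) -> np.ndarray:
        return self.direction * self.spacing[np.newaxis, :]

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.index_to_world_matrix.T + self.origin

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.index_to_world_matrix)
        return (pts - self.origin) @ inv.T

    def world_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, C-ordered, shape (N, 3)."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def center_world(self) -> np.ndarray:
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_world(c)

    # -- construction / serialization -------------------------------------
    @classmethod
    def from_volume(cls, v: "Volume") -> "GridSpec":
        return cls(v.data.shape, v.spacing.copy(), v.origin.copy(), v.direction.copy())

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": list(self.shape),
                "spacing": self.spacing.tolist(),
                "origin": self.origin.tolist(),
                "direction": self.direction.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "GridSpec":
        d = json.loads(s)
        return cls(d["shape"], d["spacing"], d["origin"], d["direction"])

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class Volume:
    """A 3D scalar image (HU-like intensities) with world geometry."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None
    direction: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D payload: data has {self.data.ndim} dimensions")
        if self.origin is None:
            self.origin = np.zeros(3)
        if self.direction is None:
            self.direction = np.eye(3)
        _, self.spacing, self.origin, self.direction = _validate_geometry(
            self.data.shape, self.spacing, self.origin, self.direction
        )

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_volume(self)

    @property
    def shape(self):
        return self.data.shape

    def index_to_world(self, idx):
        return self.grid.index_to_world(idx)

    def world_to_index(self, pts):
        return self.grid.world_to_index(pts)

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing.copy(), self.origin.copy(), self.direction.copy())


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _infer_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".mha", ".mhd")):
        return "metaimage"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def read_volume(path, format: str | None = None) -> Volume:
    """Read a 3D volume from NIfTI-1 or MetaImage.

    Geometry is taken from the header (converted to LPS mm); intensities are
    returned unchanged.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(path)
            data = np.asanyarray(img.dataobj)
            affine = img.affine
        except Exception as exc:  # malformed header
            raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
        if data.ndim != 3:
            raise ValueError(f"non-3D payload in {path}: {data.ndim} dimensions")
        lps = _RAS2LPS @ affine
        mat = lps[:3, :3]
        spacing = np.linalg.norm(mat, axis=0)
        if np.any(spacing <= 0):
            raise ValueError(f"malformed NIfTI header in {path}: zero pixdim")
        direction = mat / spacing[np.newaxis, :]
        return Volume(data, spacing, lps[:3, 3], direction)
    if fmt == "metaimage":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(path)
        except Exception as exc:
            raise ValueError(f"malformed MetaImage file {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise ValueError(f"non-3D payload in {path}: {img.GetDimension()} dimensions")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
        return Volume(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()), direction)
    raise ValueError(f"unknown volume format {fmt!r} (expected 'nifti' or 'metaimage')")


def write_volume(v: Volume, path, format: str | None = None) -> None:
    """Write a Volume to NIfTI-1 or MetaImage (format inferred from suffix)."""
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        lps = np.eye(4)
        lps[:3, :3] = v.direction * v.spacing[np.newaxis, :]
        lps[:3, 3] = v.origin
        ras = _RAS2LPS @ lps
        img = nib.Nifti1Image(np.asarray(v.data), ras)
        img.header.set_qform(ras, code=1)
        img.header.set_sform(ras, code=1)
        nib.save(img, path)
        return
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.origin))
        img.SetDirection(tuple(float(d) for d in v.direction.reshape(-1)))
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unknown volume format {fmt!r} (expected 'nifti' or 'metaimage')")


# ---------------------------------------------------------------------------
# resampling / windowing
# ---------------------------------------------------------------------------


def sample_at_world(moving: Volume, pts_world: np.ndarray, interp: str = "linear",
                    fill: float | None = None) -> np.ndarray:
    """Sample ``moving`` at arbitrary world points (mm).

    Points outside the moving extent receive ``fill`` (default: the moving
    image's minimum, approximating air/background in CT).
    """
    if interp not in _INTERP_ORDERS:
        raise ValueError(f"unknown interpolator {interp!r}; expected one of {sorted(_INTERP_ORDERS)}")
    from scipy.ndimage import map_coordinates

    order = _INTERP_ORDERS[interp]
    if fill is None:
        fill = float(np.min(moving.data))
    coords = moving.world_to_index(pts_world).T  # (3, N) index coordinates
    data = np.asarray(moving.data, dtype=float)
    return map_coordinates(
        data, coords, order=order, mode="constant", cval=float(fill),
        prefilter=(order > 1),
    )


def resample_to_grid(moving: Volume, grid: GridSpec, interp: str = "linear",
                     fill: float | None = None) -> Volume:
    """Resample ``moving`` onto ``grid`` (pipeline step 1: CECT at CBCT
    resolution).  Each output voxel takes the interpolated moving-image
    value at the same world point."""
    values = sample_at_world(moving, grid.world_points(), interp=interp, fill=fill)
    return Volume(values.reshape(grid.shape), grid.spacing.copy(),
                  grid.origin.copy(), grid.direction.copy())


def clamp_window(v: Volume, lo: float, hi: float) -> Volume:
    """Clip intensities to the window [lo, hi]; geometry unchanged."""
    if not lo < hi:
        raise ValueError(f"ill-posed window: lo ({lo}) must be < hi ({hi})")
    return v.copy_with(np.clip(v.data, lo, hi))
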