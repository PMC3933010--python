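"""3-D gray-level volumes and stack rasterization.

The volume is a scalar grid with spacing, origin and an orthonormal
direction matrix that maps image coordinates (ICS voxel indices) to the
patient coordinate system (PCS, mm):

    world = origin + orientation @ (spacing * index)

with ``index = (ix, iy, iz)``.  The voxel array is stored numpy-style as
``voxels[iz, iy, ix]``.  Rasterization of an ellipse stack assumes the
volume is in the de-rotated frame (identity in-plane orientation), which is
where all model computations live; use :func:`ellipstack.io.derotate` first
for oblique acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidParameterError
from .geometry import EllipseStack, GridSpec, rasterize_ellipse

__all__ = [
    "ImageVolume",
    "rasterize_stack",
    "stack_masks_on_grid",
    "polygon_mask",
    "contour_masks_on_grid",
]


@dataclass
class ImageVolume:
    """Gray-level grid with geometry (the Lambda_DCM role).

    voxels : (nz, ny, nx) scalar array
    spacing : (dx, dy, dz) mm, dz the slice distance
    origin : (x0, y0, z0) mm, center of voxel (0, 0, 0)
    orientation : 3x3 orthonormal direction matrix (columns = patient-space
        directions of the x/y/z index axes)
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InvalidParameterError("voxels must be a 3-D array (nz, ny, nx)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise InvalidParameterError("spacing must be positive")
        if not np.allclose(
            self.orientation.T @ self.orientation, np.eye(3), atol=1e-6
        ):
            raise GeometryError("orientation matrix must be orthonormal")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 ICS -> PCS affine on (ix, iy, iz, 1)."""
        A = np.eye(4)
        A[:3, :3] = self.orientation @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * self.spacing @ self.orientation.T + self.origin

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.origin) @ self.orientation / self.spacing

    @property
    def slice_positions(self) -> np.ndarray:
        """Patient-space z of every slice (assumes de-rotated orientation)."""
        nz = self.voxels.shape[0]
        return self.origin[2] + self.spacing[2] * np.arange(nz)

    def in_plane_grid(self) -> GridSpec:
        nz, ny, nx = self.voxels.shape
        return GridSpec(
            origin=(self.origin[0], self.origin[1]),
            spacing=(self.spacing[0], self.spacing[1]),
            shape=(ny, nx),
        )

    def slice_index_of(self, z: float, tol: float | None = None) -> int:
        zs = self.slice_positions
        k = int(np.argmin(np.abs(zs - z)))
        tol = 0.5 * self.spacing[2] if tol is None else tol
        if abs(zs[k] - z) > tol + 1e-9:
            raise GeometryError(f"no volume slice at z={z:g} mm (nearest {zs[k]:g})")
        return k


def stack_masks_on_grid(stack: EllipseStack, volume: ImageVolume) -> np.ndarray:
    """Rasterize each stack slice onto the matching volume slice.

    Returns a boolean (nz, ny, nx) array; volume slices without a stack
    slice are all-false."""
    masks = np.zeros(volume.shape, dtype=bool)
    grid = volume.in_plane_grid()
    for z, params in stack:
        k = volume.slice_index_of(z)
        masks[k] = rasterize_ellipse(params, grid)
    return masks


def polygon_mask(points_xy: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Even-odd fill of a closed polygon on the in-plane grid (pixel-center
    rule, matching the ellipse rasterizer's convention)."""
    from skimage.draw import polygon2mask

    pts = np.asarray(points_xy, dtype=float)
    cols = (pts[:, 0] - grid.origin[0]) / grid.spacing[0]
    rows = (pts[:, 1] - grid.origin[1]) / grid.spacing[1]
    return polygon2mask(grid.shape, np.column_stack([rows, cols]))


def contour_masks_on_grid(contours, volume: ImageVolume) -> np.ndarray:
    """Rasterize reference contours slice-by-slice onto the volume grid."""
    masks = np.zeros(volume.shape, dtype=bool)
    grid = volume.in_plane_grid()
    for c in contours:
        k = volume.slice_index_of(c.z)
        masks[k] = polygon_mask(c.points, grid)
    return masks


# orchestration-facing alias
rasterize_stack = stack_masks_on_grid
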