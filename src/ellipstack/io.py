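"""File I/O and coordinate handling.

Native formats are versioned JSON documents with explicit mm units
(contours, control points, ellipse stacks, shape models, slice geometry);
volumes are read and written as NRRD or NIfTI through SimpleITK, and a
DICOM image series can be read from a directory (the orientation/position
tags populate the ICS->PCS affine; inconsistent slice spacing is rejected
with the offending gap named).
"""

from __future__ import annotations

import json
import os

import numpy as np

from .errors import GeometryError, InvalidParameterError
from .geometry import EllipseStack, GridSpec, SliceContour
from .registration import ControlPointSet
from .volume import ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_contours",
    "write_contours",
    "read_control_points",
    "write_control_points",
    "read_stack",
    "write_stack",
    "read_geometry",
    "write_geometry",
    "derotate_volume",
    "derotate_contours",
]


# --------------------------------------------------------------------- #
# volumes
# --------------------------------------------------------------------- #
def _volume_from_sitk(img) -> ImageVolume:
    import SimpleITK as sitk

    vox = sitk.GetArrayFromImage(img)  # (nz, ny, nx)
    return ImageVolume(
        voxels=vox,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        orientation=np.array(img.GetDirection()).reshape(3, 3),
    )


def read_volume(path) -> ImageVolume:
    """Read a volume (NRRD/NIfTI file, or a DICOM series directory)."""
    import SimpleITK as sitk

    path = os.fspath(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(path)
        if not files:
            raise InvalidParameterError(f"no DICOM series found in {path}")
        _check_dicom_spacing(files)
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(path)
    return _volume_from_sitk(img)


def _check_dicom_spacing(files, rtol: float = 1e-3) -> None:
    """Reject DICOM series whose slice positions are not equidistant."""
    import pydicom

    pos = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        pos.append(np.asarray(ds.ImagePositionPatient, dtype=float))
    pos = np.array(pos)
    if len(pos) < 3:
        return
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    ref = np.median(d)
    bad = np.nonzero(np.abs(d - ref) > rtol * ref)[0]
    if bad.size:
        i = int(bad[0])
        raise GeometryError(
            f"inconsistent DICOM slice spacing between slices {i} and {i + 1}: "
            f"{d[i]:.4f} mm vs median {ref:.4f} mm"
        )


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NRRD or NIfTI (by file extension)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(volume.voxels))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.orientation.ravel()))
    sitk.WriteImage(img, os.fspath(path))


def derotate_volume(volume: ImageVolume) -> ImageVolume:
    """Move a volume into the de-rotated PCS (identity orientation, same
    origin); the voxel grid becomes axis-aligned."""
    if not np.allclose(
        volume.orientation.T @ volume.orientation, np.eye(3), atol=1e-6
    ):
        raise GeometryError("orientation matrix must be orthonormal")
    return ImageVolume(
        voxels=volume.voxels,
        spacing=volume.spacing,
        origin=volume.origin,
        orientation=np.eye(3),
    )


def derotate_contours(contours, orientation, origin) -> list:
    """Apply the inverse direction matrix about the volume origin so the
    contour slice planes align with the grid axes."""
    O = np.asarray(orientation, dtype=float).reshape(3, 3)
    if not np.allclose(O.T @ O, np.eye(3), atol=1e-6):
        raise GeometryError("orientation matrix must be orthonormal")
    origin = np.asarray(origin, dtype=float).reshape(3)
    out = []
    for c in contours:
        pts3 = np.column_stack([c.points, np.full(len(c.points), c.z)])
        rot = (pts3 - origin) @ O + origin  # (O^T applied from the left)
        zvals = rot[:, 2]
        if np.ptp(zvals) > 1e-6:
            raise GeometryError(
                f"contour at z={c.z:g} does not stay planar under de-rotation"
            )
        out.append(SliceContour(z=float(zvals.mean()), points=rot[:, :2]))
    return sorted(out, key=lambda c: c.z)


# --------------------------------------------------------------------- #
# JSON documents
# --------------------------------------------------------------------- #
def _load_doc(path, kind: str) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("kind") != kind:
        raise InvalidParameterError(
            f"{path}: expected document kind '{kind}', got {doc.get('kind')!r}"
        )
    return doc


def write_contours(contours, path) -> None:
    doc = {
        "version": 1,
        "kind": "ellipstack-contours",
        "units": "mm",
        "slices": [
            {"z": float(c.z), "points": np.asarray(c.points).tolist()}
            for c in contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_contours(path) -> list:
    """Read closed per-slice contours (mm, PCS), sorted by z."""
    doc = _load_doc(path, "ellipstack-contours")
    out = []
    for i, s in enumerate(doc["slices"]):
        try:
            out.append(SliceContour(z=s["z"], points=np.asarray(s["points"])))
        except (KeyError, ValueError) as exc:
            raise InvalidParameterError(
                f"{path}: bad contour record at slice index {i}: {exc}"
            ) from exc
    return sorted(out, key=lambda c: c.z)


def write_control_points(cp: ControlPointSet, path) -> None:
    doc = {
        "version": 1,
        "kind": "ellipstack-control-points",
        "units": "mm",
        "groups": {
            name: np.asarray(getattr(cp, name)).tolist()
            for name in ("first", "center", "last")
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_control_points(path) -> ControlPointSet:
    doc = _load_doc(path, "ellipstack-control-points")
    g = doc["groups"]
    return ControlPointSet(
        first=np.asarray(g["first"]),
        center=np.asarray(g["center"]),
        last=np.asarray(g["last"]),
    )


def write_stack(stack: EllipseStack, path) -> None:
    doc = {
        "version": 1,
        "kind": "ellipstack-stack",
        "units": "mm",
        "slices": [
            {
                "z": float(z),
                "theta": p.theta.tolist(),
                "alpha": p.alpha.tolist(),
                "phi": float(p.phi),
            }
            for z, p in stack
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_stack(path) -> EllipseStack:
    doc = _load_doc(path, "ellipstack-stack")
    slices = doc["slices"]
    z = [s["z"] for s in slices]
    theta = np.array([s["theta"] for s in slices])
    alpha = np.array([s["alpha"] for s in slices])
    phi = np.array([s["phi"] for s in slices])
    return EllipseStack.from_arrays(z, theta, alpha, phi)


def write_geometry(grid: GridSpec, slice_z, path) -> None:
    doc = {
        "version": 1,
        "kind": "ellipstack-geometry",
        "units": "mm",
        "grid": {
            "origin": list(grid.origin),
            "spacing": list(grid.spacing),
            "shape": list(grid.shape),
        },
        "slice_z": np.asarray(slice_z, dtype=float).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_geometry(path):
    """Read a slice-grid geometry document; returns (GridSpec, slice_z)."""
    doc = _load_doc(path, "ellipstack-geometry")
    g = doc["grid"]
    grid = GridSpec(
        origin=tuple(g["origin"]), spacing=tuple(g["spacing"]), shape=tuple(g["shape"])
    )
    return grid, np.asarray(doc["slice_z"], dtype=float)
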