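"""Control-point registration into the common sample space.

Eighteen boundary control points (6 on each of the organ's first, center and
last contour slices) determine a similarity-type transform that maps a
de-rotated case into the sample space in which training statistics are
computed:

* translation: the centroid of all 18 points goes to the origin;
* in-plane rotation: the first principal direction of the center-slice
  group is aligned with the x-axis (angle fixed to (-pi/2, pi/2]);
* isotropic in-plane scale: the RMS in-plane radius of the center-slice
  group (about its own centroid) becomes 1;
* z-scale: the z distance between the first and last groups becomes 1.

A similarity map preserves ellipse-ness exactly, so transformed stacks stay
inside the parameter family.  The same control points also define the center
curve xi: the component-wise quadratic in z through the three group
centroids; per-slice ellipse centers are modeled as xi + eta with eta the
learned offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateControlPointsError, InvalidParameterError
from .geometry import (
    EllipseParams,
    EllipseStack,
    ellipse_boundary,
    rotation_matrix,
    wrap_angle,
)

__all__ = [
    "ControlPointSet",
    "SampleSpaceTransform",
    "CenterCurve",
    "auto_control_points",
    "compute_transform",
    "to_sample_space",
    "from_sample_space",
    "center_curve",
]

_GROUPS = ("first", "center", "last")


@dataclass(frozen=True)
class ControlPointSet:
    """18 labeled boundary points: 6 per group on the first/center/last slice.

    Each group is a (6, 3) array of patient-space mm coordinates sharing one
    z value; the three group z values are distinct and increasing.
    """

    first: np.ndarray
    center: np.ndarray
    last: np.ndarray

    def __post_init__(self):
        zs = []
        for name in _GROUPS:
            pts = np.asarray(getattr(self, name), dtype=float)
            if pts.shape != (6, 3):
                raise InvalidParameterError(f"group '{name}' must be (6, 3)")
            if not np.all(np.isfinite(pts)):
                raise InvalidParameterError(f"group '{name}' has non-finite points")
            if np.ptp(pts[:, 2]) > 1e-6:
                raise InvalidParameterError(f"group '{name}' is not coplanar in z")
            object.__setattr__(self, name, pts)
            zs.append(float(pts[0, 2]))
        if not (zs[0] < zs[1] < zs[2]):
            raise InvalidParameterError(
                f"group z values must be strictly increasing, got {zs}"
            )

    @property
    def groups(self):
        return (self.first, self.center, self.last)

    @property
    def z_values(self) -> np.ndarray:
        return np.array([g[0, 2] for g in self.groups])

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack(self.groups)

    @property
    def centroids(self) -> np.ndarray:
        """(3, 3) centroids of the first/center/last groups."""
        return np.array([g.mean(axis=0) for g in self.groups])

    def transformed(self, fn) -> "ControlPointSet":
        """Apply a point-wise map (K,3)->(K,3) to every group."""
        return ControlPointSet(*(fn(g) for g in self.groups))


@dataclass(frozen=True)
class SampleSpaceTransform:
    """Similarity-type map into the sample space (the Lambda_dCP role).

    Applied to a point p = (x, y, z):
        xy -> scale * R(in_plane_rotation) @ (xy - translation[:2])
        z  -> z_scale * (z - translation[2])
    """

    translation: np.ndarray
    scale: float
    in_plane_rotation: float
    z_scale: float

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0 or self.z_scale <= 0:
            raise InvalidParameterError("scales must be positive")
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))
        object.__setattr__(self, "in_plane_rotation", float(self.in_plane_rotation))
        object.__setattr__(self, "z_scale", float(self.z_scale))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty_like(pts)
        R = rotation_matrix(self.in_plane_rotation)
        out[:, :2] = self.scale * (pts[:, :2] - self.translation[:2]) @ R.T
        out[:, 2] = self.z_scale * (pts[:, 2] - self.translation[2])
        return out

    def invert_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty_like(pts)
        R = rotation_matrix(-self.in_plane_rotation)
        out[:, :2] = (pts[:, :2] / self.scale) @ R.T + self.translation[:2]
        out[:, 2] = pts[:, 2] / self.z_scale + self.translation[2]
        return out

    def apply_z(self, z) -> np.ndarray:
        return self.z_scale * (np.asarray(z, dtype=float) - self.translation[2])

    def invert_z(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) / self.z_scale + self.translation[2]


def auto_control_points(
    stack: EllipseStack, jitter_sd: float = 0.0, rng=None
) -> ControlPointSet:
    """Place 6 control points on the fitted boundary of the first, center and
    last slices at parametric angles 0, 60, ..., 300 degrees (measured from
    the first principal axis), optionally jittered in-plane by an isotropic
    Gaussian of sd ``jitter_sd`` mm to emulate manual placement."""
    if len(stack) < 3:
        raise InvalidParameterError("need at least 3 slices for control points")
    if jitter_sd < 0:
        raise InvalidParameterError("jitter_sd must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mid = (len(stack) + 1) // 2 - 1
    groups = []
    for idx in (0, mid, len(stack) - 1):
        pts2 = ellipse_boundary(stack.params[idx], 6)
        if jitter_sd > 0:
            pts2 = pts2 + rng.normal(0.0, jitter_sd, size=pts2.shape)
        z = np.full((6, 1), stack.z[idx])
        groups.append(np.hstack([pts2, z]))
    return ControlPointSet(*groups)


def compute_transform(cp: ControlPointSet) -> SampleSpaceTransform:
    """Derive the sample-space transform from a control-point set."""
    allpts = cp.all_points
    translation = allpts.mean(axis=0)
    center_xy = cp.center[:, :2]
    centered = center_xy - center_xy.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    if rms < 1e-6:
        raise DegenerateControlPointsError("center-slice control points coincide")
    # dominant in-plane direction of the center group -> x-axis
    cov = centered.T @ centered
    w, V = np.linalg.eigh(cov)
    v = V[:, -1]  # principal direction
    beta = wrap_angle(float(np.arctan2(v[1], v[0])), period=np.pi)
    rot = wrap_angle(-beta, period=np.pi)
    z_span = cp.z_values[2] - cp.z_values[0]
    if z_span <= 0:
        raise DegenerateControlPointsError("first/last control slices coincide in z")
    return SampleSpaceTransform(
        translation=translation,
        scale=1.0 / rms,
        in_plane_rotation=rot,
        z_scale=1.0 / float(z_span),
    )


def to_sample_space(stack: EllipseStack, t: SampleSpaceTransform) -> EllipseStack:
    """Map a stack into the sample space (centers, axes, angles, z)."""
    theta = stack.theta
    R = rotation_matrix(t.in_plane_rotation)
    new_theta = t.scale * (theta - t.translation[:2]) @ R.T
    new_alpha = t.scale * stack.alpha
    new_phi = np.array([wrap_angle(p + t.in_plane_rotation) for p in stack.phi])
    new_z = t.apply_z(stack.z)
    return EllipseStack.from_arrays(new_z, new_theta, new_alpha, new_phi)


def from_sample_space(stack: EllipseStack, t: SampleSpaceTransform) -> EllipseStack:
    """Inverse of :func:`to_sample_space`."""
    R = rotation_matrix(-t.in_plane_rotation)
    new_theta = (stack.theta / t.scale) @ R.T + t.translation[:2]
    new_alpha = stack.alpha / t.scale
    new_phi = np.array([wrap_angle(p - t.in_plane_rotation) for p in stack.phi])
    new_z = t.invert_z(stack.z)
    return EllipseStack.from_arrays(new_z, new_theta, new_alpha, new_phi)


@dataclass(frozen=True)
class CenterCurve:
    """Component-wise quadratic in z through the three control-point group
    centroids: ``xi(z) = c0 + c1 z + c2 z^2`` for x and y independently."""

    coeffs: np.ndarray  # (3, 2): rows are c0, c1, c2; columns x, y

    def at(self, z) -> np.ndarray:
        """Evaluate the curve at slice positions z; returns (len(z), 2)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        vand = np.column_stack([np.ones_like(z), z, z * z])
        return vand @ self.coeffs


def center_curve(cp: ControlPointSet, L: int | None = None) -> CenterCurve:
    """Fit the unique quadratic through the three group centroids.

    The curve passes exactly through the centroids at the three control
    slice z positions.  ``L`` is accepted for symmetry with the canonical
    slice grid but the returned curve is continuous: evaluate it with
    :meth:`CenterCurve.at` at any slice positions.
    """
    cents = cp.centroids
    z = cents[:, 2]
    if len(np.unique(z)) != 3:
        raise DegenerateControlPointsError("duplicate z among control groups")
    vand = np.column_stack([np.ones(3), z, z * z])
    coeffs = np.linalg.solve(vand, cents[:, :2])
    return CenterCurve(coeffs=coeffs)
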