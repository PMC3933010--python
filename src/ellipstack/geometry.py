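"""Ellipse primitives: boundary generation, orthogonal projection,
geometric (orthogonal-distance) error and rasterization.

An ellipse in a slice is parametrized by ``rho = (theta, alpha, phi)``:
center ``theta`` (mm), semi-axis lengths ``alpha = (alpha1, alpha2)`` (mm)
and the rotation angle ``phi`` (radians) of the first axis relative to the
in-plane x-axis.  The boundary is

    C(rho) = { R(phi) x + theta :  x1^2/alpha1^2 + x2^2/alpha2^2 = 1 }.

Orthogonal projection of a point onto the boundary is the work-horse of the
best-fit objective: the squared distances of contour points to their nearest
boundary points are what the fitter minimizes.  The projection is computed in
the ellipse frame by the classic robust root-finding scheme on the scalar
equation

    F(t) = (alpha1 p1 / (t + alpha1^2))^2 + (alpha2 p2 / (t + alpha2^2))^2 - 1,

which is strictly decreasing on (-min(alpha)^2, inf) and has the unique root
corresponding to the global nearest point for points off the symmetry axes;
axis and center cases are handled by their closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, InsufficientDataError

__all__ = [
    "EllipseParams",
    "SliceContour",
    "EllipseStack",
    "ellipse_boundary",
    "project_point_to_ellipse",
    "project_points_to_ellipse",
    "geometric_error",
    "rasterize_ellipse",
    "GridSpec",
    "rotation_matrix",
    "implicit_value",
    "wrap_angle",
]


def rotation_matrix(phi: float) -> np.ndarray:
    """2x2 rotation matrix R(phi)."""
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def wrap_angle(phi: float, period: float = 2.0 * np.pi) -> float:
    """Wrap an angle into the half-open interval (-period/2, period/2]."""
    if -period / 2.0 < phi <= period / 2.0:
        return float(phi)  # already in range: keep exactly
    out = -((-phi + period / 2.0) % period) + period / 2.0
    # the modulo maps the left endpoint onto itself; push it to the right one
    if out <= -period / 2.0:
        out += period
    return out


@dataclass(frozen=True)
class EllipseParams:
    """One slice's ellipse rho = (theta, alpha, phi).

    theta : (2,) center in mm; alpha : (2,) strictly positive semi-axis
    lengths in mm; phi : rotation of the first axis, radians.
    """

    theta: np.ndarray
    alpha: np.ndarray
    phi: float

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float).reshape(2)
        alpha = np.asarray(self.alpha, dtype=float).reshape(2)
        phi = float(self.phi)
        if not np.all(np.isfinite(theta)):
            raise InvalidParameterError(f"non-finite center {theta}")
        if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
            raise InvalidParameterError(f"semi-axes must be positive, got {alpha}")
        if not np.isfinite(phi):
            raise InvalidParameterError("rotation angle must be finite")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "phi", phi)

    def as_vector(self) -> np.ndarray:
        """(theta1, theta2, alpha1, alpha2, phi) as a flat array."""
        return np.array([*self.theta, *self.alpha, self.phi])

    @classmethod
    def from_vector(cls, v) -> "EllipseParams":
        v = np.asarray(v, dtype=float).reshape(5)
        return cls(theta=v[:2], alpha=v[2:4], phi=v[4])


@dataclass(frozen=True)
class SliceContour:
    """A closed planar contour at slice position ``z`` (mm).

    ``points`` is an ordered (K, 2) array of vertices in mm; the polyline is
    closed implicitly (last vertex connects back to the first).
    """

    z: float
    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("contour points must be (K, 2)")
        if not np.all(np.isfinite(pts)):
            raise InvalidParameterError("contour points must be finite")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "z", float(self.z))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class EllipseStack:
    """Ordered per-slice ellipses with strictly increasing z positions."""

    z: np.ndarray
    params: list  # list[EllipseParams], same length as z

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float).reshape(-1)
        if len(z) != len(self.params):
            raise InvalidParameterError("z and params lengths differ")
        if len(z) >= 2 and not np.all(np.diff(z) > 0):
            raise InvalidParameterError("slice positions must be strictly increasing")
        self.z = z

    def __len__(self) -> int:
        return len(self.z)

    def __iter__(self):
        return iter(zip(self.z, self.params))

    # columnar views used throughout training and deformation
    @property
    def theta(self) -> np.ndarray:
        return np.array([p.theta for p in self.params])

    @property
    def alpha(self) -> np.ndarray:
        return np.array([p.alpha for p in self.params])

    @property
    def phi(self) -> np.ndarray:
        return np.array([p.phi for p in self.params])

    @classmethod
    def from_arrays(cls, z, theta, alpha, phi) -> "EllipseStack":
        z = np.asarray(z, dtype=float)
        params = [
            EllipseParams(theta=theta[i], alpha=alpha[i], phi=float(phi[i]))
            for i in range(len(z))
        ]
        return cls(z=z, params=params)

    def copy(self) -> "EllipseStack":
        return EllipseStack(z=self.z.copy(), params=list(self.params))


@dataclass(frozen=True)
class GridSpec:
    """In-plane pixel grid: ``origin`` is the center of pixel (0, 0) in mm,
    ``spacing`` the pixel pitch in mm, ``shape`` the (ny, nx) pixel counts.

    Pixel (iy, ix) has its center at ``origin + spacing * (ix, iy)``.
    """

    origin: tuple
    spacing: tuple
    shape: tuple

    def __post_init__(self):
        if min(self.spacing) <= 0:
            raise InvalidParameterError("grid spacing must be positive")

    def pixel_centers(self):
        """Return (X, Y) arrays of pixel-center coordinates, shape ``shape``."""
        ny, nx = self.shape
        x = self.origin[0] + self.spacing[0] * np.arange(nx)
        y = self.origin[1] + self.spacing[1] * np.arange(ny)
        return np.meshgrid(x, y)

    @property
    def pixel_area(self) -> float:
        return float(self.spacing[0] * self.spacing[1])


def ellipse_boundary(params: EllipseParams, n_points: int) -> np.ndarray:
    """Sample ``n_points`` boundary points at uniform parametric angles.

    The k-th point is ``R(phi) (a1 cos t_k, a2 sin t_k) + theta`` with
    ``t_k = 2 pi k / n``.
    """
    n_points = int(n_points)
    if n_points < 3:
        raise InvalidParameterError("need at least 3 boundary points")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    local = np.column_stack([params.alpha[0] * np.cos(t), params.alpha[1] * np.sin(t)])
    return local @ rotation_matrix(params.phi).T + params.theta


def _to_ellipse_frame(params: EllipseParams, pts: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(pts) - params.theta) @ rotation_matrix(params.phi)


def implicit_value(params: EllipseParams, pts) -> np.ndarray:
    """Evaluate x1'^2/a1^2 + x2'^2/a2^2 in the ellipse frame (1 on the boundary)."""
    local = _to_ellipse_frame(params, np.asarray(pts, dtype=float))
    return (local[:, 0] / params.alpha[0]) ** 2 + (local[:, 1] / params.alpha[1]) ** 2


def _project_quadrant(e0: float, e1: float, y0: np.ndarray, y1: np.ndarray):
    """Nearest boundary point for points with e0 >= e1 and y0, y1 >= 0.

    Vectorized bisection on the monotone scalar equation; closed forms on the
    symmetry axes.  Returns (x0, x1) feet.
    """
    x0 = np.empty_like(y0)
    x1 = np.empty_like(y1)

    # snap vanishing components onto the symmetry axes: their closed forms
    # are exact there, and sub-1e-14 offsets underflow the bracket arithmetic
    eps = 1e-14 * e0
    y0 = np.where(y0 < eps, 0.0, y0)
    y1 = np.where(y1 < eps, 0.0, y1)

    gen = (y0 > 0) & (y1 > 0)
    if np.any(gen):
        g0, g1 = y0[gen], y1[gen]
        # Bracket of the root of F(t); F(t0) >= 0 >= F(t1).
        t0 = e1 * g1 - e1 * e1
        t1 = np.sqrt((e0 * g0) ** 2 + (e1 * g1) ** 2) - e1 * e1
        # ~100 halvings drive the bracket below machine precision
        for _ in range(104):
            tm = 0.5 * (t0 + t1)
            f = (e0 * g0 / (tm + e0 * e0)) ** 2 + (e1 * g1 / (tm + e1 * e1)) ** 2 - 1.0
            take = f > 0
            t0 = np.where(take, tm, t0)
            t1 = np.where(take, t1, tm)
        t = 0.5 * (t0 + t1)
        x0[gen] = e0 * e0 * g0 / (t + e0 * e0)
        x1[gen] = e1 * e1 * g1 / (t + e1 * e1)

    ax1 = (y1 == 0)  # on the major axis (or center)
    if np.any(ax1):
        g0 = y0[ax1]
        if e0 > e1:
            crit = (e0 * e0 - e1 * e1) / e0
            inner = g0 < crit
            f0 = np.where(inner, e0 * e0 * g0 / (e0 * e0 - e1 * e1), e0)
            f1 = np.where(inner, e1 * np.sqrt(np.clip(1.0 - (f0 / e0) ** 2, 0.0, None)), 0.0)
        else:  # circle: radial projection; center handled by caller convention
            r = np.where(g0 > 0, g0, 1.0)
            f0 = e0 * np.where(g0 > 0, g0 / r, 1.0)
            f1 = np.zeros_like(g0)
        x0[ax1], x1[ax1] = f0, f1
    ax0 = (y0 == 0) & (y1 > 0)  # on the minor axis: endpoint is nearest
    if np.any(ax0):
        x0[ax0] = 0.0
        x1[ax0] = e1
    return x0, x1


def project_points_to_ellipse(params: EllipseParams, points) -> tuple:
    """Orthogonally project points onto the ellipse boundary.

    Returns ``(feet, distances)``: feet (K, 2) on the boundary, distances (K,)
    Euclidean.  A point at the center of a circular ellipse deterministically
    projects to the first-axis endpoint.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise InvalidParameterError("query points must be finite")
    local = _to_ellipse_frame(params, pts)
    a = params.alpha
    s0 = np.where(local[:, 0] < 0, -1.0, 1.0)
    s1 = np.where(local[:, 1] < 0, -1.0, 1.0)
    y0, y1 = np.abs(local[:, 0]), np.abs(local[:, 1])
    swap = a[1] > a[0]
    if swap:
        y0, y1 = y1, y0
        e0, e1 = a[1], a[0]
    else:
        e0, e1 = a[0], a[1]
    x0, x1 = _project_quadrant(float(e0), float(e1), y0, y1)
    if swap:
        x0, x1 = x1, x0
    feet_local = np.column_stack([s0 * x0, s1 * x1])
    dist = np.hypot(local[:, 0] - feet_local[:, 0], local[:, 1] - feet_local[:, 1])
    feet = feet_local @ rotation_matrix(params.phi).T + params.theta
    return feet, dist


def project_point_to_ellipse(params: EllipseParams, point) -> tuple:
    """Single-point convenience wrapper; returns (foot (2,), distance)."""
    feet, dist = project_points_to_ellipse(params, np.asarray(point).reshape(1, 2))
    return feet[0], float(dist[0])


def geometric_error(params: EllipseParams, contour: SliceContour) -> float:
    """Sum of squared orthogonal distances of contour points to the ellipse."""
    _, dist = project_points_to_ellipse(params, contour.points)
    return float(np.sum(dist**2))


def rasterize_ellipse(params: EllipseParams, grid: GridSpec) -> np.ndarray:
    """Binary mask of pixels whose centers lie inside (or on) the ellipse."""
    X, Y = grid.pixel_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    vals = implicit_value(params, pts)
    return (vals <= 1.0).reshape(grid.shape)
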