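"""Best-fitting ellipse (BFE) per contour slice.

The fit minimizes the *geometric* objective: the sum of squared orthogonal
distances of the contour points to the ellipse boundary,

    g(rho) = sum_k || x_k - c_k(rho) ||^2,

where c_k is the nearest boundary point of x_k.  This is the orthogonal
distance (total least squares) formulation rather than the algebraic one, so
the solution does not depend on the conic normalization and is equivariant
under rigid motions of the data.

Strategy: a direct algebraic least-squares conic fit constrained to ellipses
(the standard numerically-stable scatter-matrix scheme) supplies the
initializer; Levenberg-Marquardt on the geometric residuals refines it.  The
length parameters are optimized as log(alpha) so positivity is structural.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateContourError, InsufficientDataError, StackFitError
from .geometry import (
    EllipseParams,
    EllipseStack,
    SliceContour,
    project_points_to_ellipse,
    wrap_angle,
)

__all__ = ["fit_ellipse", "algebraic_fit", "fit_stack"]


def algebraic_fit(points: np.ndarray) -> EllipseParams:
    """Direct least-squares conic fit constrained to ellipses.

    Solves the generalized eigenproblem of the ellipse-specific scatter
    matrix (Halir & Flusser's numerically stable formulation of the direct
    ellipse-fit) and converts the conic to center/axes/angle form.
    Raises :class:`DegenerateContourError` when the points admit no ellipse.
    """
    pts = np.asarray(points, dtype=float)
    # center & scale for conditioning
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale < 1e-12:
        raise DegenerateContourError("contour points are (nearly) coincident")
    q = (pts - mean) / scale
    x, y = q[:, 0], q[:, 1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateContourError(f"degenerate contour: {exc}") from exc
    M = S1 + S2 @ T
    # constraint matrix inverse applied by row shuffle: C^{-1} M
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    # ellipse condition: 4ac - b^2 > 0
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (cond > 0)
    if not np.any(ok):
        raise DegenerateContourError("no elliptical solution for the contour")
    a1 = np.real(evecs[:, ok][:, 0])
    conic = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in scaled frame
    return _conic_to_params(conic, mean, scale)


def _conic_to_params(conic: np.ndarray, mean: np.ndarray, scale: float) -> EllipseParams:
    A, B, C, D, E, F = conic
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        raise DegenerateContourError("conic is not an ellipse")
    # center in scaled frame
    cx = (2.0 * C * D - B * E) / disc
    cy = (2.0 * A * E - B * D) / disc
    # evaluate the form at the center to normalize
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    M = np.array([[A, B / 2.0], [B / 2.0, C]]) / (-Fc)
    w, V = np.linalg.eigh(M)
    if np.any(w <= 0):
        raise DegenerateContourError("conic is not an ellipse")
    axes = 1.0 / np.sqrt(w)  # eigh ascending -> axes descending
    # label the first axis by the direction of the first eigenvector
    phi = float(np.arctan2(V[1, 0], V[0, 0]))
    phi = wrap_angle(phi, period=np.pi)
    return EllipseParams(
        theta=mean + scale * np.array([cx, cy]),
        alpha=scale * axes,
        phi=phi,
    )


def _residuals(vec: np.ndarray, pts: np.ndarray) -> np.ndarray:
    params = EllipseParams(theta=vec[:2], alpha=np.exp(vec[2:4]), phi=vec[4])
    _, dist = project_points_to_ellipse(params, pts)
    return dist


def fit_ellipse(contour: SliceContour, max_iter: int = 200) -> EllipseParams:
    """Fit the best-fitting ellipse to one closed contour.

    Requires >= 5 non-collinear points.  Returns parameters with
    ``phi`` normalized to (-pi/2, pi/2] and ``alpha1`` labeled as the axis
    along ``phi`` (no magnitude ordering is imposed; relabeling across
    slices is the correspondence step's job).
    """
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 5:
        raise InsufficientDataError(
            f"need at least 5 contour points to fit an ellipse, got {len(pts)}"
        )
    # collinearity check via the centered covariance spectrum
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-10 * max(sv[0], 1.0):
        raise DegenerateContourError("contour points are collinear")

    init = algebraic_fit(pts)
    x0 = np.array([*init.theta, *np.log(init.alpha), init.phi])
    sol = least_squares(
        _residuals,
        x0,
        args=(pts,),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-12,
        max_nfev=max_iter * 6,
    )
    if not sol.success:  # pragma: no cover - LM on benign contours converges
        warnings.warn("ellipse refinement did not converge; returning best iterate")
    best = sol.x if sol.cost <= 0.5 * np.sum(_residuals(x0, pts) ** 2) else x0
    phi = wrap_angle(float(best[4]), period=np.pi)
    return EllipseParams(theta=best[:2], alpha=np.exp(best[2:4]), phi=phi)


def fit_stack(contours: list) -> EllipseStack:
    """Fit every slice of a case; failing slices are reported, never dropped.

    ``contours`` must be sorted by z.  Raises :class:`StackFitError` naming
    each failing slice if any slice cannot be fitted.
    """
    if len(contours) == 0:
        raise InsufficientDataError("no contours to fit")
    z = np.array([c.z for c in contours], dtype=float)
    if len(z) >= 2 and not np.all(np.diff(z) > 0):
        raise InsufficientDataError("contours must be sorted by strictly increasing z")
    params, failures = [], []
    for i, c in enumerate(contours):
        try:
            params.append(fit_ellipse(c))
        except (InsufficientDataError, DegenerateContourError) as exc:
            failures.append((i, c.z, exc))
    if failures:
        raise StackFitError(failures)
    return EllipseStack(z=z, params=params)
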