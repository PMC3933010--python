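"""Parameter correspondence across slices: axis reordering, circularity
relaxation, rotation smoothing and resampling to a common slice count.

A fitted ellipse admits four equivalent (axis-label, angle) representations:
``(a1, a2, phi)``, ``(a1, a2, phi + pi)`` and the swapped ``(a2, a1,
phi +/- pi/2)``.  Statistics over slices and cases are only meaningful when
the labeling is consistent, so the reordering pass walks outward from the
center slice and picks, per slice, the representation whose angle is closest
to the already-reordered neighbor.  Two constraints then improve the angle
sequence: near-circular slices (where orientation is ill-determined) have
their angle blended toward the neighbors', and a moving average removes
residual back-and-forth rotation between adjacent slices.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import InvalidParameterError
from .geometry import EllipseParams, EllipseStack, wrap_angle

__all__ = [
    "reorder_axes",
    "relax_circular",
    "smooth_rotation",
    "resample_stack",
    "interpolate_stack",
    "unwrap_angles",
]


def unwrap_angles(phi, period: float = np.pi) -> np.ndarray:
    """Cumulatively unwrap an angle sequence resolving jumps toward minimal
    successive difference (default period pi, the symmetry of an unlabeled
    ellipse orientation)."""
    phi = np.asarray(phi, dtype=float)
    if len(phi) < 2:
        return phi.copy()
    return np.unwrap(phi, period=period)


def _representations(alpha: np.ndarray, phi: float):
    """The four equivalent (alpha, angle-class) representations of a slice.

    Each angle is a representative of its class mod 2*pi; callers additionally
    consider +/- 2*pi shifts when matching a reference angle.
    """
    a_swap = alpha[::-1]
    return [
        (alpha, phi),
        (alpha, phi + np.pi),
        (a_swap, phi + np.pi / 2.0),
        (a_swap, phi - np.pi / 2.0),
    ]


def _closest_representation(alpha: np.ndarray, phi: float, ref: float):
    """Representation minimizing |angle - ref| over the four classes and
    their 2*pi shifts."""
    best = None
    for a, p in _representations(alpha, phi):
        # shift p by multiples of 2*pi toward ref
        p_adj = p + 2.0 * np.pi * np.round((ref - p) / (2.0 * np.pi))
        d = abs(p_adj - ref)
        if best is None or d < best[0]:
            best = (d, a, p_adj)
    return best[1], best[2]


def reorder_axes(stack: EllipseStack) -> EllipseStack:
    """Relabel axes/angles outward from the center slice for correspondence.

    The center slice M = ceil(L/2) (1-based) is the basis and is unchanged;
    every other slice takes the representation closest in angle to its
    already-processed neighbor.  Boundaries are point-wise unchanged; the
    final angles are wrapped to (-pi, pi].
    """
    L = len(stack)
    if L < 2:
        return stack.copy()
    mid = (L + 1) // 2 - 1  # 0-based index of ceil(L/2)
    alpha = stack.alpha.copy()
    phi = stack.phi.astype(float).copy()
    out_alpha = alpha.copy()
    out_phi = phi.copy()
    for i in range(mid + 1, L):
        out_alpha[i], out_phi[i] = _closest_representation(
            alpha[i], phi[i], out_phi[i - 1]
        )
    for i in range(mid - 1, -1, -1):
        out_alpha[i], out_phi[i] = _closest_representation(
            alpha[i], phi[i], out_phi[i + 1]
        )
    out_phi = np.array([wrap_angle(p) for p in out_phi])
    return EllipseStack.from_arrays(stack.z, stack.theta, out_alpha, out_phi)


def relax_circular(stack: EllipseStack, circ_threshold: float = 0.95) -> EllipseStack:
    """Blend the angle of near-circular slices toward the neighbors' angles.

    For a slice with circularity ``c = min(alpha)/max(alpha) > threshold``
    the angle becomes ``(1 - w) phi + w phi_nb`` with weight
    ``w = (c - threshold)/(1 - threshold)`` and ``phi_nb`` the mean of the
    adjacent slices' (input) angles.  A perfectly circular slice thus takes
    its neighbors' mean angle; slices below the threshold are unchanged.
    """
    if not (0.0 < circ_threshold < 1.0):
        raise InvalidParameterError("circ_threshold must be in (0, 1)")
    L = len(stack)
    if L < 2:
        return stack.copy()
    alpha = stack.alpha
    phi_u = unwrap_angles(stack.phi)
    out_phi = phi_u.copy()
    for i in range(L):
        c = float(np.min(alpha[i]) / np.max(alpha[i]))
        if c <= circ_threshold:
            continue
        nb = [phi_u[j] for j in (i - 1, i + 1) if 0 <= j < L]
        phi_nb = float(np.mean(nb))
        w = (c - circ_threshold) / (1.0 - circ_threshold)
        out_phi[i] = (1.0 - w) * phi_u[i] + w * phi_nb
    out_phi = np.array([wrap_angle(p) for p in out_phi])
    return EllipseStack.from_arrays(stack.z, stack.theta, alpha, out_phi)


def smooth_rotation(stack: EllipseStack, window: int = 3) -> EllipseStack:
    """Centered moving average of the unwrapped angle sequence.

    The window is clipped at the stack ends (end slices average over the
    available part of the window).  Centers and axis lengths are untouched;
    the total variation of the angle sequence never increases.
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be a positive odd integer")
    L = len(stack)
    phi_u = unwrap_angles(stack.phi)
    half = window // 2
    out_phi = np.empty(L)
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        out_phi[i] = float(np.mean(phi_u[lo:hi]))
    out_phi = np.array([wrap_angle(p) for p in out_phi])
    return EllipseStack.from_arrays(stack.z, stack.theta, stack.alpha, out_phi)


def interpolate_stack(stack: EllipseStack, t_new) -> EllipseStack:
    """Interpolate a stack at arbitrary normalized positions ``t_new``.

    ``t`` is the normalized slice position (z - z0)/(z1 - z0) of the input;
    each parameter is an independent 1-D spline in t (cubic when >= 4 input
    slices, else degraded).  Used by :func:`resample_stack` (uniform grid)
    and by deformation (case slice grid)."""
    n = len(stack)
    if n < 2:
        raise InvalidParameterError("need at least 2 slices to interpolate")
    t_new = np.asarray(t_new, dtype=float).reshape(-1)
    z = stack.z
    t = (z - z[0]) / (z[-1] - z[0])
    cols = np.column_stack([stack.theta, stack.alpha, unwrap_angles(stack.phi)])
    spl = make_interp_spline(t, cols, k=min(3, n - 1))
    new = np.asarray(spl(t_new))
    alpha = new[:, 2:4]
    if np.any(alpha < 1e-6):
        warnings.warn("interpolated axis length fell below 1e-6 mm; flooring")
        alpha = np.maximum(alpha, 1e-6)
    z_new = z[0] + t_new * (z[-1] - z[0])
    return EllipseStack.from_arrays(z_new, new[:, :2], alpha, new[:, 4])


def resample_stack(stack: EllipseStack, L: int) -> EllipseStack:
    """Resample a stack to ``L`` slices by independent cubic interpolation.

    Each parameter (theta1, theta2, alpha1, alpha2, unwrapped phi) is
    interpolated as a 1-D function of the normalized slice position
    ``t = (z - z0)/(z1 - z0) in [0, 1]``; output slices sit at
    ``t = 0, 1/(L-1), ..., 1``.  Original knots reproduce original values
    exactly.  Below 4 input slices the spline degree degrades gracefully
    (quadratic / linear).  Interpolated axis lengths are floored at 1e-6 mm
    with a warning.
    """
    L = int(L)
    if L < 3:
        raise InvalidParameterError("target slice count L must be >= 3")
    return interpolate_stack(stack, np.linspace(0.0, 1.0, L))
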