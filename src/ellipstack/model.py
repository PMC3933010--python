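"""Statistical shape model over stacked ellipses.

:class:`StackedEllipseModel` holds a training population (per-case ellipse
stacks and their control points) and :meth:`~StackedEllipseModel.fit`
normalizes every case into the common sample space, resamples it to ``L``
canonical slices and estimates per-slice moments, returning a
:class:`ShapeModelResults`.

Per canonical slice ``l`` the model stores, over the N training cases:

* ``mu_eta, sigma_eta`` -- mean/sd of the center offset
  ``eta^l = theta^l - xi^l`` from the control-point center curve xi
  (the default position parametrization: the mean shape stays closest to
  the control points);
* ``mu_theta, sigma_theta, Sigma_theta`` -- absolute-center statistics
  (3-vectors including the canonical z), retained for the absolute mode;
* ``mu_a, sigma_a`` with ``a = log(alpha)`` -- the axis lengths are
  log-normal, so their prior mean is a geometric mean and positivity is
  structural;
* ``mu_phi, sigma_phi`` -- linear (non-circular) moments of the unwrapped
  rotation angle; the angle variance is small after de-rotation, so a
  circular distribution is unnecessary.

Variances use the unbiased 1/(N-1) normalization.  The prior for a new case
factorizes per slice and per parameter: eta and phi Gaussian, alpha
log-normal.  The results object also produces the method's primary output:
the mean shape deformed into a new patient from that patient's 18 control
points (:meth:`ShapeModelResults.deform`), optionally refined against the
image by MCMC (:meth:`ShapeModelResults.predict`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correspondence as corr
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    MissingInputError,
    ShapeMismatchError,
)
from .fitting import fit_stack
from .geometry import EllipseStack, wrap_angle
from .registration import (
    CenterCurve,
    ControlPointSet,
    SampleSpaceTransform,
    auto_control_points,
    center_curve,
    compute_transform,
    from_sample_space,
    to_sample_space,
)

__all__ = ["StackedEllipseModel", "ShapeModelResults", "CasePrediction", "train"]

_SCHEMA_VERSION = 1


def _canonical_phi(phi: np.ndarray) -> np.ndarray:
    """Unwrap an angle sequence (period pi) and shift it by a multiple of pi
    so the center slice's angle lies in (-pi/2, pi/2].  Makes angle sequences
    comparable across cases."""
    phi_u = corr.unwrap_angles(phi)
    mid = (len(phi_u) + 1) // 2 - 1
    shift = wrap_angle(phi_u[mid], period=np.pi) - phi_u[mid]
    return phi_u + shift


def _normal_logpdf(x, mu, sigma):
    """Element-wise Gaussian log density with a point-mass convention for
    sigma == 0: contributes 0 where x == mu (within 1e-9) and -inf
    otherwise, never NaN."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    out = np.full(np.broadcast(x, mu, sigma).shape, -np.inf)
    pos = sigma > 0
    sig = np.where(pos, sigma, 1.0)
    vals = -0.5 * np.log(2.0 * np.pi * sig**2) - 0.5 * ((x - mu) / sig) ** 2
    out = np.where(pos, vals, out)
    zero_ok = (~pos) & (np.abs(x - mu) <= 1e-9)
    out = np.where(zero_ok, 0.0, out)
    return out


def _pmean(x: np.ndarray) -> np.ndarray:
    """Mean over the case axis with a canonical (sorted) summation order, so
    the estimate is bit-identical under any permutation of the cases."""
    return np.sort(x, axis=0).sum(axis=0) / x.shape[0]


def _psum_sorted(x: np.ndarray) -> np.ndarray:
    return np.sort(x, axis=0).sum(axis=0)


def train(
    stacks: list,
    curves: list,
    L: int,
    position_mode: str = "eta",
) -> "ShapeModelResults":
    """Estimate per-slice moments from sample-space stacks.

    ``stacks`` must all have ``L`` slices (already resampled); ``curves``
    are the matching sample-space center curves (one per case).  The
    estimator is deterministic and permutation-invariant over cases.
    """
    N = len(stacks)
    if N < 2:
        raise InsufficientDataError("variance undefined: need at least 2 cases")
    if len(curves) != N:
        raise ShapeMismatchError("one center curve per training stack required")
    if position_mode not in ("eta", "theta"):
        raise InvalidParameterError("position_mode must be 'eta' or 'theta'")
    for s in stacks:
        if len(s) != L:
            raise ShapeMismatchError(
                f"stack has {len(s)} slices, expected L={L}; resample first"
            )
    theta = np.array([s.theta for s in stacks])  # (N, L, 2)
    zpos = np.array([s.z for s in stacks])  # (N, L)
    alpha = np.array([s.alpha for s in stacks])
    phi = np.array([_canonical_phi(s.phi) for s in stacks])
    xi = np.array([curves[n].at(zpos[n]) for n in range(N)])  # (N, L, 2)
    eta = theta - xi
    a = np.log(alpha)
    theta3 = np.concatenate([theta, zpos[..., None]], axis=2)  # (N, L, 3)

    def moments(x):
        mu = _pmean(x)
        var = _psum_sorted((x - mu) ** 2) / (N - 1)
        return mu, np.sqrt(var)

    mu_eta, sigma_eta = moments(eta)
    mu_a, sigma_a = moments(a)
    mu_phi, sigma_phi = moments(phi)
    mu_theta, sigma_theta = moments(theta3)

    dev = theta3 - mu_theta  # (N, L, 3)
    Sigma_theta = np.empty((L, 3, 3))
    for i in range(3):
        for j in range(3):
            Sigma_theta[:, i, j] = _psum_sorted(dev[:, :, i] * dev[:, :, j]) / (N - 1)

    return ShapeModelResults(
        L=L,
        n_train=N,
        position_mode=position_mode,
        t_grid=np.linspace(0.0, 1.0, L),
        mu_eta=mu_eta,
        sigma_eta=sigma_eta,
        mu_theta=mu_theta,
        sigma_theta=sigma_theta,
        Sigma_theta=Sigma_theta,
        mu_a=mu_a,
        sigma_a=sigma_a,
        mu_phi=mu_phi,
        sigma_phi=sigma_phi,
    )


class StackedEllipseModel:
    """Training-population container for the stacked-ellipse shape model.

    Parameters
    ----------
    stacks : list of EllipseStack
        Fitted per-case ellipse stacks in the (de-rotated) patient frame.
    control_points : list of ControlPointSet
        Matching control points (6 boundary points on each of the first,
        center and last contour slice of every case).
    L : int
        Canonical slice count the population is resampled to.
    position_mode : {"eta", "theta"}
        Whether centers are modeled as offsets from the control-point
        center curve (default) or as absolute positions.
    circ_threshold, smooth_window
        Correspondence constraints: circularity ratio above which the
        rotation angle is blended toward the neighbors', and the moving
        average window for the angle sequence.
    """

    def __init__(
        self,
        stacks: list,
        control_points: list,
        L: int = 11,
        position_mode: str = "eta",
        circ_threshold: float = 0.95,
        smooth_window: int = 3,
    ):
        if len(stacks) != len(control_points):
            raise ShapeMismatchError("stacks and control_points lengths differ")
        self.stacks = list(stacks)
        self.control_points = list(control_points)
        self.L = int(L)
        self.position_mode = position_mode
        self.circ_threshold = float(circ_threshold)
        self.smooth_window = int(smooth_window)

    @classmethod
    def from_contours(
        cls,
        contour_cases: list,
        control_points: list | None = None,
        cp_jitter_sd: float = 0.0,
        rng=None,
        **kwargs,
    ) -> "StackedEllipseModel":
        """Build the model from raw per-case contour lists.

        Every case's contours are fitted slice-by-slice; when
        ``control_points`` is None, control points are placed automatically
        on the fitted first/center/last slices (optionally jittered)."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        stacks = [fit_stack(contours) for contours in contour_cases]
        if control_points is None:
            control_points = [
                auto_control_points(s, jitter_sd=cp_jitter_sd, rng=rng) for s in stacks
            ]
        return cls(stacks, control_points, **kwargs)

    def _normalize_case(self, stack: EllipseStack, cp: ControlPointSet):
        """Correspondence + registration for one case; returns the resampled
        sample-space stack and its sample-space center curve."""
        s = corr.reorder_axes(stack)
        s = corr.relax_circular(s, self.circ_threshold)
        s = corr.smooth_rotation(s, self.smooth_window)
        t = compute_transform(cp)
        s = to_sample_space(s, t)
        s = corr.resample_stack(s, self.L)
        cp_s = cp.transformed(t.apply_points)
        return s, center_curve(cp_s)

    def fit(self) -> "ShapeModelResults":
        """Normalize every training case and estimate the shape statistics."""
        norm = [
            self._normalize_case(s, cp)
            for s, cp in zip(self.stacks, self.control_points)
        ]
        stacks = [s for s, _ in norm]
        curves = [c for _, c in norm]
        res = train(stacks, curves, self.L, self.position_mode)
        res.model = self
        return res


@dataclass
class CasePrediction:
    """Output of :meth:`ShapeModelResults.predict`: the delineation stack,
    optional per-slice masks on the volume grid, and MCMC diagnostics."""

    stack: EllipseStack
    masks: np.ndarray | None = None
    diagnostics: dict | None = None


@dataclass
class ShapeModelResults:
    """Per-slice shape statistics; see the module docstring for fields."""

    L: int
    n_train: int
    position_mode: str
    t_grid: np.ndarray
    mu_eta: np.ndarray
    sigma_eta: np.ndarray
    mu_theta: np.ndarray
    sigma_theta: np.ndarray
    Sigma_theta: np.ndarray
    mu_a: np.ndarray
    sigma_a: np.ndarray
    mu_phi: np.ndarray
    sigma_phi: np.ndarray
    model: "StackedEllipseModel | None" = field(default=None, repr=False)

    def __post_init__(self):
        for name in (
            "t_grid",
            "mu_eta",
            "sigma_eta",
            "mu_theta",
            "sigma_theta",
            "Sigma_theta",
            "mu_a",
            "sigma_a",
            "mu_phi",
            "sigma_phi",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.sigma_eta < 0) or np.any(self.sigma_a < 0) or np.any(
            self.sigma_phi < 0
        ):
            raise InvalidParameterError("standard deviations must be >= 0")

    # ------------------------------------------------------------------ #
    # mean shape, prior sampling and prior density
    # ------------------------------------------------------------------ #
    def mean_shape(self, curve: CenterCurve | None = None, z=None) -> EllipseStack:
        """The mean best-fitting ellipses (MBFE) in the sample space.

        Without a center curve the slice centers are the raw mean offsets
        ``mu_eta`` (or ``mu_theta`` in absolute mode); with a curve they are
        ``xi(z) + mu_eta``.  ``z`` defaults to the canonical grid."""
        z = self.t_grid if z is None else np.asarray(z, dtype=float)
        if len(z) != self.L:
            raise ShapeMismatchError("z grid length must equal L")
        if self.position_mode == "eta":
            theta = self.mu_eta.copy()
        else:
            theta = self.mu_theta[:, :2].copy()
        if curve is not None:
            theta = theta + curve.at(z) if self.position_mode == "eta" else theta
        return EllipseStack.from_arrays(z, theta, np.exp(self.mu_a), self.mu_phi)

    def sample(self, rng=None, curve: CenterCurve | None = None) -> EllipseStack:
        """Draw one stack from the prior (independent per slice/parameter:
        Gaussian eta and phi, log-normal alpha); reproducible given a seed."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        if self.position_mode == "eta":
            pos = rng.normal(self.mu_eta, self.sigma_eta)
        else:
            pos = rng.normal(self.mu_theta[:, :2], self.sigma_theta[:, :2])
        a = rng.normal(self.mu_a, self.sigma_a)
        phi = rng.normal(self.mu_phi, self.sigma_phi)
        z = self.t_grid
        if curve is not None and self.position_mode == "eta":
            pos = pos + curve.at(z)
        return EllipseStack.from_arrays(z, pos, np.exp(a), phi)

    # alias matching the sampling-prior vocabulary
    sample_prior = sample

    def prior_logdensity(
        self,
        stack,
        curve: CenterCurve | None = None,
        center_stack: EllipseStack | None = None,
    ) -> float:
        """Log prior density of a stack (sum over slices and parameters).

        ``stack`` may be an :class:`EllipseStack` or an (L, 5) array of
        ``(theta1, theta2, alpha1, alpha2, phi)`` rows; non-positive alpha
        values are outside the log-normal support and yield ``-inf``.
        ``center_stack`` re-centers the prior means on another stack (used
        by the MCMC refinement, which centers the prior on the deformed
        template); the variances always come from the trained model."""
        if isinstance(stack, EllipseStack):
            theta, alpha, phi, z = stack.theta, stack.alpha, stack.phi, stack.z
        else:
            arr = np.asarray(stack, dtype=float)
            theta, alpha, phi, z = arr[:, :2], arr[:, 2:4], arr[:, 4], self.t_grid
        if len(phi) != self.L:
            raise ShapeMismatchError("stack length must equal L")
        if np.any(alpha <= 0):
            return float("-inf")
        a = np.log(alpha)

        if center_stack is not None:
            mu_pos = center_stack.theta
            mu_a = np.log(center_stack.alpha)
            mu_phi = center_stack.phi
        else:
            mu_a = self.mu_a
            mu_phi = self.mu_phi
            if self.position_mode == "eta":
                mu_pos = self.mu_eta + (curve.at(z) if curve is not None else 0.0)
            else:
                mu_pos = self.mu_theta[:, :2]

        sig_pos = self.sigma_eta if self.position_mode == "eta" else self.sigma_theta[:, :2]
        total = 0.0
        total += float(np.sum(_normal_logpdf(theta, mu_pos, sig_pos)))
        # log-normal density of alpha: normal in a = log alpha with Jacobian
        total += float(np.sum(_normal_logpdf(a, mu_a, self.sigma_a) - a))
        dphi = phi - mu_phi
        dphi = dphi - np.pi * np.round(dphi / np.pi)  # nearest pi-equivalent
        total += float(np.sum(_normal_logpdf(dphi, 0.0, self.sigma_phi)))
        return total

    # ------------------------------------------------------------------ #
    # deformation into a new case (the method's primary output)
    # ------------------------------------------------------------------ #
    def deform(self, cp: ControlPointSet, slice_z) -> EllipseStack:
        """Deform the mean shape into a new case from its control points.

        Deterministic: compute the control-point transform and center
        curve, resample the sample-space mean shape to the case slices
        spanned (inclusively) by the first..last control slices, set
        centers to ``xi + mu_eta`` and map back to the patient frame.
        """
        slice_z = np.sort(np.asarray(slice_z, dtype=float).reshape(-1))
        t = compute_transform(cp)
        zf, zl = cp.z_values[0], cp.z_values[2]
        tol = 1e-6
        sel = (slice_z >= zf - tol) & (slice_z <= zl + tol)
        zs = slice_z[sel]
        if len(zs) < 3:
            raise InsufficientDataError(
                f"control points span {len(zs)} case slices; need at least 3"
            )
        mean_stack = self.mean_shape()  # centers are mu_eta offsets
        t_new = (zs - zs[0]) / (zs[-1] - zs[0])
        resampled = corr.interpolate_stack(mean_stack, t_new)
        cp_s = cp.transformed(t.apply_points)
        curve_s = center_curve(cp_s)
        z_s = t.apply_z(zs)
        theta_s = curve_s.at(z_s) + resampled.theta
        stack_s = EllipseStack.from_arrays(z_s, theta_s, resampled.alpha, resampled.phi)
        return from_sample_space(stack_s, t)

    def predict(
        self,
        cp: ControlPointSet,
        slice_z=None,
        volume=None,
        refine: bool = False,
        mcmc_config=None,
        rasterize: bool = False,
    ) -> CasePrediction:
        """One-call orchestration: deform, optionally MCMC-refine against the
        image, optionally rasterize per-slice masks on the volume grid."""
        if refine and volume is None:
            raise MissingInputError("refinement requested but no volume given")
        if slice_z is None:
            if volume is None:
                raise MissingInputError("need slice_z or a volume for the slice grid")
            slice_z = volume.slice_positions
        stack = self.deform(cp, slice_z)
        diagnostics = None
        if refine:
            from .posterior import MCMCConfig, mcmc_refine

            config = mcmc_config or MCMCConfig()
            stack, diagnostics = mcmc_refine(volume, self, cp, config)
        masks = None
        if rasterize or (volume is not None and not refine):
            if volume is not None:
                from .volume import rasterize_stack

                masks = rasterize_stack(stack, volume)
        return CasePrediction(stack=stack, masks=masks, diagnostics=diagnostics)

    # ------------------------------------------------------------------ #
    # presentation & persistence
    # ------------------------------------------------------------------ #
    def params_frame(self) -> pd.DataFrame:
        """Per-slice parameter table (one row per canonical slice)."""
        return pd.DataFrame(
            {
                "t": self.t_grid,
                "mu_eta1": self.mu_eta[:, 0],
                "mu_eta2": self.mu_eta[:, 1],
                "sd_eta1": self.sigma_eta[:, 0],
                "sd_eta2": self.sigma_eta[:, 1],
                "alpha1": np.exp(self.mu_a[:, 0]),
                "alpha2": np.exp(self.mu_a[:, 1]),
                "sd_log_a1": self.sigma_a[:, 0],
                "sd_log_a2": self.sigma_a[:, 1],
                "mu_phi": self.mu_phi,
                "sd_phi": self.sigma_phi,
            }
        )

    def summary(self) -> str:
        """Human-readable per-slice summary of the trained shape model."""
        head = (
            "Stacked-ellipse shape model\n"
            f"  canonical slices L = {self.L}, training cases N = {self.n_train}, "
            f"position mode = {self.position_mode}\n"
            "  alpha columns are geometric means exp(mu_a) [sample-space units];\n"
            "  eta are center offsets from the control-point center curve.\n\n"
        )
        return head + self.params_frame().to_string(
            index=False, float_format=lambda v: f"{v: .4f}"
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "ellipstack-shape-model",
            "L": int(self.L),
            "n_train": int(self.n_train),
            "position_mode": self.position_mode,
            "t_grid": self.t_grid.tolist(),
            "mu_eta": self.mu_eta.tolist(),
            "sigma_eta": self.sigma_eta.tolist(),
            "mu_theta": self.mu_theta.tolist(),
            "sigma_theta": self.sigma_theta.tolist(),
            "Sigma_theta": self.Sigma_theta.tolist(),
            "mu_a": self.mu_a.tolist(),
            "sigma_a": self.sigma_a.tolist(),
            "mu_phi": self.mu_phi.tolist(),
            "sigma_phi": self.sigma_phi.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeModelResults":
        if d.get("kind") != "ellipstack-shape-model":
            raise InvalidParameterError("not an ellipstack shape-model document")
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise InvalidParameterError(
                f"unsupported schema version {d.get('schema_version')}"
            )
        keys = [
            "L",
            "n_train",
            "position_mode",
            "t_grid",
            "mu_eta",
            "sigma_eta",
            "mu_theta",
            "sigma_theta",
            "Sigma_theta",
            "mu_a",
            "sigma_a",
            "mu_phi",
            "sigma_phi",
        ]
        return cls(**{k: d[k] for k in keys})

    @classmethod
    def load(cls, path) -> "ShapeModelResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
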