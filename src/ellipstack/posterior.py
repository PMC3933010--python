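"""Empirical-Bayes MCMC refinement of the deformed template.

The refined delineation is a draw-summary of the posterior

    pi(rho | S, CP)  proportional to  L(S | rho) * pi(rho | CP),

where the prior pi(rho | CP) is the trained shape prior re-centered on the
deformed template (the control points fix position, scale and orientation;
the prior then models realistic residual variation) and the likelihood
L(S | rho) scores the gray levels: voxels inside the ellipses under the
inside Gaussian, voxels in a fixed-width outside shell under the outside
Gaussian.  Both gray-level models are estimated from the image itself
(empirical Bayes), so no intensity calibration is needed.

The sampler is component-blocked random-walk Metropolis: one slice's five
sample-space parameters (eta1, eta2, a1 = log alpha1, a2, phi) form a block,
proposals are Gaussian with per-parameter scale proportional to the prior
sd.  Working in a = log(alpha) keeps the axis lengths positive
structurally.  Only the proposed slice's likelihood term is recomputed, so
one sweep costs L slice rasterizations over a bounding-box region of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidParameterError,
    MissingInputError,
    ShellUndefinedError,
)
from .geometry import EllipseParams, EllipseStack, implicit_value
from .registration import center_curve, compute_transform, from_sample_space, to_sample_space
from .volume import ImageVolume

__all__ = [
    "LikelihoodModel",
    "MCMCConfig",
    "estimate_likelihood_params",
    "log_likelihood",
    "mcmc_refine",
    "random_walk_metropolis",
]

_SD_FLOOR = 1e-6  # gray units


@dataclass(frozen=True)
class LikelihoodModel:
    """Two-population Gaussian gray-level model.

    ``mu_in/sd_in`` describe voxels inside the delineation, ``mu_out/sd_out``
    a shell of width ``band_mm`` just outside it."""

    mu_in: float
    sd_in: float
    mu_out: float
    sd_out: float
    band_mm: float = 5.0

    def __post_init__(self):
        if self.sd_in <= 0 or self.sd_out <= 0:
            raise InvalidParameterError("gray-level sds must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``proposal_scale`` is the per-parameter random-walk sd as a fraction of
    the prior sd; with ``adapt`` (default) a per-slice factor is tuned
    toward ``target_accept`` during burn-in and frozen afterwards, so the
    sampling phase is a fixed-kernel Metropolis chain whatever the relative
    informativeness of image and prior.  ``estimator`` picks the chain summary: the posterior mean
    of the parameters (alpha via the mean of log alpha) or the maximum
    a-posteriori visited state.  ``use_likelihood=False`` samples the prior
    alone (a diagnostic mode: the chain must then recenter on the deformed
    template)."""

    n_iter: int = 20000
    burn_in: int = 5000
    proposal_scale: float = 0.25
    seed: int | None = None
    estimator: str = "posterior_mean"
    use_likelihood: bool = True
    band_mm: float = 5.0
    adapt: bool = True
    target_accept: float = 0.3

    def __post_init__(self):
        if not (0 < self.burn_in < self.n_iter):
            raise InvalidParameterError("need 0 < burn_in < n_iter")
        if self.proposal_scale <= 0:
            raise InvalidParameterError("proposal_scale must be positive")
        if self.estimator not in ("posterior_mean", "map"):
            raise InvalidParameterError("estimator must be 'posterior_mean' or 'map'")


def _slice_region_values(
    volume: ImageVolume, z: float, params: EllipseParams, band_mm: float
):
    """Gray values inside the ellipse and in the outside shell, restricted to
    a bounding-box region of interest for speed."""
    k = volume.slice_index_of(z)
    outer = EllipseParams(
        theta=params.theta, alpha=params.alpha + band_mm, phi=params.phi
    )
    nz, ny, nx = volume.shape
    ox, oy = volume.origin[0], volume.origin[1]
    dx, dy = volume.spacing[0], volume.spacing[1]
    r = float(np.max(outer.alpha))
    ix0 = max(0, int(np.floor((params.theta[0] - r - ox) / dx)))
    ix1 = min(nx, int(np.ceil((params.theta[0] + r - ox) / dx)) + 1)
    iy0 = max(0, int(np.floor((params.theta[1] - r - oy) / dy)))
    iy1 = min(ny, int(np.ceil((params.theta[1] + r - oy) / dy)) + 1)
    if ix0 >= ix1 or iy0 >= iy1:
        return np.empty(0), np.empty(0)
    xs = ox + dx * np.arange(ix0, ix1)
    ys = oy + dy * np.arange(iy0, iy1)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    inside = implicit_value(params, pts) <= 1.0
    in_outer = implicit_value(outer, pts) <= 1.0
    shell = in_outer & ~inside
    vals = volume.voxels[k, iy0:iy1, ix0:ix1].ravel()
    return vals[inside], vals[shell]


def estimate_likelihood_params(
    volume: ImageVolume,
    stack: EllipseStack,
    band_mm: float = 5.0,
    rel_sd_floor: float = 0.05,
) -> LikelihoodModel:
    """Estimate the two gray-level populations from a delineation stack.

    The empirical sds are floored at 1e-6 gray units and, for robustness, at
    ``rel_sd_floor`` times the inside/outside contrast |mu_in - mu_out|: a
    (near-)noiseless region would otherwise make its Gaussian degenerate and
    let a single mis-assigned voxel dominate the whole posterior.
    """
    if band_mm <= 0:
        raise ShellUndefinedError("shell width must be positive")
    ins, outs = [], []
    for z, params in stack:
        vin, vout = _slice_region_values(volume, z, params, band_mm)
        ins.append(vin)
        outs.append(vout)
    vin = np.concatenate(ins) if ins else np.empty(0)
    vout = np.concatenate(outs) if outs else np.empty(0)
    if vin.size == 0:
        raise ShellUndefinedError("no voxels inside the delineation")
    if vout.size == 0:
        raise ShellUndefinedError("outside shell contains no voxels")
    mu_in, mu_out = float(vin.mean()), float(vout.mean())
    floor = max(_SD_FLOOR, rel_sd_floor * abs(mu_in - mu_out))
    return LikelihoodModel(
        mu_in=mu_in,
        sd_in=max(float(vin.std()), floor),
        mu_out=mu_out,
        sd_out=max(float(vout.std()), floor),
        band_mm=float(band_mm),
    )


def _gauss_loglik(vals: np.ndarray, mu: float, sd: float) -> float:
    if vals.size == 0:
        return 0.0
    return float(
        -0.5 * vals.size * np.log(2.0 * np.pi * sd * sd)
        - 0.5 * np.sum((vals - mu) ** 2) / (sd * sd)
    )


def slice_log_likelihood(
    volume: ImageVolume, z: float, params: EllipseParams, lik: LikelihoodModel
) -> float:
    """Log-likelihood contribution of one slice."""
    vin, vout = _slice_region_values(volume, z, params, lik.band_mm)
    return _gauss_loglik(vin, lik.mu_in, lik.sd_in) + _gauss_loglik(
        vout, lik.mu_out, lik.sd_out
    )


def log_likelihood(
    volume: ImageVolume, stack: EllipseStack, lik: LikelihoodModel
) -> float:
    """Joint gray-level log density of the volume given the stack: inside
    voxels scored under the inside Gaussian, shell voxels under the outside
    Gaussian.  Deterministic."""
    return float(
        sum(slice_log_likelihood(volume, z, p, lik) for z, p in stack)
    )


class _SliceROI:
    """Fixed scoring region for one slice of the refinement chain.

    The region (template ellipse dilated by the band plus a movement
    margin) is frozen at chain start; every contained voxel is scored under
    the inside Gaussian when the *current* ellipse covers it and under the
    outside Gaussian otherwise.  Because the voxel set never changes, the
    joint gray-level density is comparable across states — a per-state
    voxel set would reward shrinking the ellipse (fewer factors in the
    product) rather than matching the boundary."""

    def __init__(self, volume: ImageVolume, z: float, params: EllipseParams,
                 pad_mm: float, lik: LikelihoodModel):
        k = volume.slice_index_of(z)
        outer = EllipseParams(
            theta=params.theta, alpha=params.alpha + pad_mm, phi=params.phi
        )
        nz, ny, nx = volume.shape
        ox, oy = volume.origin[0], volume.origin[1]
        dx, dy = volume.spacing[0], volume.spacing[1]
        r = float(np.max(outer.alpha))
        ix0 = max(0, int(np.floor((params.theta[0] - r - ox) / dx)))
        ix1 = min(nx, int(np.ceil((params.theta[0] + r - ox) / dx)) + 1)
        iy0 = max(0, int(np.floor((params.theta[1] - r - oy) / dy)))
        iy1 = min(ny, int(np.ceil((params.theta[1] + r - oy) / dy)) + 1)
        xs = ox + dx * np.arange(ix0, ix1)
        ys = oy + dy * np.arange(iy0, iy1)
        X, Y = np.meshgrid(xs, ys)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        keep = implicit_value(outer, pts) <= 1.0
        self.pts = pts[keep]
        vals = volume.voxels[k, iy0:iy1, ix0:ix1].ravel()[keep].astype(float)

        def logpdf(v, mu, sd):
            return -0.5 * np.log(2.0 * np.pi * sd * sd) - 0.5 * ((v - mu) / sd) ** 2

        lp_in = logpdf(vals, lik.mu_in, lik.sd_in)
        lp_out = logpdf(vals, lik.mu_out, lik.sd_out)
        self._lp_out_total = float(lp_out.sum())
        self._delta = lp_in - lp_out  # gain of classifying a voxel inside

    def log_likelihood(self, params: EllipseParams) -> float:
        inside = implicit_value(params, self.pts) <= 1.0
        return self._lp_out_total + float(self._delta[inside].sum())


def random_walk_metropolis(logpost, x0, scales, n_iter: int, rng=None):
    """Plain random-walk Metropolis on a flat parameter vector.

    Returns (samples (n_iter, d), acceptance_rate, logpost_trace).  Used
    directly for low-dimensional diagnostics; the delineation refiner uses
    the slice-blocked variant inside :func:`mcmc_refine`."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(x0, dtype=float).copy()
    scales = np.asarray(scales, dtype=float)
    lp = float(logpost(x))
    samples = np.empty((n_iter, x.size))
    trace = np.empty(n_iter)
    accepted = 0
    for i in range(n_iter):
        prop = x + rng.normal(0.0, scales)
        lp_prop = float(logpost(prop))
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        samples[i] = x
        trace[i] = lp
    return samples, accepted / n_iter, trace


def mcmc_refine(
    volume: ImageVolume,
    results,
    cp,
    config: MCMCConfig | None = None,
    slice_z=None,
):
    """Refine the deformed template against the image gray levels.

    Runs slice-blocked random-walk Metropolis over the sample-space
    parameters, prior re-centered on the deformed template, likelihood from
    the empirical two-population gray model.  Returns the summary stack (in
    the patient frame) and a diagnostics dict with per-slice acceptance
    rates and the log-posterior trace.
    """
    if volume is None:
        raise MissingInputError("refinement requires an image volume")
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)

    if slice_z is None:
        slice_z = volume.slice_positions
    template = results.deform(cp, slice_z)
    Lc = len(template)
    t = compute_transform(cp)
    template_s = to_sample_space(template, t)
    cp_s = cp.transformed(t.apply_points)
    curve_s = center_curve(cp_s)
    z_s = template_s.z
    xi = curve_s.at(z_s)

    # prior: means from the template, sds interpolated to the case slices
    t_case = (z_s - z_s[0]) / (z_s[-1] - z_s[0])
    t_grid = results.t_grid

    def interp_cols(arr):
        arr = np.atleast_2d(arr.T).T
        return np.column_stack(
            [np.interp(t_case, t_grid, arr[:, j]) for j in range(arr.shape[1])]
        )

    sd = np.column_stack(
        [
            interp_cols(results.sigma_eta),
            interp_cols(results.sigma_a),
            interp_cols(results.sigma_phi),
        ]
    )  # (Lc, 5) sds for (eta1, eta2, a1, a2, phi)
    mu = np.column_stack(
        [
            template_s.theta - xi,
            np.log(template_s.alpha),
            template_s.phi,
        ]
    )  # (Lc, 5) prior means = template parameters

    if config.use_likelihood:
        lik = estimate_likelihood_params(volume, template, band_mm=config.band_mm)
        rois = [
            _SliceROI(volume, z, p, 2.0 * config.band_mm, lik)
            for z, p in template
        ]
    else:
        lik, rois = None, None

    def patient_params(row, l):
        """Map one slice's state row to patient-frame EllipseParams."""
        theta_s = xi[l] + row[:2]
        stack_row = EllipseStack.from_arrays(
            [z_s[l]], theta_s[None, :], np.exp(row[2:4])[None, :], [row[4]]
        )
        return from_sample_space(stack_row, t).params[0]

    def prior_term(row, l):
        v = (row - mu[l]) / np.where(sd[l] > 0, sd[l], 1.0)
        bad = (sd[l] <= 0) & (np.abs(row - mu[l]) > 1e-12)
        if np.any(bad):
            return -np.inf
        live = sd[l] > 0
        return float(
            -0.5 * np.sum(v[live] ** 2)
            - np.sum(np.log(sd[l][live]))
            - row[2]
            - row[3]  # log-normal Jacobian for alpha
        )

    def lik_term(row, l):
        if lik is None:
            return 0.0
        return rois[l].log_likelihood(patient_params(row, l))
    state = mu.copy()
    prior_vals = np.array([prior_term(state[l], l) for l in range(Lc)])
    lik_vals = np.array([lik_term(state[l], l) for l in range(Lc)])

    prop_sd = config.proposal_scale * np.maximum(sd, 1e-8)
    prop_factor = np.ones(Lc)
    n_samp = config.n_iter
    sums = np.zeros_like(state)
    count = 0
    accept_post = np.zeros(Lc)
    win_acc = np.zeros(Lc)
    win_n = 0
    trace = np.empty(n_samp)
    best_lp, best_state = -np.inf, state.copy()

    for it in range(n_samp):
        for l in range(Lc):
            prop = state[l] + rng.normal(0.0, prop_factor[l] * prop_sd[l])
            p_new = prior_term(prop, l)
            if np.isfinite(p_new):
                l_new = lik_term(prop, l)
                if np.log(rng.uniform()) < (p_new + l_new) - (
                    prior_vals[l] + lik_vals[l]
                ):
                    state[l] = prop
                    prior_vals[l] = p_new
                    lik_vals[l] = l_new
                    win_acc[l] += 1
                    if it >= config.burn_in:
                        accept_post[l] += 1
        win_n += 1
        if config.adapt and it < config.burn_in and win_n >= 25:
            prop_factor *= np.exp(2.0 * (win_acc / win_n - config.target_accept))
            np.clip(prop_factor, 1e-3, 1e2, out=prop_factor)
            win_acc[:] = 0.0
            win_n = 0
        lp = float(prior_vals.sum() + lik_vals.sum())
        trace[it] = lp
        if lp > best_lp:
            best_lp, best_state = lp, state.copy()
        if it >= config.burn_in:
            sums += state
            count += 1
    accept = accept_post / max(config.n_iter - config.burn_in, 1)

    diagnostics = {
        "acceptance_rates": accept,
        "proposal_factors": prop_factor,
        "logpost_trace": trace,
        "n_iter": config.n_iter,
        "burn_in": config.burn_in,
        "stuck": bool(np.all(accept == 0.0)),
    }
    if diagnostics["stuck"]:
        import warnings

        warnings.warn("MCMC chain accepted no proposals; inspect diagnostics")

    summary = best_state if config.estimator == "map" else sums / max(count, 1)
    theta_s = xi + summary[:, :2]
    refined_s = EllipseStack.from_arrays(
        z_s, theta_s, np.exp(summary[:, 2:4]), summary[:, 4]
    )
    refined = from_sample_space(refined_s, t)
    return refined, diagnostics
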