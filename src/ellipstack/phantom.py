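"""Synthetic phantom populations.

The generator emulates the acquisition geometry of the axial MR data the
method targets: ~0.559 mm in-plane spacing on a 288 x 288 grid, 3.3 mm
slice distance, and 6-15 contour slices per case (population mean ~10.5).
Each case's ground truth is a stack of ellipses with smoothly varying
parameters: end-tapered axis profiles with mid-slice semi-axes in the
15-30 mm range, a smooth center drift around a gentle arc, and a small
smooth rotation-angle profile around a population orientation.  Gray levels
follow a two-population model (organ vs background) with additive Gaussian
noise.

Observed contours are densely sampled truth boundaries plus point jitter;
an optional "bumpy" mode adds low-order angular perturbations to the true
boundary so the best ellipse no longer matches it exactly — this emulates
the residual between real organs and the ellipse family and separates
fitting error from model mismatch in experiments.  Control points are
placed automatically on the first/center/last truth slices with their own
jitter, emulating manual clicks.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .geometry import (
    EllipseParams,
    EllipseStack,
    GridSpec,
    SliceContour,
    rotation_matrix,
)
from .registration import ControlPointSet, auto_control_points
from .volume import ImageVolume, contour_masks_on_grid

__all__ = ["PhantomSpec", "PhantomCase", "generate_case", "generate_population", "split_population"]


@dataclass(frozen=True)
class PhantomSpec:
    """Population-level generator settings (defaults are the study
    conditions; see module docstring)."""

    n_cases: int = 33
    L_range: tuple = (6, 15)
    in_plane_spacing: tuple = (0.559, 0.559)  # mm
    slice_distance: float = 3.3  # mm
    grid_shape: tuple = (288, 288)  # (ny, nx)
    margin_slices: int = 2
    alpha_mid_range: tuple = (15.0, 30.0)  # mm, first semi-axis at mid slice
    aspect_range: tuple = (0.70, 0.95)  # alpha2/alpha1
    taper_range: tuple = (0.70, 0.85)  # end-taper coefficient
    center_offset_mm: float = 10.0  # uniform in-plane offset of the organ
    center_arc_sd: float = 2.0  # mm, quadratic bow of the center curve
    center_drift_sd: float = 0.5  # mm per slice, smoothed random walk
    phi_pop_mean: float = 0.2  # rad, population orientation
    phi_case_sd: float = 0.1  # rad, case-to-case orientation spread
    phi_slice_amplitude: float = 0.05  # rad, smooth within-case variation
    mu_in: float = 200.0
    mu_out: float = 100.0
    noise_sd: float = 10.0
    contour_points: int = 96
    contour_jitter_sd: float = 0.3  # mm
    cp_jitter_sd: float = 1.0  # mm
    bumpy: bool = False
    bump_amplitudes: tuple = (0.03, 0.02)  # relative radius, harmonics 2 and 3
    seed: int = 0

    def __post_init__(self):
        if not (4 <= self.L_range[0] <= self.L_range[1] <= 20):
            raise InvalidParameterError("L_range must lie within [4, 20]")
        for s in (self.contour_jitter_sd, self.cp_jitter_sd, self.noise_sd):
            if s < 0:
                raise InvalidParameterError("jitter/noise sds must be >= 0")


@dataclass
class PhantomCase:
    """One generated case: ground truth, observations and geometry."""

    truth: EllipseStack
    truth_contours: list  # noise-free boundary contours (bumpy if enabled)
    contours: list  # observed (jittered) contours
    cp: ControlPointSet
    grid: GridSpec
    slice_z: np.ndarray  # z positions of all volume slices
    volume: ImageVolume | None = None

    def geometry_volume(self) -> ImageVolume:
        """An ImageVolume carrying only the case geometry (zero voxels);
        enough for rasterization and metric evaluation."""
        if self.volume is not None:
            return self.volume
        nz = len(self.slice_z)
        ny, nx = self.grid.shape
        return ImageVolume(
            voxels=np.zeros((nz, ny, nx), dtype=np.float32),
            spacing=(self.grid.spacing[0], self.grid.spacing[1],
                     self.slice_z[1] - self.slice_z[0]),
            origin=(self.grid.origin[0], self.grid.origin[1], self.slice_z[0]),
        )

    def truth_masks(self) -> np.ndarray:
        """Reference masks: the noise-free truth contours voxelized."""
        return contour_masks_on_grid(self.truth_contours, self.geometry_volume())


def _smooth_walk(rng, n: int, sd: float) -> np.ndarray:
    """Zero-mean smooth in-plane drift: moving-averaged random walk."""
    if sd <= 0 or n < 2:
        return np.zeros((n, 2))
    steps = rng.normal(0.0, sd, size=(n, 2))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(3) / 3.0
    sm = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(2)]
    )
    return sm - sm.mean(axis=0)


def _bumpy_boundary(params: EllipseParams, psi: np.ndarray, amps, phases) -> np.ndarray:
    """Boundary points with low-order angular radius perturbations."""
    factor = 1.0 + sum(
        a * np.cos((k + 2) * psi + p) for k, (a, p) in enumerate(zip(amps, phases))
    )
    local = np.column_stack(
        [params.alpha[0] * np.cos(psi), params.alpha[1] * np.sin(psi)]
    ) * factor[:, None]
    return local @ rotation_matrix(params.phi).T + params.theta


def generate_case(
    spec: PhantomSpec, case_seed, with_volume: bool = True
) -> PhantomCase:
    """Generate one phantom case, fully reproducible from (spec, case_seed)."""
    rng = np.random.default_rng(case_seed)
    Ln = int(rng.integers(spec.L_range[0], spec.L_range[1] + 1))
    u = np.linspace(-1.0, 1.0, Ln)

    a1_mid = rng.uniform(*spec.alpha_mid_range)
    aspect = rng.uniform(*spec.aspect_range)
    taper = rng.uniform(*spec.taper_range)
    prof = np.sqrt(1.0 - taper * u * u)
    alpha = np.column_stack([a1_mid * prof, a1_mid * aspect * prof])

    base = rng.uniform(-spec.center_offset_mm, spec.center_offset_mm, size=2)
    bow = rng.normal(0.0, spec.center_arc_sd, size=2)
    theta = base + bow * (1.0 - u * u)[:, None] + _smooth_walk(
        rng, Ln, spec.center_drift_sd
    )

    phi0 = rng.normal(spec.phi_pop_mean, spec.phi_case_sd)
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    phi = phi0 + spec.phi_slice_amplitude * np.sin(np.pi * freq * u + phase)

    z = spec.slice_distance * (spec.margin_slices + np.arange(Ln))
    truth = EllipseStack.from_arrays(z, theta, alpha, phi)

    bump_phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.bump_amplitudes))
    psi_dense = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    psi_obs = np.linspace(0.0, 2.0 * np.pi, spec.contour_points, endpoint=False)

    def boundary(params, psi):
        if spec.bumpy:
            return _bumpy_boundary(params, psi, spec.bump_amplitudes, bump_phases)
        local = np.column_stack(
            [params.alpha[0] * np.cos(psi), params.alpha[1] * np.sin(psi)]
        )
        return local @ rotation_matrix(params.phi).T + params.theta

    truth_contours, contours = [], []
    for zi, params in truth:
        truth_contours.append(SliceContour(z=zi, points=boundary(params, psi_dense)))
        pts = boundary(params, psi_obs)
        if spec.contour_jitter_sd > 0:
            pts = pts + rng.normal(0.0, spec.contour_jitter_sd, size=pts.shape)
        contours.append(SliceContour(z=zi, points=pts))

    cp = auto_control_points(truth, jitter_sd=spec.cp_jitter_sd, rng=rng)

    ny, nx = spec.grid_shape
    dx, dy = spec.in_plane_spacing
    grid = GridSpec(
        origin=(-(nx - 1) / 2.0 * dx, -(ny - 1) / 2.0 * dy),
        spacing=(dx, dy),
        shape=(ny, nx),
    )
    nz = Ln + 2 * spec.margin_slices
    slice_z = spec.slice_distance * np.arange(nz)

    case = PhantomCase(
        truth=truth,
        truth_contours=truth_contours,
        contours=contours,
        cp=cp,
        grid=grid,
        slice_z=slice_z,
        volume=None,
    )
    if with_volume:
        vol = case.geometry_volume()
        masks = contour_masks_on_grid(truth_contours, vol)
        vox = np.where(masks, spec.mu_in, spec.mu_out).astype(np.float32)
        if spec.noise_sd > 0:
            vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape).astype(
                np.float32
            )
        case.volume = ImageVolume(
            voxels=vox, spacing=vol.spacing, origin=vol.origin
        )
    return case


def generate_population(spec: PhantomSpec, with_volume: bool = False) -> list:
    """Generate ``spec.n_cases`` cases with independent per-case seeds
    derived from ``spec.seed``."""
    if spec.n_cases < 4:
        raise InvalidParameterError("need at least 4 cases for a population")
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_cases)
    return [generate_case(spec, s, with_volume=with_volume) for s in children]


def split_population(cases, n_train: int = 23, mode: str = "sequential", seed=None):
    """Split cases into (train, test).

    ``sequential`` keeps acquisition order (first ``n_train`` cases train);
    ``random`` permutes with the given seed, for robustness experiments."""
    if not (0 < n_train < len(cases)):
        raise InvalidParameterError("n_train must be within (0, n_cases)")
    if mode == "sequential":
        idx = np.arange(len(cases))
    elif mode == "random":
        idx = np.random.default_rng(seed).permutation(len(cases))
    else:
        raise InvalidParameterError("mode must be 'sequential' or 'random'")
    train = [cases[i] for i in idx[:n_train]]
    test = [cases[i] for i in idx[n_train:]]
    return train, test
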