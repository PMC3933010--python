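"""Shared fixtures and helpers for the ellipstack test suite."""

import numpy as np
import pytest

from ellipstack.geometry import EllipseParams, EllipseStack, SliceContour, rotation_matrix


def sample_ellipse_points(params: EllipseParams, n: int, rng=None, noise_sd: float = 0.0):
    """Points on (or near) an ellipse boundary at uniform parametric angles."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    local = np.column_stack([params.alpha[0] * np.cos(t), params.alpha[1] * np.sin(t)])
    pts = local @ rotation_matrix(params.phi).T + params.theta
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts


def random_params(rng, center_scale: float = 20.0) -> EllipseParams:
    """A random, well-conditioned ellipse."""
    return EllipseParams(
        theta=rng.uniform(-center_scale, center_scale, 2),
        alpha=np.sort(rng.uniform(5.0, 30.0, 2))[::-1],
        phi=rng.uniform(-np.pi / 2, np.pi / 2),
    )


def smooth_stack(L: int = 9, phi0: float = 0.3, slice_distance: float = 3.3) -> EllipseStack:
    """A benign, deterministic stack: tapered axes, smooth centers, constant
    rotation; non-circular everywhere so correspondence passes are no-ops."""
    u = np.linspace(-1.0, 1.0, L)
    prof = np.sqrt(1.0 - 0.8 * u * u)
    alpha = np.column_stack([20.0 * prof, 14.0 * prof])
    theta = np.column_stack([5.0 + 2.0 * (1.0 - u * u), -3.0 + 0.5 * u])
    phi = np.full(L, phi0)
    return EllipseStack.from_arrays(slice_distance * np.arange(L), theta, alpha, phi)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def benign_stack():
    return smooth_stack()
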